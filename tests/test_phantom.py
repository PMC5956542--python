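"""Geometry oracles: edge positions, thicknesses, rasterisation."""

import math

import numpy as np
import pytest

from uswicrack import (
    BLOOD,
    CrackSpec,
    DomainSpec,
    LIVER,
    MaterialSpec,
    build_material_field,
    curved_crack,
    ground_truth_table,
    horizontal_thickness,
    left_edge_x,
    right_edge_x,
    slim_crack,
    straight_crack,
)
from uswicrack.phantom import TABLE_DEPTHS_CM, crack_mask_at

# Transverse positions of the right (near-end) edge at the reference
# depths, cm: the published comparison table's analytic column.
GIVEN_RIGHT_EDGE = {
    "straight": [1.464, 1.441, 1.408, 1.274, 1.173, 1.062, 0.961, 0.850, 0.738],
    "curved": [1.515, 1.510, 1.500, 1.425, 1.328, 1.183],
    "slim": [1.464, 1.441, 1.408],
}

CRACKS = {
    "straight": straight_crack,
    "curved": curved_crack,
    "slim": slim_crack,
}


@pytest.mark.parametrize("shape", list(GIVEN_RIGHT_EDGE))
def test_right_edge_matches_reference_table(shape):
    """Closed-form right edge reproduces every printed position to 0.002 cm."""
    crack = CRACKS[shape]()
    for depth, given in zip(TABLE_DEPTHS_CM[shape], GIVEN_RIGHT_EDGE[shape]):
        assert right_edge_x(crack, depth) == pytest.approx(given, abs=0.002)


def test_right_edge_closed_forms():
    straight = straight_crack()
    assert right_edge_x(straight, 0.0) == pytest.approx(1.519)
    assert right_edge_x(straight, 2.917) == pytest.approx(0.738, abs=0.002)
    curved = curved_crack()
    assert right_edge_x(curved, 1.709) == pytest.approx(1.183, abs=0.002)
    # slim and straight share the (immovable) right edge
    assert right_edge_x(slim_crack(), 0.291) == pytest.approx(
        right_edge_x(straight, 0.291)
    )


def test_left_edge_closed_forms():
    assert left_edge_x(straight_crack(), 0.0) == pytest.approx(1.354)
    # curved left arc passes through the same top-left point
    assert left_edge_x(curved_crack(), 0.0) == pytest.approx(-3.146 + 4.5)
    assert left_edge_x(slim_crack(), 0.0) == pytest.approx(1.467)


def test_edge_depth_out_of_range_raises():
    with pytest.raises(ValueError):
        right_edge_x(slim_crack(), 0.6)
    with pytest.raises(ValueError):
        right_edge_x(straight_crack(), -0.1)


def test_horizontal_thickness():
    assert horizontal_thickness(straight_crack()) == pytest.approx(0.165)
    assert horizontal_thickness(slim_crack()) == pytest.approx(0.052)
    # perpendicular thicknesses recovered via the 15-degree tilt
    assert horizontal_thickness(straight_crack()) * math.cos(math.radians(15)) == (
        pytest.approx(0.160, abs=0.001)
    )
    assert horizontal_thickness(slim_crack()) * math.cos(math.radians(15)) == (
        pytest.approx(0.050, abs=0.001)
    )
    # curved crack: per-depth horizontal gap, constant by construction
    assert horizontal_thickness(curved_crack(), 1.0) == pytest.approx(0.165)


def test_edges_monotone_decreasing_in_depth():
    for shape, make in CRACKS.items():
        crack = make()
        d = np.linspace(0, crack.depth_cm, 50)
        x = right_edge_x(crack, d)
        assert np.all(np.diff(x) < 0), shape


def test_material_specs():
    assert LIVER.shear_modulus == pytest.approx(6000 / (2 * 1.499))
    # nearly incompressible: c within 0.5% of sqrt(E / (3 rho))
    assert LIVER.shear_speed == pytest.approx(
        math.sqrt(6000 / (3 * 1200)), rel=0.005
    )
    assert BLOOD.shear_modulus < 2e-3
    with pytest.raises(ValueError):
        MaterialSpec(density=1000, poisson=0.5, young=1e3)


def test_crack_spec_consistency_checks():
    with pytest.raises(ValueError):
        CrackSpec("straight", 1.354, 1.60, 3.2, 0.16)  # gap vs thickness
    with pytest.raises(ValueError):
        CrackSpec("curved", 1.30, 1.519, 1.8, 0.16)  # arc misses top point
    with pytest.raises(ValueError):
        CrackSpec("banana", 1.354, 1.519, 3.2, 0.16)


def test_domain_roi_grid():
    dom = DomainSpec()
    assert dom.roi_shape == (200, 400)
    with pytest.raises(ValueError):
        DomainSpec(grid_dx_cm=0.013)


def test_material_field_rasterisation(domain):
    mf = build_material_field(domain, None)
    assert np.allclose(mf.shear_modulus, 6000 / (2 * 1.499))
    mf = build_material_field(domain, straight_crack())
    # a point between the edge curves carries the filler material
    ix = int(np.argmin(np.abs(mf.x_centers_cm - 1.45)))
    iy = int(np.argmin(np.abs(mf.y_centers_cm - 0.10)))
    assert mf.crack_mask[iy, ix]
    assert mf.shear_modulus[iy, ix] == pytest.approx(BLOOD.shear_modulus)
    # far-away background point
    ix = int(np.argmin(np.abs(mf.x_centers_cm - 0.5)))
    iy = int(np.argmin(np.abs(mf.y_centers_cm - 2.0)))
    assert not mf.crack_mask[iy, ix]
    # every cell assigned exactly one material
    assert set(np.unique(mf.density)) == {BLOOD.density, LIVER.density}


def test_resolution_guard():
    with pytest.raises(ValueError, match="resolution"):
        build_material_field(DomainSpec(), slim_crack(), resolution_cm=0.03)


def test_rasterisation_converges_to_analytic_band_area(domain):
    """Halving the cell size at least halves the relative area error."""
    crack = straight_crack()
    # analytic band area: horizontal width x depth (constant width band)
    analytic = horizontal_thickness(crack) * crack.depth_cm
    errs = []
    for res in (0.0125, 0.00625):
        mf = build_material_field(domain, crack, resolution_cm=res)
        area = mf.crack_mask.sum() * res * res
        errs.append(abs(area - analytic) / analytic)
    assert errs[1] <= errs[0] * 0.6 or errs[1] < 1e-3


def test_crack_mask_band_thickness(domain):
    """Mask thickness perpendicular to the edge matches the specified thickness within a cell."""
    crack = straight_crack()
    mf = build_material_field(domain, crack)
    iy = int(np.argmin(np.abs(mf.y_centers_cm - 1.5)))
    row = np.flatnonzero(mf.crack_mask[iy])
    width = (row.max() - row.min() + 1) * mf.dx_cm * math.cos(math.radians(15))
    assert width == pytest.approx(crack.thickness_cm, abs=mf.dx_cm * 1.5)


def test_ground_truth_table():
    tab = ground_truth_table(straight_crack(), [0.208, 0.917, 2.500])
    assert tab["given_x_cm"].tolist() == pytest.approx(
        [1.464, 1.274, 0.850], abs=0.002
    )
    assert ground_truth_table(curved_crack(), [0.416])["given_x_cm"][0] == (
        pytest.approx(1.500, abs=0.002)
    )
    empty = ground_truth_table(straight_crack(), [])
    assert len(empty) == 0
    with pytest.raises(ValueError):
        ground_truth_table(slim_crack(), [1.0])


def test_crack_mask_point_test_matches_edges():
    crack = curved_crack()
    d = 1.0
    xr = right_edge_x(crack, d)
    xl = left_edge_x(crack, d)
    assert crack_mask_at(crack, (xl + xr) / 2, d)
    assert not crack_mask_at(crack, xr + 0.01, d)
    assert not crack_mask_at(crack, xl - 0.01, d)
    assert not crack_mask_at(crack, (xl + xr) / 2, crack.depth_cm + 0.01)
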