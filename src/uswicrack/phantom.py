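"""Phantom geometry: crack shapes, material maps and analytic ground truth.

Coordinate frame
----------------
``x`` is the lateral position (cm) from the left boundary of the 5 x 5 cm
medium; the vertical push rod sits on the centre plane ``x = 2.5``.
``y`` is the depth (cm) below the top free surface, ``y in [0, 5]``.  The
imaging region of interest (ROI) is the half-domain left of the rod,
``x in [0, 2.5]``, ``y in [0, 5]``; the incident shear wave therefore
travels toward -x inside the ROI, and the crack's right edge (larger x)
is the near end facing the source.

All public geometry interfaces use cm (the natural unit at this scale);
the wave solver converts to SI once when it consumes a
:class:`MaterialField`.

Three crack geometries are supported, each a thin blood-filled band that
opens at the top surface:

* ``straight`` — 3.2 cm deep, 1.6 mm thick, tilted 15 degrees from vertical,
  top edges at x = 1.354 and 1.519 cm;
* ``slim``     — same direction and right edge, but only 0.5 cm deep and
  0.5 mm thick (top edges at x = 1.467 and 1.519 cm);
* ``curved``   — the band between two circles of radius 4.5 cm centred at
  depth 0 and x = -3.146 / -2.981 cm, truncated at 1.8 cm depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DomainSpec", "MaterialSpec", "CrackSpec", "MaterialField",
    "LIVER", "BLOOD", "straight_crack", "curved_crack", "slim_crack",
    "right_edge_x", "left_edge_x", "horizontal_thickness",
    "build_material_field", "ground_truth_table", "TABLE_DEPTHS_CM",
]

CM = 1e-2  # metres per centimetre


@dataclass(frozen=True)
class DomainSpec:
    """Simulation domain and ROI export grid (cm)."""

    width_cm: float = 5.0
    height_cm: float = 5.0
    roi_x_cm: tuple[float, float] = (0.0, 2.5)
    roi_y_cm: tuple[float, float] = (0.0, 5.0)
    grid_dx_cm: float = 0.0125
    grid_dy_cm: float = 0.0125

    def __post_init__(self) -> None:
        nx = (self.roi_x_cm[1] - self.roi_x_cm[0]) / self.grid_dx_cm
        ny = (self.roi_y_cm[1] - self.roi_y_cm[0]) / self.grid_dy_cm
        if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
            raise ValueError("ROI extent must be an integer number of grid cells")
        if not (self.roi_x_cm[0] >= -1e-12
                and self.roi_x_cm[1] <= self.width_cm + 1e-12
                and self.roi_y_cm[1] <= self.height_cm + 1e-12):
            raise ValueError("ROI must be contained in the domain")

    @property
    def roi_shape(self) -> tuple[int, int]:
        """(nx, ny) of the ROI export grid; the default is (200, 400)."""
        return (
            round((self.roi_x_cm[1] - self.roi_x_cm[0]) / self.grid_dx_cm),
            round((self.roi_y_cm[1] - self.roi_y_cm[0]) / self.grid_dy_cm),
        )

    @property
    def x_range_cm(self) -> tuple[float, float]:
        return (0.0, self.width_cm)

    @property
    def rod_plane_x_cm(self) -> float:
        return self.width_cm / 2


@dataclass(frozen=True)
class MaterialSpec:
    """Linear elastic material (SI units)."""

    density: float        # kg/m^3
    poisson: float        # dimensionless, in (0, 0.5)
    young: float          # Pa

    def __post_init__(self) -> None:
        if not 0.0 < self.poisson < 0.5:
            raise ValueError(f"Poisson ratio must be in (0, 0.5), got {self.poisson}")
        if self.young <= 0 or self.density <= 0:
            raise ValueError("Young's modulus and density must be positive")

    @property
    def shear_modulus(self) -> float:
        """mu = E / (2 (1 + nu)), Pa."""
        return self.young / (2.0 * (1.0 + self.poisson))

    @property
    def shear_speed(self) -> float:
        """c = sqrt(mu / rho), m/s.  For nu -> 0.5 this tends to sqrt(E/(3 rho))."""
        return math.sqrt(self.shear_modulus / self.density)


#: Background liver-mimicking medium (shear speed ~1.29 m/s).
LIVER = MaterialSpec(density=1.2e3, poisson=0.499, young=6e3)
#: Blood-mimicking crack filler: essentially zero shear stiffness.
BLOOD = MaterialSpec(density=1.06e3, poisson=0.499, young=0.005)


@dataclass(frozen=True)
class CrackSpec:
    """Geometry of one crack band opening at the top surface.

    ``thickness_cm`` is measured perpendicular to the band for straight/slim
    cracks; for the curved crack it is the nominal value (the exact band is
    defined by the two circles).
    """

    shape: str                      # "straight" | "curved" | "slim"
    top_left_x_cm: float
    top_right_x_cm: float
    depth_cm: float
    thickness_cm: float
    tilt_deg: float = 15.0          # straight/slim only
    circle_center_left_x_cm: float = -3.146   # curved only; centres at depth 0
    circle_center_right_x_cm: float = -2.981
    circle_radius_cm: float = 4.5

    def __post_init__(self) -> None:
        if self.shape not in ("straight", "curved", "slim"):
            raise ValueError(f"unknown crack shape {self.shape!r}")
        if self.depth_cm <= 0:
            raise ValueError("crack depth must be positive")
        if self.shape in ("straight", "slim"):
            gap = self.top_right_x_cm - self.top_left_x_cm
            want = self.thickness_cm / math.cos(math.radians(self.tilt_deg))
            if abs(gap - want) > 0.005:
                raise ValueError(
                    f"top edge gap {gap:.4f} cm inconsistent with thickness "
                    f"{self.thickness_cm:.4f} cm at {self.tilt_deg} deg tilt"
                )
        else:
            for xc, xt in (
                (self.circle_center_left_x_cm, self.top_left_x_cm),
                (self.circle_center_right_x_cm, self.top_right_x_cm),
            ):
                if abs(abs(xt - xc) - self.circle_radius_cm) > 1e-6:
                    raise ValueError("curved-crack arc does not pass through its top point")


def straight_crack() -> CrackSpec:
    """The 3.2 cm deep, 1.6 mm thick crack tilted 15 degrees from vertical."""
    return CrackSpec("straight", 1.354, 1.519, 3.2, 0.16)


def slim_crack() -> CrackSpec:
    """The 0.5 cm deep, 0.5 mm thick crack sharing the straight crack's right edge."""
    return CrackSpec("slim", 1.467, 1.519, 0.5, 0.05)


def curved_crack() -> CrackSpec:
    """The 1.8 cm deep band between two intersecting 4.5 cm radius circles."""
    return CrackSpec("curved", 1.354, 1.519, 1.8, 0.16)


def _check_depth(crack: CrackSpec, depth_cm) -> np.ndarray:
    d = np.asarray(depth_cm, dtype=float)
    if np.any(d < -1e-12) or np.any(d > crack.depth_cm + 1e-12):
        raise ValueError(
            f"depth must lie in [0, {crack.depth_cm}] cm for the {crack.shape} crack"
        )
    return d


def right_edge_x(crack: CrackSpec, depth_cm) -> np.ndarray | float:
    """Lateral position (cm) of the crack's right (near-end) edge at a depth.

    The right edge faces the push rod; it is the edge the reflected shear
    wave delineates.  Scalar in, scalar out; array in, array out.
    """
    d = _check_depth(crack, depth_cm)
    if crack.shape in ("straight", "slim"):
        x = crack.top_right_x_cm - d * math.tan(math.radians(crack.tilt_deg))
    else:
        x = crack.circle_center_right_x_cm + np.sqrt(crack.circle_radius_cm**2 - d**2)
    return float(x) if np.isscalar(depth_cm) else x


def left_edge_x(crack: CrackSpec, depth_cm) -> np.ndarray | float:
    """Lateral position (cm) of the crack's left (far-end) edge at a depth."""
    d = _check_depth(crack, depth_cm)
    if crack.shape in ("straight", "slim"):
        x = crack.top_left_x_cm - d * math.tan(math.radians(crack.tilt_deg))
    else:
        x = crack.circle_center_left_x_cm + np.sqrt(crack.circle_radius_cm**2 - d**2)
    return float(x) if np.isscalar(depth_cm) else x


def horizontal_thickness(crack: CrackSpec, depth_cm: float = 0.0) -> float:
    """Horizontal gap (cm) between the two edges.

    Constant for straight/slim cracks (``top_right - top_left``); for the
    curved crack the gap varies with depth, so the per-depth value is
    returned.
    """
    if crack.shape in ("straight", "slim"):
        return crack.top_right_x_cm - crack.top_left_x_cm
    return float(right_edge_x(crack, depth_cm) - left_edge_x(crack, depth_cm))


@dataclass
class MaterialField:
    """Rasterised material maps over the full domain.

    Arrays are indexed ``[iy, ix]`` with cell centres at
    ``x = x0 + (ix + 0.5) dx``, ``y = (iy + 0.5) dy``.
    """

    density: np.ndarray       # kg/m^3
    shear_modulus: np.ndarray  # Pa
    crack_mask: np.ndarray    # bool
    dx_cm: float
    dy_cm: float
    x0_cm: float              # left edge of the domain
    y0_cm: float = 0.0
    domain: DomainSpec = field(default_factory=DomainSpec)
    crack: CrackSpec | None = None

    @property
    def x_centers_cm(self) -> np.ndarray:
        return self.x0_cm + (np.arange(self.density.shape[1]) + 0.5) * self.dx_cm

    @property
    def y_centers_cm(self) -> np.ndarray:
        return self.y0_cm + (np.arange(self.density.shape[0]) + 0.5) * self.dy_cm


def crack_mask_at(crack: CrackSpec, x_cm: np.ndarray, y_cm: np.ndarray) -> np.ndarray:
    """Point-in-band test: True where (x, y) lies inside the crack filler."""
    x = np.asarray(x_cm, dtype=float)
    y = np.asarray(y_cm, dtype=float)
    inside_depth = (y >= 0) & (y <= crack.depth_cm)
    d = np.clip(y, 0.0, crack.depth_cm)
    if crack.shape in ("straight", "slim"):
        t = math.tan(math.radians(crack.tilt_deg))
        left = crack.top_left_x_cm - d * t
        right = crack.top_right_x_cm - d * t
    else:
        s = np.sqrt(np.maximum(crack.circle_radius_cm**2 - d**2, 0.0))
        left = crack.circle_center_left_x_cm + s
        right = crack.circle_center_right_x_cm + s
    return inside_depth & (x >= left) & (x <= right)


def build_material_field(
    domain: DomainSpec,
    crack: CrackSpec | None,
    bg: MaterialSpec = LIVER,
    filler: MaterialSpec = BLOOD,
    resolution_cm: float | None = None,
) -> MaterialField:
    """Rasterise the phantom onto a regular grid over the full domain.

    ``resolution_cm`` defaults to the ROI export spacing.  It must resolve
    the crack with at least three cells across its thickness.
    """
    res = resolution_cm if resolution_cm is not None else domain.grid_dx_cm
    if crack is not None and res > crack.thickness_cm / 3 + 1e-12:
        raise ValueError(
            f"resolution {res} cm too coarse for a {crack.thickness_cm} cm thick "
            f"crack; need <= {crack.thickness_cm / 3:.4f} cm"
        )
    x0 = 0.0
    nx = round(domain.width_cm / res)
    ny = round(domain.height_cm / res)
    x = x0 + (np.arange(nx) + 0.5) * res
    y = (np.arange(ny) + 0.5) * res
    X, Y = np.meshgrid(x, y)

    density = np.full((ny, nx), bg.density)
    mu = np.full((ny, nx), bg.shear_modulus)
    if crack is not None:
        mask = crack_mask_at(crack, X, Y)
        density[mask] = filler.density
        mu[mask] = filler.shear_modulus
    else:
        mask = np.zeros((ny, nx), dtype=bool)
    return MaterialField(density, mu, mask, res, res, x0, 0.0, domain, crack)


#: Depth rows (cm) at which detected and given right-edge positions are
#: compared, per crack shape.  The shallower cracks use the leading subset.
TABLE_DEPTHS_CM = {
    "straight": [0.208, 0.291, 0.416, 0.917, 1.291, 1.709, 2.083, 2.500, 2.917],
    "curved": [0.208, 0.291, 0.416, 0.917, 1.291, 1.709],
    "slim": [0.208, 0.291, 0.416],
}


def ground_truth_table(crack: CrackSpec, depths_cm=None) -> pd.DataFrame:
    """Analytic right-edge positions at a list of depths.

    Returns a DataFrame with columns ``depth_cm`` and ``given_x_cm``
    (monotone non-increasing in depth for all three crack shapes).
    """
    if depths_cm is None:
        depths_cm = TABLE_DEPTHS_CM[crack.shape]
    depths = list(depths_cm)
    xs = [float(right_edge_x(crack, d)) for d in depths]
    return pd.DataFrame({"depth_cm": depths, "given_x_cm": xs})
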