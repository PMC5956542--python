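"""Speckle-tracking oracles: demodulation, correlation, sub-sample shifts."""

import numpy as np
import pytest

from uswicrack import (
    accumulate,
    correlate_pair,
    demodulate_frame,
    estimate_speckle_size,
    filter_correlations,
    make_fixture,
    peak_displacement,
)
from uswicrack.rf import ImagingSpec
from uswicrack.tracking import TrackingSpec, _odd

F0 = 5e6
FS = 40e6
LAMBDA_US_M = 1540.0 / F0  # 308 um


@pytest.fixture(scope="module")
def iq_frame(speckle_frame):
    return demodulate_frame(speckle_frame, F0, FS)


def test_demodulate_pure_carrier():
    """A pure cosine at f0 basebands to constant magnitude and phase."""
    n = 2048
    rf = np.cos(2 * np.pi * F0 / FS * np.arange(n))[:, None] * np.ones((1, 4))
    iq = demodulate_frame(rf, F0, FS)
    mid = iq[200:-200, 0]
    assert np.abs(mid) == pytest.approx(np.ones(len(mid)), rel=0.02)
    assert np.std(np.angle(mid)) < 1e-3


def test_demodulate_delay_phase():
    """A one-sample RF delay appears as a -2 pi f0/fs baseband phase step."""
    rng = np.random.default_rng(0)
    base = rng.standard_normal(4096)
    rf = np.stack([base[1:-1], base[:-2]], axis=1)  # col 1 delayed by 1 sample
    iq = demodulate_frame(rf, F0, FS)
    dphi = np.angle(np.vdot(iq[500:-500, 0], iq[500:-500, 1]))
    assert dphi == pytest.approx(-2 * np.pi * F0 / FS, abs=0.05)


def test_demodulate_zero_and_validation():
    assert np.all(demodulate_frame(np.zeros((64, 2)), F0, FS) == 0)
    with pytest.raises(ValueError):
        demodulate_frame(np.zeros((64, 2)), 30e6, FS)


def test_envelope_preserved_by_demodulation(speckle_frame, iq_frame):
    from scipy.signal import hilbert

    env_rf = np.abs(hilbert(speckle_frame[300:-300, 30:-30].astype(float), axis=0))
    env_iq = np.abs(iq_frame[300:-300, 30:-30])
    corr = np.corrcoef(env_rf.ravel(), env_iq.ravel())[0, 1]
    assert corr > 0.99


def test_speckle_size_estimates(iq_frame, imaging):
    """Autocovariance widths land near the published speckle dimensions."""
    ax, lat = estimate_speckle_size(iq_frame, imaging)
    assert ax == pytest.approx(0.270, rel=0.15)
    assert lat == pytest.approx(0.586, rel=0.15)
    with pytest.raises(ValueError):
        estimate_speckle_size(np.ones((64, 16)), imaging)


def test_speckle_size_of_white_noise(imaging):
    """Without a PSF the autocorrelation is a delta: widths ~ 1 pitch."""
    rng = np.random.default_rng(2)
    frame = rng.standard_normal((512, 64)) + 1j * rng.standard_normal((512, 64))
    ax, lat = estimate_speckle_size(frame, imaging)
    assert ax < 3 * imaging.axial_pitch_cm * 10
    assert lat < 3 * imaging.beam_pitch_cm * 10


def test_correlation_identical_frames(iq_frame):
    spec = TrackingSpec(grid_step_cm=0.125, search_axial_lags=2,
                        search_lateral_lags=1)
    vol = correlate_pair(iq_frame, iq_frame, spec)
    res = peak_displacement(vol, spec)
    assert np.allclose(res["axial_m"][vol.valid], 0.0, atol=1e-12)
    zero_ax = np.flatnonzero(vol.ax_lags == 0)[0]
    zero_lat = np.flatnonzero(vol.lat_lags == 0)[0]
    assert np.abs(vol.corr[vol.valid][:, zero_ax, zero_lat]) == pytest.approx(
        np.ones(vol.valid.sum()), abs=1e-9
    )


def test_correlation_integer_shift(iq_frame):
    """A 2-sample axial roll is recovered as exactly 2 lags."""
    spec = TrackingSpec(grid_step_cm=0.125, search_axial_lags=4,
                        search_lateral_lags=1)
    shifted = np.roll(iq_frame, 2, axis=0)
    vol = correlate_pair(iq_frame, shifted, spec)
    mag = np.abs(vol.corr[vol.valid])
    ia = np.argmax(mag.reshape(mag.shape[0], -1), axis=1)
    lag_ax = vol.ax_lags[np.unravel_index(ia, mag.shape[1:])[0]]
    assert np.all(lag_ax == 2)


def test_correlation_of_independent_noise():
    rng = np.random.default_rng(9)
    a = rng.standard_normal((512, 64)) + 1j * rng.standard_normal((512, 64))
    b = rng.standard_normal((512, 64)) + 1j * rng.standard_normal((512, 64))
    spec = TrackingSpec(grid_step_cm=0.125, search_axial_lags=2,
                        search_lateral_lags=1)
    imaging = ImagingSpec(n_axial=512, n_beams=64)
    vol = correlate_pair(a, b, spec, imaging)
    assert np.max(np.abs(vol.corr[vol.valid])) < 0.5


def test_filter_correlations_identities(iq_frame):
    spec = TrackingSpec(grid_step_cm=0.025, search_axial_lags=1,
                        search_lateral_lags=1)
    vol = correlate_pair(iq_frame[:600, :60], iq_frame[:600, :60], spec,
                         ImagingSpec(n_axial=600, n_beams=60))
    # spatially constant volume is unchanged by the unit-sum window
    const = vol.corr.copy()
    const[:] = 0.3 + 0.1j
    vol.corr = const
    out = filter_correlations(vol, spec)
    assert np.allclose(out.corr, 0.3 + 0.1j)
    # an impulse spreads but its sum is preserved
    imp = np.zeros_like(const)
    imp[10, 10, 0, 0] = 1.0
    vol.corr = imp
    out = filter_correlations(vol, spec)
    assert out.corr[:, :, 0, 0].real.sum() == pytest.approx(1.0, rel=1e-6)
    assert out.corr[10, 10, 0, 0].real < 1.0


def test_subsample_shifts_recovered(imaging):
    """Uniform sub-wavelength shifts recovered to a few um (phase refinement)."""
    spec = TrackingSpec(grid_step_cm=0.05, search_axial_lags=3,
                        search_lateral_lags=1)
    errors = []
    for delta_um in (9.0, 19.25, 28.9, 45.0, 70.0):
        a, b = make_fixture("shifted_speckle", {"delta_um": delta_um}, seed=11)
        iq_a = demodulate_frame(a, F0, FS)
        iq_b = demodulate_frame(b, F0, FS)
        vol = filter_correlations(correlate_pair(iq_a, iq_b, spec, imaging), spec)
        res = peak_displacement(vol, spec)
        est = np.median(res["axial_m"][res["valid"]])
        errors.append(abs(est - delta_um * 1e-6))
    assert np.mean(errors) < LAMBDA_US_M / 20
    # the lambda/16 shift individually lands within 10%
    assert errors[1] < 0.1 * 19.25e-6
    # the 1.5-sample shift within 3 um
    assert errors[2] < 3e-6


def test_accumulate_properties():
    ngy, ngx = 4, 3
    per_pair = np.full((105, ngy, ngx), 1e-6)
    x = np.arange(ngx) * 0.1
    y = np.arange(ngy) * 0.1
    dm = accumulate(per_pair, x, y)
    assert dm.accumulated.shape == (106, ngy, ngx)
    assert np.all(dm.accumulated[0] == 0)
    assert dm.accumulated[-1] == pytest.approx(np.full((ngy, ngx), 105e-6))
    alt = np.tile(np.array([1.0, -1.0])[:, None, None] * 1e-6, (5, ngy, ngx))[:10]
    dm = accumulate(alt, x, y)
    assert set(np.round(np.unique(dm.accumulated), 12)) <= {0.0, 1e-6}
    with pytest.raises(ValueError):
        accumulate(np.zeros((3, 2, 2)), x, y)


def test_odd_rounding():
    assert _odd(6.0) == 7
    assert _odd(0.2) == 1
    assert _odd(14.2) == 15
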