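"""RF synthesis: PSF spectrum, scatterer handling, speckle statistics."""

import numpy as np
import pytest
from scipy.signal import hilbert
from scipy.stats import kstest

from uswicrack import (
    DomainSpec,
    WaveField,
    displace_scatterers,
    envelope_snr,
    make_psf,
    seed_scatterers,
    synthesize_frame,
)
from uswicrack.rf import ImagingSpec, PSFSpec, ScattererSet

RAYLEIGH_SNR = np.sqrt(np.pi / (4 - np.pi))  # ~1.913


def test_imaging_geometry(imaging):
    assert imaging.axial_pitch_cm * 1e4 == pytest.approx(19.25)
    assert imaging.n_axial * imaging.axial_pitch_cm == pytest.approx(5.0, abs=0.01)
    assert imaging.beam_pitch_cm * 1e4 == pytest.approx(97.65625)


def test_scatterer_density_and_determinism(imaging):
    sset = seed_scatterers(((0.0, 2.5), (0.0, 5.0)), 6.0, seed=3)
    lam_cm = imaging.psf.wavelength_m * 100
    expected = 36.0 * 12.5 / lam_cm**2  # 6 per wavelength along each axis
    assert abs(len(sset) - expected) < 3 * np.sqrt(expected)
    again = seed_scatterers(((0.0, 2.5), (0.0, 5.0)), 6.0, seed=3)
    assert np.array_equal(sset.x_cm, again.x_cm)
    assert np.array_equal(sset.amplitude, again.amplitude)
    assert len(seed_scatterers(((1.0, 1.0), (0.0, 5.0)), 6.0, seed=3)) == 0
    with pytest.raises(ValueError):
        seed_scatterers(((0.0, 1.0), (0.0, 1.0)), -1.0)


def test_psf_spectrum(psf):
    """Axial spectrum peaks at 5 MHz with a -6 dB width of 2.5 MHz."""
    spec = psf.spec
    n = 4096
    S = np.abs(np.fft.rfft(psf.axial, n))
    f = np.fft.rfftfreq(n, 1.0 / spec.fs_hz)
    peak = int(np.argmax(S))
    assert f[peak] == pytest.approx(5e6, abs=f[1])
    half = S[peak] / 2  # -6 dB in amplitude
    above = f[S >= half]
    assert above.max() - above.min() == pytest.approx(2.5e6, rel=0.02)


def test_psf_lateral_fwhm(psf):
    from uswicrack.tracking import _fwhm

    pitch_m = 2.5e-2 / 256
    assert _fwhm(psf.lateral, pitch_m) == pytest.approx(0.5e-3, rel=0.02)


def _uniform_field(value_m, nx=8, ny=8, nt=2):
    u = np.full((nx, ny, nt), value_m, dtype=np.float64)
    u[:, :, 0] = 0
    return WaveField(u, 0.35, 0.7, 0.0, 0.0, 2e-4, DomainSpec())


def test_displace_scatterers_uniform_and_zero():
    sset = ScattererSet(np.array([1.0, 2.0]), np.array([2.0, 4.0]), np.ones(2))
    wave = _uniform_field(10e-6)
    moved = displace_scatterers(sset, wave, 1)
    assert moved.y_cm == pytest.approx(sset.y_cm + 10e-4)
    still = displace_scatterers(sset, wave, 0)
    assert np.array_equal(still.y_cm, sset.y_cm)
    with pytest.raises(IndexError):
        displace_scatterers(sset, wave, 5)


def test_displace_scatterers_linear_ramp():
    """u = k x reproduces the exact per-scatterer shift via interpolation."""
    nx, ny = 64, 16
    dx = 2.5 / nx
    dy = 5.0 / ny
    x_cm = (np.arange(nx) + 0.5) * dx
    k = 4e-4  # per cm, displacement in m
    u = np.broadcast_to((k * x_cm)[:, None, None], (nx, ny, 2)).copy()
    wave = WaveField(u, dx, dy, 0.0, 0.0, 2e-4, DomainSpec())
    rng = np.random.default_rng(5)
    sx = rng.uniform(0.2, 2.3, 200)
    sy = rng.uniform(0.2, 4.8, 200)
    sset = ScattererSet(sx, sy, np.ones(200))
    moved = displace_scatterers(sset, wave, 1)
    assert moved.y_cm - sy == pytest.approx(k * sx * 100, abs=1e-6)


def test_single_scatterer_peak_position(imaging, psf):
    """A scatterer at 2.5 cm depth echoes at sample round(y / pitch)."""
    sset = ScattererSet(np.array([1.25]), np.array([2.5]), np.array([1.0]))
    frame = synthesize_frame(sset, psf, imaging)
    env = np.abs(hilbert(frame.astype(float), axis=0))
    peak = np.unravel_index(np.argmax(env), env.shape)
    assert abs(peak[0] - round(2.5 / imaging.axial_pitch_cm)) <= 1
    assert abs(peak[1] - 1.25 / imaging.beam_pitch_cm) <= 1


def test_frame_linearity(imaging, psf, rng):
    sx = rng.uniform(0, 2.5, 50)
    sy = rng.uniform(0, 5.0, 50)
    amp = rng.standard_normal(50)
    a = synthesize_frame(ScattererSet(sx, sy, amp), psf, imaging)
    b = synthesize_frame(ScattererSet(sx, sy, 2 * amp), psf, imaging)
    assert np.allclose(b, 2 * a, atol=1e-7)
    # superposition of two disjoint sets
    c = synthesize_frame(
        ScattererSet(sx[:25], sy[:25], amp[:25]), psf, imaging
    ) + synthesize_frame(ScattererSet(sx[25:], sy[25:], amp[25:]), psf, imaging)
    assert np.allclose(c, a, atol=1e-6)


def test_empty_set_gives_zero_frame(imaging, psf):
    frame = synthesize_frame(
        ScattererSet(np.empty(0), np.empty(0), np.empty(0)), psf, imaging
    )
    assert frame.shape == (2596, 256)
    assert np.all(frame == 0)


def test_envelope_snr_values(speckle_frame):
    """Full-density speckle lands near the Rayleigh mean/std ratio."""
    snr = envelope_snr(speckle_frame)
    assert 1.8 <= snr <= 2.4
    with pytest.raises(ValueError):
        envelope_snr(np.zeros((64, 8)))


def test_rayleigh_envelope_statistics(speckle_frame, imaging, psf):
    """Fully developed speckle: envelope passes a KS test against Rayleigh.

    Samples are taken one per speckle cell (stride of the correlation
    lengths) so they are effectively independent, over two scatterer
    realizations to exceed 1e4 samples.
    """
    frames = [speckle_frame]
    other = seed_scatterers(((0.0, 2.5), (0.0, 5.0)), 6.0, seed=8, psf=imaging.psf)
    frames.append(synthesize_frame(other, psf, imaging))
    subs = []
    for fr in frames:
        env = np.abs(hilbert(fr[200:-200, 20:-20].astype(float), axis=0))
        subs.append(env[::14, ::6].ravel())
    sample = np.concatenate(subs)
    assert sample.size >= 10_000
    sigma = np.sqrt(np.mean(sample**2) / 2)
    stat = kstest(sample / sigma, "rayleigh")
    assert stat.pvalue > 0.01


def test_synthesis_psf_validates():
    with pytest.raises(ValueError):
        PSFSpec(f0_hz=30e6)  # above Nyquist
    with pytest.raises(ValueError):
        PSFSpec(fractional_bandwidth=-0.5)
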