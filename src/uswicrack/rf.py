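"""Ultrasound RF speckle synthesis via the 2-D linear scattering model.

Each RF frame is the convolution of a separable point-spread function (PSF)
with a random scattering function: point scatterers are deposited onto the
RF sample grid (amplitude-weighted bilinear splatting) and the result is
convolved with an axial modulated-Gaussian pulse and a lateral Gaussian
beam profile.  Scatterers ride on the simulated shear-wave displacement
field between frames, so consecutive frames carry the tissue motion as
sub-wavelength echo delays.

Pulse-echo geometry: a scatterer at depth ``y`` echoes at time ``2 y / c``,
so one RF sample at sampling frequency ``fs`` spans ``c / (2 fs)`` of depth
(19.25 um at 40 MHz / 1540 m/s), and an axial displacement ``dy`` delays
the echo by ``2 dy / c``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal import hilbert

from .phantom import CM
from .wavesim import WaveField

__all__ = [
    "PSFSpec", "ImagingSpec", "ScattererSet", "PSF", "RFStack",
    "seed_scatterers", "make_psf", "displace_scatterers",
    "synthesize_frame", "synthesize_stack", "envelope_snr",
]


@dataclass(frozen=True)
class PSFSpec:
    """Transducer point-spread function parameters.

    ``fractional_bandwidth`` is the two-sided -6 dB (half-power) spectral
    width of the axial pulse relative to the centre frequency.
    """

    f0_hz: float = 5e6
    fractional_bandwidth: float = 0.5
    lateral_fwhm_m: float = 0.5e-3
    fs_hz: float = 40e6
    c_us: float = 1540.0          # speed of sound, m/s

    def __post_init__(self) -> None:
        if not 0 < self.f0_hz < self.fs_hz / 2:
            raise ValueError("need 0 < f0 < fs/2")
        if min(self.fractional_bandwidth, self.lateral_fwhm_m, self.c_us) <= 0:
            raise ValueError("PSF parameters must be positive")

    @property
    def wavelength_m(self) -> float:
        return self.c_us / self.f0_hz

    @property
    def axial_pitch_m(self) -> float:
        """Depth per RF sample, c / (2 fs)."""
        return self.c_us / (2.0 * self.fs_hz)

    @property
    def sigma_t_s(self) -> float:
        """Gaussian envelope sigma in time, from the -6 dB spectral width."""
        width_hz = self.fractional_bandwidth * self.f0_hz
        sigma_f = width_hz / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return 1.0 / (2.0 * np.pi * sigma_f)


@dataclass(frozen=True)
class ImagingSpec:
    """RF frame geometry: 5.0 cm (axial) x 2.5 cm (lateral) field of view."""

    n_axial: int = 2596
    n_beams: int = 256
    axial_extent_cm: float = 5.0
    lateral_extent_cm: float = 2.5
    psf: PSFSpec = PSFSpec()

    @property
    def beam_pitch_cm(self) -> float:
        return self.lateral_extent_cm / self.n_beams

    @property
    def axial_pitch_cm(self) -> float:
        return self.psf.axial_pitch_m / CM

    def beam_x_cm(self) -> np.ndarray:
        return (np.arange(self.n_beams) + 0.5) * self.beam_pitch_cm

    def sample_y_cm(self) -> np.ndarray:
        return (np.arange(self.n_axial) + 0.5) * self.axial_pitch_cm


@dataclass
class ScattererSet:
    """Random point scatterers: reference positions (cm) and amplitudes."""

    x_cm: np.ndarray
    y_cm: np.ndarray
    amplitude: np.ndarray
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.x_cm)


@dataclass
class PSF:
    """Separable PSF kernels sampled on the RF grid."""

    axial: np.ndarray     # modulated pulse, odd length, RF samples
    lateral: np.ndarray   # Gaussian beam profile, odd length, beams
    spec: PSFSpec


@dataclass
class RFStack:
    """Per-frame RF images, ``frames[t]`` of shape (n_axial, n_beams)."""

    frames: np.ndarray    # (n_frames, n_axial, n_beams), float32
    imaging: ImagingSpec
    frame_interval_s: float = 0.2e-3

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def seed_scatterers(
    region_cm: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 2.5), (0.0, 5.0)),
    density_per_wavelength: float = 6.0,
    seed: int | None = None,
    psf: PSFSpec = PSFSpec(),
) -> ScattererSet:
    """Draw a random scatterer field over ``((x0, x1), (y0, y1))`` in cm.

    ``density_per_wavelength`` scatterers per ultrasound wavelength
    (lambda = c/f0 = 0.308 mm at 5 MHz) along each dimension, i.e.
    ``density**2`` per lambda^2 of area.  The default 6 puts ~45
    scatterers in each resolution cell, enough for fully developed
    (Rayleigh) speckle.  The count is Poisson, positions uniform,
    amplitudes i.i.d. standard normal.
    """
    if density_per_wavelength <= 0:
        raise ValueError("scatterer density must be positive")
    (x0, x1), (y0, y1) = region_cm
    area_cm2 = (x1 - x0) * (y1 - y0)
    if area_cm2 <= 0:
        return ScattererSet(np.empty(0), np.empty(0), np.empty(0), seed)
    lam_cm = psf.wavelength_m / CM
    expected = density_per_wavelength**2 * area_cm2 / lam_cm**2
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(expected))
    return ScattererSet(
        x_cm=rng.uniform(x0, x1, n),
        y_cm=rng.uniform(y0, y1, n),
        amplitude=rng.standard_normal(n),
        seed=seed,
    )


def make_psf(spec: PSFSpec = PSFSpec(), truncate: float = 1e-3) -> PSF:
    """Build the separable PSF kernels.

    Axial: cosine at ``f0`` under a Gaussian envelope whose -6 dB spectral
    width is ``fractional_bandwidth * f0``; the carrier is sampled in
    pulse-echo depth units (spatial frequency ``2 f0 / c``).  Lateral:
    Gaussian with the specified FWHM.  Kernels are truncated where the
    envelope falls below ``truncate`` of its peak and have odd length.
    """
    sigma_t = spec.sigma_t_s
    half_t = int(np.ceil(sigma_t * np.sqrt(2.0 * np.log(1.0 / truncate)) * spec.fs_hz))
    t = np.arange(-half_t, half_t + 1) / spec.fs_hz
    axial = np.cos(2.0 * np.pi * spec.f0_hz * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))

    sigma_x = spec.lateral_fwhm_m / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    pitch = 2.5e-2 / 256  # default beam pitch; lateral kernel is in beams
    half_x = int(np.ceil(sigma_x * np.sqrt(2.0 * np.log(1.0 / truncate)) / pitch))
    x = np.arange(-half_x, half_x + 1) * pitch
    lateral = np.exp(-(x**2) / (2.0 * sigma_x**2))
    return PSF(axial.astype(np.float64), lateral.astype(np.float64), spec)


def displace_scatterers(
    sset: ScattererSet, wave: WaveField, frame_index: int
) -> ScattererSet:
    """Shift scatterers axially by the displacement field of one frame.

    ``y_deformed = y_ref + u(x_ref, y_ref, t_frame)`` with bilinear
    interpolation of the nodal field; lateral positions are unchanged
    (the solver tracks the axial component only).  Scatterers outside the
    wave grid are clamped to the nearest cell with a warning.
    """
    if not 0 <= frame_index < wave.u.shape[2]:
        raise IndexError(f"frame index {frame_index} out of range")
    if len(sset) == 0:
        return sset
    xg, yg = wave.x_cm, wave.y_cm
    fx = (sset.x_cm - xg[0]) / wave.dx_cm
    fy = (sset.y_cm - yg[0]) / wave.dy_cm
    out = (fx < -0.5) | (fx > len(xg) - 0.5) | (fy < -0.5) | (fy > len(yg) - 0.5)
    if np.any(out):
        warnings.warn(f"{int(out.sum())} scatterers outside the wave grid; clamped")
    fx = np.clip(fx, 0.0, len(xg) - 1.0)
    fy = np.clip(fy, 0.0, len(yg) - 1.0)
    ix = np.minimum(fx.astype(int), len(xg) - 2)
    iy = np.minimum(fy.astype(int), len(yg) - 2)
    wx = fx - ix
    wy = fy - iy
    u = wave.u[:, :, frame_index]
    disp_m = (
        u[ix, iy] * (1 - wx) * (1 - wy)
        + u[ix + 1, iy] * wx * (1 - wy)
        + u[ix, iy + 1] * (1 - wx) * wy
        + u[ix + 1, iy + 1] * wx * wy
    )
    return ScattererSet(sset.x_cm, sset.y_cm + disp_m / CM, sset.amplitude, sset.seed)


def synthesize_frame(
    sset: ScattererSet, psf: PSF, imaging: ImagingSpec = ImagingSpec()
) -> np.ndarray:
    """One RF frame: bilinear scatterer splatting followed by PSF convolution.

    Returns a float32 array of shape ``(n_axial, n_beams)``.  An empty
    scatterer set yields a zero frame.  Synthesis is linear in the
    amplitudes and shift-equivariant to sub-sample accuracy.
    """
    grid = np.zeros((imaging.n_axial, imaging.n_beams), dtype=np.float64)
    if len(sset) > 0:
        fy = sset.y_cm / imaging.axial_pitch_cm - 0.5
        fx = sset.x_cm / imaging.beam_pitch_cm - 0.5
        inside = (
            (fy > -1) & (fy < imaging.n_axial) & (fx > -1) & (fx < imaging.n_beams)
        )
        fy, fx, amp = fy[inside], fx[inside], sset.amplitude[inside]
        iy = np.floor(fy).astype(int)
        ix = np.floor(fx).astype(int)
        wy = fy - iy
        wx = fx - ix
        flat_n = imaging.n_axial * imaging.n_beams
        for dy, dx, w in (
            (0, 0, (1 - wy) * (1 - wx)),
            (1, 0, wy * (1 - wx)),
            (0, 1, (1 - wy) * wx),
            (1, 1, wy * wx),
        ):
            yy = iy + dy
            xx = ix + dx
            ok = (yy >= 0) & (yy < imaging.n_axial) & (xx >= 0) & (xx < imaging.n_beams)
            grid += np.bincount(
                yy[ok] * imaging.n_beams + xx[ok],
                weights=amp[ok] * w[ok],
                minlength=flat_n,
            ).reshape(grid.shape)
    grid = convolve1d(grid, psf.axial, axis=0, mode="constant")
    grid = convolve1d(grid, psf.lateral, axis=1, mode="constant")
    return grid.astype(np.float32)


def synthesize_stack(
    wave: WaveField,
    seed: int | None = None,
    imaging: ImagingSpec = ImagingSpec(),
    density_per_wavelength: float = 6.0,
) -> RFStack:
    """RF movie of the deforming phantom: one frame per wave-field frame."""
    psf = make_psf(imaging.psf)
    region = (
        (wave.x0_cm, wave.x0_cm + wave.u.shape[0] * wave.dx_cm),
        (wave.y0_cm, wave.y0_cm + wave.u.shape[1] * wave.dy_cm),
    )
    sset = seed_scatterers(region, density_per_wavelength, seed, imaging.psf)
    n_frames = wave.u.shape[2]
    frames = np.empty((n_frames, imaging.n_axial, imaging.n_beams), dtype=np.float32)
    for k in range(n_frames):
        frames[k] = synthesize_frame(displace_scatterers(sset, wave, k), psf, imaging)
    return RFStack(frames, imaging, wave.frame_interval_s)


def envelope_snr(frame: np.ndarray, central_fraction: float = 0.5) -> float:
    """Mean/std ratio of the envelope over a central window.

    For fully developed (Rayleigh) speckle the theoretical value is
    ``sqrt(pi / (4 - pi)) ~ 1.91``.
    """
    if np.max(np.abs(frame)) == 0:
        raise ValueError("cannot compute envelope SNR of an all-zero frame")
    env = np.abs(hilbert(np.asarray(frame, dtype=np.float64), axis=0))
    ny, nx = env.shape
    my = int(ny * (1 - central_fraction) / 2)
    mx = int(nx * (1 - central_fraction) / 2)
    win = env[my:ny - my, mx:nx - mx]
    sd = float(win.std())
    if sd == 0:
        raise ValueError("constant envelope: SNR undefined")
    return float(win.mean()) / sd
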