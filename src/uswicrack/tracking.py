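"""Phase-sensitive 2-D correlation speckle tracking.

Displacement between consecutive RF frames is estimated from the complex
normalized cross-correlation of their baseband (IQ) signals: the integer
correlation peak gives the coarse lag, and the phase of the complex
correlation at the peak refines the axial estimate to a small fraction of
the ultrasound wavelength (phase zero-crossing refinement).  Correlation
functions of adjacent estimation points are smoothed with a separable
Hanning window before the peak search to trade a little resolution for a
large variance reduction.  Frame-to-frame axial displacements are then
accumulated at fixed grid points to recover the total motion relative to
the first frame.

Phase-to-distance conversion uses the pulse-echo factor: an axial motion
``dy`` delays the echo by ``2 dy / c``, i.e. a correlation phase
``phi = 4 pi f0 dy / c``, so ``dy = phi c / (4 pi f0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal import butter, sosfiltfilt

from .phantom import CM, DomainSpec
from .rf import ImagingSpec, RFStack
from .wavesim import WaveField

__all__ = [
    "TrackingSpec", "CorrelationVolume", "DisplacementMap",
    "demodulate", "demodulate_frame", "estimate_speckle_size",
    "correlate_pair", "filter_correlations", "peak_displacement",
    "accumulate", "track_stack",
]


def _odd(n: float) -> int:
    """Round to the nearest odd integer >= 1."""
    k = max(1, int(round(n)))
    return k if k % 2 == 1 else k + 1


@dataclass(frozen=True)
class TrackingSpec:
    """Kernel, search and filter geometry for the correlation tracker.

    Lengths are in mm and are rounded to whole RF samples / beams (odd
    counts) when applied.  The kernel defaults to the speckle size; the
    search region is the total window width; the Hanning filter sizes are
    the smoothing extents over the estimation grid.  ``search_axial_lags``
    / ``search_lateral_lags`` directly cap the half-width of the lag
    search when set (the frame-to-frame motions of the shear-wave movie
    are sub-sample, so a tight cap loses nothing).
    """

    kernel_axial_mm: float = 0.270
    kernel_lateral_mm: float = 0.586
    search_mm: float = 0.781
    filter_lateral_mm: float = 0.781
    filter_axial_mm: float = 0.308
    grid_step_cm: float = 0.0125
    search_axial_lags: int | None = None
    search_lateral_lags: int | None = None
    #: estimates whose filtered peak correlation magnitude falls below this
    #: are treated as unreliable and zeroed (decorrelated speckle)
    min_correlation: float = 0.0

    def kernel_samples(self, imaging: ImagingSpec) -> tuple[int, int]:
        ka = _odd(self.kernel_axial_mm / (imaging.axial_pitch_cm * 10))
        kl = _odd(self.kernel_lateral_mm / (imaging.beam_pitch_cm * 10))
        return ka, kl

    def search_lags(self, imaging: ImagingSpec) -> tuple[int, int]:
        half_mm = self.search_mm / 2.0
        la = int(round(half_mm / (imaging.axial_pitch_cm * 10)))
        ll = int(round(half_mm / (imaging.beam_pitch_cm * 10)))
        if self.search_axial_lags is not None:
            la = min(la, self.search_axial_lags)
        if self.search_lateral_lags is not None:
            ll = min(ll, self.search_lateral_lags)
        return max(la, 1), max(ll, 1)


@dataclass
class CorrelationVolume:
    """Complex normalized cross-correlation per grid point and lag.

    ``corr[iy, ix, a, l]`` is the correlation at grid point (iy, ix) for
    axial lag ``ax_lags[a]`` (RF samples) and lateral lag ``lat_lags[l]``
    (beams).  ``valid`` flags grid points whose kernel+search window fits
    inside the frame.
    """

    corr: np.ndarray
    ax_lags: np.ndarray
    lat_lags: np.ndarray
    grid_iy: np.ndarray     # RF sample index of each grid row centre
    grid_ix: np.ndarray     # beam index of each grid column centre
    valid: np.ndarray
    imaging: ImagingSpec


@dataclass
class DisplacementMap:
    """Tracked axial displacement on the estimation grid.

    ``accumulated[k]`` is the total axial displacement (m) of frame ``k``
    relative to frame 0; ``per_pair[j]`` the frame ``j`` -> ``j+1``
    increment.  ``quality`` holds the mean peak correlation magnitude per
    pair.
    """

    accumulated: np.ndarray      # (n_frames, ngy, ngx), metres
    per_pair: np.ndarray         # (n_frames-1, ngy, ngx), metres
    lateral_per_pair: np.ndarray | None
    x_cm: np.ndarray             # (ngx,)
    y_cm: np.ndarray             # (ngy,)
    frame_interval_s: float
    quality: np.ndarray | None = None

    def as_wavefield(self, domain: DomainSpec | None = None) -> WaveField:
        """View the accumulated movie as a WaveField (x, y, t axis order)."""
        u = np.transpose(self.accumulated, (2, 1, 0))
        dx = float(self.x_cm[1] - self.x_cm[0])
        dy = float(self.y_cm[1] - self.y_cm[0])
        return WaveField(
            u, dx, dy, float(self.x_cm[0]) - dx / 2, float(self.y_cm[0]) - dy / 2,
            self.frame_interval_s, domain or DomainSpec(),
        )


def demodulate_frame(
    rf: np.ndarray, f0_hz: float = 5e6, fs_hz: float = 40e6
) -> np.ndarray:
    """Complex baseband of one RF frame (axial axis 0).

    Mixes each A-line down by the carrier and applies a zero-phase
    low-pass at ``f0`` (5th-order Butterworth, forward-backward).  The
    factor 2 restores the analytic-signal amplitude so ``|IQ|`` matches
    the RF envelope up to filter ripple.
    """
    if not 0 < f0_hz < fs_hz / 2:
        raise ValueError("need 0 < f0 < fs/2")
    rf = np.asarray(rf, dtype=np.float64)
    n = np.arange(rf.shape[0])
    mixer = np.exp(-2j * np.pi * f0_hz / fs_hz * n)
    mixed = 2.0 * rf * mixer[:, None]
    sos = butter(5, f0_hz / (fs_hz / 2), output="sos")
    iq = sosfiltfilt(sos, mixed.real, axis=0) + 1j * sosfiltfilt(sos, mixed.imag, axis=0)
    return iq.astype(np.complex64)


def demodulate(stack: RFStack) -> np.ndarray:
    """Baseband all frames of an RF stack -> complex64 (n_frames, n_axial, n_beams)."""
    psf = stack.imaging.psf
    out = np.empty(stack.frames.shape, dtype=np.complex64)
    for k in range(stack.n_frames):
        out[k] = demodulate_frame(stack.frames[k], psf.f0_hz, psf.fs_hz)
    return out


def _fwhm(profile: np.ndarray, pitch: float) -> float:
    """Full width at half maximum of a peaked symmetric profile (linear interp)."""
    p = profile / profile.max()
    c = int(np.argmax(p))
    half = 0.5

    def cross(side: int) -> float:
        i = c
        while 0 < i < len(p) - 1 and p[i + side] > half:
            i += side
        j = i + side
        if j < 0 or j >= len(p):
            return abs(i - c)
        return abs(i - c) + (p[i] - half) / (p[i] - p[j])

    return (cross(+1) + cross(-1)) * pitch


def estimate_speckle_size(
    iq_frame: np.ndarray, imaging: ImagingSpec = ImagingSpec()
) -> tuple[float, float]:
    """Speckle-cell size (axial, lateral; mm) of a baseband frame.

    Computed as the FWHM, per axis, of the squared magnitude of the
    normalized 2-D autocorrelation of the complex baseband — the envelope
    autocovariance width, the usual definition of the speckle cell.
    Raises on a degenerate (constant) frame.
    """
    f = np.asarray(iq_frame)
    f = f - f.mean()
    if np.max(np.abs(f)) == 0:
        raise ValueError("degenerate frame: speckle size undefined")
    ny, nx = f.shape
    spec = np.fft.fft2(f, s=(2 * ny, 2 * nx))
    ac = np.fft.ifft2(np.abs(spec) ** 2)
    acm = np.abs(ac) ** 2
    ax_prof = np.fft.fftshift(acm[:, 0])
    lat_prof = np.fft.fftshift(acm[0, :])
    ax = _fwhm(ax_prof, imaging.axial_pitch_cm * 10)
    lat = _fwhm(lat_prof, imaging.beam_pitch_cm * 10)
    return ax, lat


def _integral_image(img: np.ndarray) -> np.ndarray:
    s = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=img.dtype)
    np.cumsum(img, axis=0, out=s[1:, 1:])
    np.cumsum(s[1:, 1:], axis=1, out=s[1:, 1:])
    return s


def _window_sums(S: np.ndarray, iy: np.ndarray, ix: np.ndarray,
                 ka: int, kl: int) -> np.ndarray:
    """Kernel-window sums at grid centres from an integral image."""
    ny, nx = S.shape[0] - 1, S.shape[1] - 1
    ha, hl = ka // 2, kl // 2
    y0 = np.clip(iy - ha, 0, ny)
    y1 = np.clip(iy + ha + 1, 0, ny)
    x0 = np.clip(ix - hl, 0, nx)
    x1 = np.clip(ix + hl + 1, 0, nx)
    return (S[np.ix_(y1, x1)] - S[np.ix_(y0, x1)]
            - S[np.ix_(y1, x0)] + S[np.ix_(y0, x0)])


def _default_grid(imaging: ImagingSpec, step_cm: float) -> tuple[np.ndarray, np.ndarray]:
    """Estimation-grid centres as RF sample / beam indices.

    The grid lives on the RF lattice itself — every beam laterally and
    every ``round(step / axial_pitch)`` samples axially — so each
    estimate carries its exact physical coordinate.  Snapping a nominal
    grid to the nearest beam instead would mislabel positions by up to
    half a beam pitch (~0.005 cm), a visible bias at the deep, small-x
    end of the crack contour.
    """
    stride = max(1, round(step_cm / imaging.axial_pitch_cm))
    iy = np.arange(0, imaging.n_axial, stride)
    ix = np.arange(imaging.n_beams)
    return iy, ix


def correlate_pair(
    iq_a: np.ndarray,
    iq_b: np.ndarray,
    spec: TrackingSpec = TrackingSpec(),
    imaging: ImagingSpec = ImagingSpec(),
) -> CorrelationVolume:
    """Complex normalized cross-correlation over the lag search window.

    For every estimation grid point, correlates a kernel around the point
    in frame ``a`` against the laterally/axially lagged kernel in frame
    ``b``; normalization uses the local energies, so identical frames give
    exactly 1 at zero lag.  Grid points whose window leaves the frame are
    flagged invalid.
    """
    if iq_a.shape != iq_b.shape:
        raise ValueError("frames must share geometry")
    a = np.asarray(iq_a, dtype=np.complex128)
    b = np.asarray(iq_b, dtype=np.complex128)
    ka, kl = spec.kernel_samples(imaging)
    la, ll = spec.search_lags(imaging)
    iy, ix = _default_grid(imaging, spec.grid_step_cm)
    if ka > a.shape[0] or kl > a.shape[1]:
        raise ValueError("kernel exceeds frame bounds")

    S_aa = _integral_image((a * a.conj()).real)
    S_bb = _integral_image((b * b.conj()).real)
    e_a = _window_sums(S_aa, iy, ix, ka, kl)

    ax_lags = np.arange(-la, la + 1)
    lat_lags = np.arange(-ll, ll + 1)
    corr = np.zeros((len(iy), len(ix), len(ax_lags), len(lat_lags)),
                    dtype=np.complex128)
    eps = 1e-30
    for ia, da in enumerate(ax_lags):
        for il, dl in enumerate(lat_lags):
            b_s = np.roll(b, (-da, -dl), axis=(0, 1))
            S_ab = _integral_image(a * b_s.conj())
            num = _window_sums(S_ab, iy, ix, ka, kl)
            e_b = _window_sums(S_bb, iy + da, ix + dl, ka, kl)
            corr[:, :, ia, il] = num / np.sqrt(np.maximum(e_a * e_b, eps))

    ha, hl = ka // 2, kl // 2
    valid = (
        ((iy - ha - la) >= 0)[:, None] & ((iy + ha + la) < a.shape[0])[:, None]
        & ((ix - hl - ll) >= 0)[None, :] & ((ix + hl + ll) < a.shape[1])[None, :]
    )
    return CorrelationVolume(corr, ax_lags, lat_lags, iy, ix, valid, imaging)


def filter_correlations(
    vol: CorrelationVolume, spec: TrackingSpec = TrackingSpec()
) -> CorrelationVolume:
    """Smooth the correlation functions across neighbouring grid points.

    For each lag, the field of complex correlation values over the
    estimation grid is convolved with a separable unit-sum Hanning window
    (sizes from ``filter_axial_mm`` x ``filter_lateral_mm`` converted to
    grid steps).  The lag axes are untouched, so a spatially constant
    volume passes through unchanged.
    """
    ax_step_mm = (
        float(vol.grid_iy[1] - vol.grid_iy[0]) * vol.imaging.axial_pitch_cm * 10
        if len(vol.grid_iy) > 1 else spec.grid_step_cm * 10
    )
    lat_step_mm = (
        float(vol.grid_ix[1] - vol.grid_ix[0]) * vol.imaging.beam_pitch_cm * 10
        if len(vol.grid_ix) > 1 else spec.grid_step_cm * 10
    )
    na = _odd(spec.filter_axial_mm / ax_step_mm)
    nl = _odd(spec.filter_lateral_mm / lat_step_mm)
    if na > vol.corr.shape[0] or nl > vol.corr.shape[1]:
        raise ValueError("Hanning filter window larger than the estimation grid")
    out = vol.corr
    for axis, n in ((0, na), (1, nl)):
        if n > 1:
            w = np.hanning(n + 2)[1:-1]
            w /= w.sum()
            out = (convolve1d(out.real, w, axis=axis, mode="nearest")
                   + 1j * convolve1d(out.imag, w, axis=axis, mode="nearest"))
    return CorrelationVolume(out, vol.ax_lags, vol.lat_lags,
                             vol.grid_iy, vol.grid_ix, vol.valid, vol.imaging)


def peak_displacement(
    vol: CorrelationVolume,
    spec: TrackingSpec = TrackingSpec(),
) -> dict:
    """Displacement per grid point from the correlation peak and its phase.

    The integer lag of the maximum correlation magnitude gives the coarse
    estimate; the axial estimate is refined with the phase zero-crossing:
    the echo delay is ``lag/fs`` plus the wrapped residual of
    ``phase - 2 pi f0 lag / fs``, converted to distance by ``c/2``.
    Returns axial/lateral displacement maps (m), peak correlation
    magnitude, and flags for border peaks and phase-wrap risk.
    """
    psf = vol.imaging.psf
    mag = np.abs(vol.corr)
    flat = mag.reshape(mag.shape[0], mag.shape[1], -1)
    idx = np.argmax(flat, axis=2)
    ia, il = np.unravel_index(idx, mag.shape[2:])
    gy, gx = np.meshgrid(np.arange(mag.shape[0]), np.arange(mag.shape[1]),
                         indexing="ij")
    peak = vol.corr[gy, gx, ia, il]
    lag_ax = vol.ax_lags[ia]
    lag_lat = vol.lat_lags[il]

    phase = np.angle(peak)
    expected = 2.0 * np.pi * psf.f0_hz / psf.fs_hz * lag_ax
    resid = np.angle(np.exp(1j * (phase - expected)))
    tau = lag_ax / psf.fs_hz + resid / (2.0 * np.pi * psf.f0_hz)
    axial_m = tau * psf.c_us / 2.0
    lateral_m = lag_lat * (vol.imaging.beam_pitch_cm * CM)

    border = (
        (ia == 0) | (ia == len(vol.ax_lags) - 1)
        | (il == 0) | (il == len(vol.lat_lags) - 1)
    )
    if len(vol.ax_lags) == 1:
        border = (il == 0) | (il == len(vol.lat_lags) - 1)
    wrap_risk = np.abs(resid) > np.pi / 2
    return {
        "axial_m": axial_m,
        "lateral_m": lateral_m,
        "peak_corr": mag[gy, gx, ia, il],
        "border_flag": border & vol.valid,
        "wrap_flag": wrap_risk & vol.valid,
        "valid": vol.valid,
    }


def accumulate(
    per_pair: np.ndarray,
    x_cm: np.ndarray,
    y_cm: np.ndarray,
    frame_interval_s: float = 0.2e-3,
    lateral_per_pair: np.ndarray | None = None,
    quality: np.ndarray | None = None,
) -> DisplacementMap:
    """Cumulative-sum the frame-pair estimates into total displacement.

    Accumulation is Eulerian: sums are taken at fixed grid points.  The
    per-frame motions here (tens of um) are far below the estimation-grid
    spacing, so material-point advection would change the sums negligibly.
    Frame 0 of the accumulated movie is identically zero.
    """
    per_pair = np.asarray(per_pair)
    if per_pair.ndim != 3 or per_pair.shape[1] != len(y_cm) or per_pair.shape[2] != len(x_cm):
        raise ValueError("per-pair stack inconsistent with the estimation grid")
    acc = np.zeros((per_pair.shape[0] + 1,) + per_pair.shape[1:], dtype=per_pair.dtype)
    np.cumsum(per_pair, axis=0, out=acc[1:])
    return DisplacementMap(acc, per_pair, lateral_per_pair,
                           np.asarray(x_cm), np.asarray(y_cm),
                           frame_interval_s, quality)


def track_stack(
    stack: RFStack,
    spec: TrackingSpec = TrackingSpec(),
    progress: bool = False,
) -> DisplacementMap:
    """Track all consecutive frame pairs of an RF stack.

    Frames are basebanded on the fly (only two IQ frames are held at a
    time), correlated, Hanning-filtered, peak-picked, and the axial
    increments accumulated to the total displacement relative to frame 0.
    """
    imaging = stack.imaging
    psf = imaging.psf
    iy, ix = _default_grid(imaging, spec.grid_step_cm)
    n_pairs = stack.n_frames - 1
    if n_pairs < 1:
        raise ValueError("need at least two frames to track")
    per_pair = np.zeros((n_pairs, len(iy), len(ix)), dtype=np.float32)
    lat_pair = np.zeros_like(per_pair)
    quality = np.zeros(n_pairs, dtype=np.float32)

    iq_prev = demodulate_frame(stack.frames[0], psf.f0_hz, psf.fs_hz)
    for j in range(n_pairs):
        iq_next = demodulate_frame(stack.frames[j + 1], psf.f0_hz, psf.fs_hz)
        vol = correlate_pair(iq_prev, iq_next, spec, imaging)
        vol = filter_correlations(vol, spec)
        res = peak_displacement(vol, spec)
        # border grid points see wrapped-around kernels; decorrelated
        # estimates carry mostly noise — suppress both
        ok = res["valid"] & (res["peak_corr"] >= spec.min_correlation)
        per_pair[j] = np.where(ok, res["axial_m"], 0.0)
        lat_pair[j] = np.where(ok, res["lateral_m"], 0.0)
        quality[j] = float(np.mean(res["peak_corr"][res["valid"]]))
        iq_prev = iq_next
        if progress:
            print(f"  tracked pair {j + 1}/{n_pairs}", end="\r")
    if progress:
        print()

    y_cm = (iy + 0.5) * imaging.axial_pitch_cm
    x_cm = (ix + 0.5) * imaging.beam_pitch_cm
    return accumulate(per_pair, x_cm, y_cm, stack.frame_interval_s,
                      lat_pair, quality)
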