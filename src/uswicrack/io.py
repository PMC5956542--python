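"""HDF5 persistence for the array containers (NPZ fallback by extension)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .phantom import DomainSpec
from .wavesim import WaveField


def _is_npz(path) -> bool:
    return str(path).endswith(".npz")


def save_wavefield(path, wave: WaveField) -> None:
    attrs = dict(
        dx_cm=wave.dx_cm, dy_cm=wave.dy_cm, x0_cm=wave.x0_cm, y0_cm=wave.y0_cm,
        frame_interval_s=wave.frame_interval_s,
    )
    if _is_npz(path):
        np.savez_compressed(path, u=wave.u, **attrs)
        return
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("u", data=wave.u, compression="gzip", shuffle=True)
        for k, v in attrs.items():
            d.attrs[k] = v


def load_wavefield(path) -> WaveField:
    if _is_npz(path):
        z = np.load(path)
        return WaveField(z["u"], float(z["dx_cm"]), float(z["dy_cm"]),
                         float(z["x0_cm"]), float(z["y0_cm"]),
                         float(z["frame_interval_s"]), DomainSpec())
    import h5py

    with h5py.File(path, "r") as f:
        d = f["u"]
        return WaveField(d[...], float(d.attrs["dx_cm"]), float(d.attrs["dy_cm"]),
                         float(d.attrs["x0_cm"]), float(d.attrs["y0_cm"]),
                         float(d.attrs["frame_interval_s"]), DomainSpec())


def save_rf(path, stack) -> None:
    import h5py

    psf = stack.imaging.psf
    with h5py.File(path, "w") as f:
        d = f.create_dataset("rf", data=stack.frames, compression="gzip", shuffle=True)
        d.attrs["fs_hz"] = psf.fs_hz
        d.attrs["f0_hz"] = psf.f0_hz
        d.attrs["c_us"] = psf.c_us
        d.attrs["axial_pitch_cm"] = stack.imaging.axial_pitch_cm
        d.attrs["beam_pitch_cm"] = stack.imaging.beam_pitch_cm
        d.attrs["frame_interval_s"] = stack.frame_interval_s


def load_rf(path):
    import h5py

    from .rf import ImagingSpec, RFStack

    with h5py.File(path, "r") as f:
        d = f["rf"]
        return RFStack(d[...], ImagingSpec(), float(d.attrs["frame_interval_s"]))


def save_displacement(path, disp) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("accumulated", data=disp.accumulated,
                         compression="gzip", shuffle=True)
        f.create_dataset("per_pair", data=disp.per_pair,
                         compression="gzip", shuffle=True)
        f.create_dataset("x_cm", data=disp.x_cm)
        f.create_dataset("y_cm", data=disp.y_cm)
        if disp.quality is not None:
            f.create_dataset("quality", data=disp.quality)
        f.attrs["frame_interval_s"] = disp.frame_interval_s


def load_displacement(path):
    import h5py

    from .tracking import DisplacementMap

    with h5py.File(path, "r") as f:
        return DisplacementMap(
            f["accumulated"][...], f["per_pair"][...], None,
            f["x_cm"][...], f["y_cm"][...], float(f.attrs["frame_interval_s"]),
            f["quality"][...] if "quality" in f else None,
        )


def save_reflected(path, refl) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("R", data=refl.R, compression="gzip")
        f.create_dataset("x_cm", data=refl.x_cm)
        f.create_dataset("y_cm", data=refl.y_cm)


def load_reflected(path):
    import h5py

    from .dirfilter import ReflectedAmplitudeMap

    with h5py.File(path, "r") as f:
        return ReflectedAmplitudeMap(f["R"][...], f["x_cm"][...], f["y_cm"][...])
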