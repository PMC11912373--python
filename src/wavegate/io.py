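"""File IO helpers: HDF5 trajectories, NPY fields, PNG renderings, Gamma images.

Attenuation maps can be drawn as grayscale images: ``load_gamma_image`` maps
pixel values linearly from [0, white] onto a configured [gamma_min, gamma_max]
range.  Snapshots are rendered as log10|Z| (the standard way to visualize
wave fields spanning decades of amplitude).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
from matplotlib import cm

__all__ = [
    "save_trajectory_h5",
    "save_png_logabs",
    "save_gamma_png",
    "load_gamma_image",
    "load_kernel_npy",
    "write_json",
]


def save_trajectory_h5(path, snapshots, final, attrs: dict | None = None) -> None:
    """Write snapshots to ``/Z/<step>`` datasets plus ``/Z/final``."""
    with h5py.File(path, "w") as f:
        g = f.create_group("Z")
        for step, Z in snapshots:
            g.create_dataset(str(step), data=np.asarray(Z))
        g.create_dataset("final", data=np.asarray(final))
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def save_png_logabs(path, Z, floor: float = 1e-12) -> None:
    """Render log10(|Z|) of a 2D field to a color-mapped PNG."""
    img = np.log10(np.abs(np.asarray(Z)) + floor)
    lo, hi = img.min(), img.max()
    scaled = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    rgba = (cm.viridis(scaled) * 255).astype(np.uint8)
    iio.imwrite(Path(path), rgba)


def save_gamma_png(path, gamma) -> None:
    """Write an attenuation map as an 8-bit grayscale PNG (1.0 -> white)."""
    g = np.clip(np.asarray(gamma, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (g * 255).astype(np.uint8))


def load_gamma_image(path, gamma_min: float = 0.01, gamma_max: float = 1.0) -> np.ndarray:
    """Load a grayscale PNG/TIFF and map pixel values linearly onto
    [gamma_min, gamma_max] (black -> gamma_min, white -> gamma_max)."""
    img = np.asarray(iio.imread(Path(path))).astype(float)
    if img.ndim == 3:  # collapse RGB(A) to luminance
        img = img[..., :3].mean(axis=-1)
    top = img.max() if img.max() > 0 else 1.0
    return gamma_min + (gamma_max - gamma_min) * img / top


def load_kernel_npy(path) -> np.ndarray:
    """Load a compact complex kernel from an NPY file."""
    return np.load(Path(path)).astype(complex)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, complex):
            return {"re": o.real, "im": o.imag}
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
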