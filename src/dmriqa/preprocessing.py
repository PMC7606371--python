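"""Slice extraction, padding/normalization, and training-time augmentation.

Volumes are read as stacks of sagittal slices (artifacts from subject motion
are most conspicuous in the sagittal view for axially-acquired EPI).  Each
slice is centered on a square zero canvas and min-max normalized over the
padded array, so the zero background participates in the normalization and
the output always lies in [0, 1].
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from skimage.transform import rotate as _sk_rotate

__all__ = ["load_nifti_volume", "extract_sagittal_slices", "pad_and_normalize", "augment"]


def load_nifti_volume(path: str | Path, volume_index: int = 0) -> np.ndarray:
    """Read a NIfTI-1 file as a 3D float array.

    4D diffusion series are indexed along the last axis by ``volume_index``.
    Gradient tables (b-values/b-vectors) are not read — quality rating does
    not use them.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4:
        data = data[..., volume_index]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D or 4D image, got ndim={data.ndim}")
    return data


def extract_sagittal_slices(volume: np.ndarray, sagittal_axis: int = 0) -> list[np.ndarray]:
    """Split a 3D volume into its ordered sagittal 2D slices."""
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={vol.ndim}")
    vol = np.moveaxis(vol, sagittal_axis, 0)
    return [vol[i].copy() for i in range(vol.shape[0])]


def pad_and_normalize(slice_2d: np.ndarray, target: int = 144) -> np.ndarray:
    """Center a slice on a target x target zero canvas, then min-max normalize.

    Asymmetric padding remainders go to the bottom/right.  A constant-valued
    slice normalizes to all zeros (continuous with the black-background
    limit); cropping is refused — inputs larger than the canvas are an error.
    """
    x = np.asarray(slice_2d, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a 2D slice")
    h, w = x.shape
    if h > target or w > target:
        raise ValueError(f"slice {h}x{w} exceeds target {target}; cropping is not supported")
    top = (target - h) // 2
    left = (target - w) // 2
    canvas = np.zeros((target, target), dtype=np.float64)
    canvas[top : top + h, left : left + w] = x
    lo, hi = canvas.min(), canvas.max()
    if hi - lo <= 0:
        return np.zeros_like(canvas)
    return (canvas - lo) / (hi - lo)


def augment(slice_2d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random rotation in [0°, 30°] (bilinear, zero fill) + horizontal flip.

    Applied at training time only; labels are untouched.  Mirror diversity
    beyond the one-sided rotation range comes from the flip.
    """
    x = np.asarray(slice_2d, dtype=np.float64)
    angle = float(rng.uniform(0.0, 30.0))
    flip = bool(rng.uniform() < 0.5)
    if angle > 0.0:
        x = _sk_rotate(x, angle, resize=False, order=1, mode="constant", cval=0.0)
    if flip:
        x = x[:, ::-1].copy()
    return x
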