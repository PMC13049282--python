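"""Standardization of volumes before the networks, and exact restoration.

Pipeline order: resample to the common grid (third-order spline for
images, nearest-neighbor for masks), clip intensities to the
[0.05, 99.5] percentile range and z-score per volume (per subject and
contrast), zero-pad coronal slices to the 256×256 network canvas.
Predicted masks are taken back to native geometry by cropping to the
original matrix size and nearest-neighbor resampling to native
resolution.

Notes on conventions (the resampling literature leaves these open):

* percentiles use the linear-interpolation order statistic
  (``numpy.percentile`` default);
* the resampled grid size is ``round(native_extent / target_spacing)``;
* z-scoring uses post-clipping statistics (clip first, then normalize).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from .types import ImageVolume, LabelMask

CANVAS_DEFAULT = 256


@dataclass
class CropRecord:
    """Bookkeeping to undo padding and resampling exactly."""
    pad_offsets: tuple[tuple[int, int], tuple[int, int]]
    original_shape: tuple[int, int, int]
    original_spacing: tuple[float, float, float]


def _target_shape(shape, spacing, target_spacing):
    extent = np.asarray(shape) * np.asarray(spacing)
    return tuple(int(round(e / t)) for e, t in zip(extent, target_spacing))


def _resample_data(data: np.ndarray, spacing, target_spacing,
                   order: int) -> np.ndarray:
    new_shape = _target_shape(data.shape, spacing, target_spacing)
    factors = [n / o for n, o in zip(new_shape, data.shape)]
    out = zoom(data, factors, order=order, mode="nearest",
               grid_mode=False, prefilter=order > 1)
    assert out.shape == new_shape, (out.shape, new_shape)
    return out


def resample_volume(vol: ImageVolume | LabelMask,
                    target_spacing: tuple[float, float, float],
                    is_mask: bool = False):
    """Resample to ``target_spacing`` (mm); spline for images, NN for masks."""
    if any(t <= 0 for t in target_spacing):
        raise ValueError("target spacing must be positive")
    if is_mask or isinstance(vol, LabelMask):
        out = _resample_data(vol.labels.astype(np.int16), vol.spacing_mm,
                             target_spacing, order=0)
        return LabelMask(out, vol.scheme, tuple(target_spacing))
    out = _resample_data(vol.data, vol.spacing_mm, target_spacing, order=3)
    return ImageVolume(out, tuple(target_spacing), vol.contrast,
                       native_shape=vol.native_shape)


def clip_and_zscore(vol: ImageVolume, lo_pct: float = 0.05,
                    hi_pct: float = 99.5) -> ImageVolume:
    """Clip to the [lo, hi] percentile of the volume, then z-score it."""
    lo, hi = np.percentile(vol.data, [lo_pct, hi_pct])
    clipped = np.clip(vol.data, lo, hi)
    sd = clipped.std()
    if sd == 0:
        warnings.warn("degenerate input: constant volume, returning zeros")
        out = np.zeros_like(clipped)
    else:
        out = (clipped - clipped.mean()) / sd
    return ImageVolume(out, vol.spacing_mm, vol.contrast, vol.native_shape)


def pad_to_canvas(slice2d: np.ndarray, canvas: int = CANVAS_DEFAULT):
    """Center a 2-D slice on a zero canvas; return (padded, CropRecord)."""
    h, w = slice2d.shape
    if h > canvas or w > canvas:
        raise ValueError(
            f"slice {slice2d.shape} larger than canvas {canvas}; "
            "resample before padding")
    br = (canvas - h) // 2
    bc = (canvas - w) // 2
    out = np.zeros((canvas, canvas), dtype=slice2d.dtype)
    out[br:br + h, bc:bc + w] = slice2d
    rec = CropRecord(((br, canvas - h - br), (bc, canvas - w - bc)),
                     (1, h, w), (1.0, 1.0, 1.0))
    return out, rec


def pad_volume_to_canvas(data: np.ndarray, canvas: int,
                         original_shape, original_spacing):
    """Pad the in-plane axes of a (S, H, W) array; record native geometry."""
    s, h, w = data.shape
    if h > canvas or w > canvas:
        raise ValueError("volume in-plane size exceeds canvas; resample first")
    br, bc = (canvas - h) // 2, (canvas - w) // 2
    out = np.zeros((s, canvas, canvas), dtype=data.dtype)
    out[:, br:br + h, bc:bc + w] = data
    rec = CropRecord(((br, canvas - h - br), (bc, canvas - w - bc)),
                     tuple(original_shape), tuple(original_spacing))
    return out, rec


def crop_from_canvas(data: np.ndarray, rec: CropRecord) -> np.ndarray:
    (br, ar), (bc, ac) = rec.pad_offsets
    h = data.shape[-2] - br - ar
    w = data.shape[-1] - bc - ac
    if h <= 0 or w <= 0:
        raise ValueError("CropRecord inconsistent with array shape")
    return data[..., br:br + h, bc:bc + w]


def restore_native_geometry(mask: LabelMask, rec: CropRecord) -> LabelMask:
    """Crop to the pre-padding matrix, then NN-resample to native spacing."""
    cropped = crop_from_canvas(mask.labels, rec)
    factors = [n / o for n, o in zip(rec.original_shape, cropped.shape)]
    out = zoom(cropped.astype(np.int16), factors, order=0, mode="nearest",
               prefilter=False)
    if out.shape != tuple(rec.original_shape):
        raise ValueError("CropRecord original_shape inconsistent with crop")
    return LabelMask(out, mask.scheme, rec.original_spacing)


def preprocess_volume(vol: ImageVolume,
                      target_spacing=(3.0, 1.5, 1.5),
                      canvas: int = CANVAS_DEFAULT):
    """resample → clip+z-score → pad; returns (ImageVolume, CropRecord)."""
    native_shape, native_spacing = vol.data.shape, vol.spacing_mm
    res = resample_volume(vol, target_spacing)
    norm = clip_and_zscore(res)
    padded, rec = pad_volume_to_canvas(norm.data, canvas,
                                       native_shape, native_spacing)
    out = ImageVolume(padded, target_spacing, vol.contrast,
                      native_shape=native_shape)
    return out, rec
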