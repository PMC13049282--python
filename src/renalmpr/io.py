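"""NIfTI import/export for volumes, masks and displacement fields.

Arrays are (slices, rows, cols) in memory; on disk they are stored in
(cols, rows, slices) order with a diagonal affine built from the spacing,
so geometry metadata round-trips.  Fields are 4-D (cols, rows, slices, 2)
with a JSON sidecar naming the convention (backward/sampling, pixels).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .types import (ImageVolume, LabelMask, DisplacementField, SUBREGION5,
                    KIDNEY3, ClassScheme)

_SCHEMES = {s.name: s for s in (SUBREGION5, KIDNEY3)}


def _affine(spacing_mm) -> np.ndarray:
    s = np.asarray(spacing_mm, dtype=float)  # (slice, row, col)
    return np.diag([s[2], s[1], s[0], 1.0])


def _to_disk(data: np.ndarray) -> np.ndarray:
    return np.transpose(data, (2, 1, 0))


def _from_disk(data: np.ndarray) -> np.ndarray:
    return np.transpose(data, (2, 1, 0))


def save_volume(vol: ImageVolume, path: str | Path):
    img = nib.Nifti1Image(_to_disk(vol.data).astype(np.float32),
                          _affine(vol.spacing_mm))
    nib.save(img, str(path))


def load_volume(path: str | Path, contrast: str) -> ImageVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return ImageVolume(_from_disk(np.asarray(img.dataobj, dtype=np.float64)),
                       spacing, contrast)


def save_mask(mask: LabelMask, path: str | Path):
    img = nib.Nifti1Image(_to_disk(mask.labels).astype(np.int16),
                          _affine(mask.spacing_mm))
    nib.save(img, str(path))
    Path(str(path) + ".json").write_text(
        json.dumps({"scheme": mask.scheme.name}))


def load_mask(path: str | Path,
              scheme: ClassScheme | None = None) -> LabelMask:
    img = nib.load(str(path))
    if scheme is None:
        side = Path(str(path) + ".json")
        scheme = _SCHEMES[json.loads(side.read_text())["scheme"]] \
            if side.exists() else SUBREGION5
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return LabelMask(_from_disk(np.asarray(img.dataobj)).astype(np.int16),
                     scheme, spacing)


def save_fields(fields: list[DisplacementField], spacing_mm,
                path: str | Path):
    """Per-slice (2,H,W) fields → one 4-D NIfTI + convention sidecar."""
    stack = np.stack([f.u for f in fields])          # (S, 2, H, W)
    disk = np.transpose(stack, (3, 2, 0, 1))          # (W, H, S, 2)
    nib.save(nib.Nifti1Image(disk.astype(np.float32), _affine(spacing_mm)),
             str(path))
    Path(str(path) + ".json").write_text(json.dumps({
        "convention": "backward/sampling: warped(x) = moving(x + u(x))",
        "units": "pixels", "channels": ["row", "col"],
        "slices": [f.slice_index for f in fields]}))


def load_fields(path: str | Path) -> list[DisplacementField]:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)   # (W, H, S, 2)
    stack = np.transpose(arr, (2, 3, 1, 0))           # (S, 2, H, W)
    return [DisplacementField(stack[s], s) for s in range(stack.shape[0])]


def write_study(study, out_dir: str | Path):
    """Serialize a synthetic study (volumes, masks, true fields, spec)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for contrast, vol in study.volumes.items():
        save_volume(vol, out / f"{contrast}.nii.gz")
        save_mask(study.masks[contrast], out / f"{contrast}_mask.nii.gz")
        if contrast in study.true_fields:
            save_fields(study.true_fields[contrast], vol.spacing_mm,
                        out / f"{contrast}_truefield.nii.gz")
    (out / "phantom_spec.json").write_text(study.spec.to_json())


def load_study_volumes(study_dir: str | Path,
                       contrast_map: dict | None = None) -> dict:
    """Recognize contrasts from filename tags; return contrast → ImageVolume."""
    from .types import CONTRASTS
    tags = contrast_map or {c: c for c in CONTRASTS}
    out = {}
    for path in sorted(Path(study_dir).glob("*.nii*")):
        if "_mask" in path.name or "_truefield" in path.name:
            continue
        stem = path.name.split(".")[0].upper()
        for tag, contrast in tags.items():
            if tag.upper() == stem:
                out[contrast] = load_volume(path, contrast)
    return out
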