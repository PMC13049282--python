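"""Quantitative outputs: region volumes and per-region parametric means.

Volumes (mL) come from the Dixon 5-class mask; per-contrast region means
are taken in native (unnormalized) intensity units by applying binary
region masks to each parametric map.  High-contrast maps (Dixon, T1, T2,
T2*) use their direct 5-class segmentations; the low-contrast RBF and ADC
maps use the Dixon segmentation propagated through the registration
fields, which is recorded per row as the mask provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (LabelMask, ImageVolume, LOW_CONTRAST,
                    REFERENCE_CONTRAST, CONTRAST_UNITS)

#: (side, region) → the SUBREGION5 labels it covers
REGION_LABELS = {
    ("left", "kidney"): (1, 2), ("left", "cortex"): (2,),
    ("left", "medulla"): (1,),
    ("right", "kidney"): (3, 4), ("right", "cortex"): (4,),
    ("right", "medulla"): (3,),
    ("both", "kidney"): (1, 2, 3, 4), ("both", "cortex"): (2, 4),
    ("both", "medulla"): (1, 3),
}


@dataclass
class RegionReport:
    volumes_mL: dict = field(default_factory=dict)   # (side, region) → mL
    rows: list = field(default_factory=list)         # per contrast × region

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json(self) -> str:
        return json.dumps(
            {"volumes_mL": {f"{s}_{r}": v
                            for (s, r), v in self.volumes_mL.items()},
             "rows": self.rows}, indent=2, default=float)


def _region_mask(mask: LabelMask, labels) -> np.ndarray:
    return np.isin(mask.labels, labels)


def region_volumes(mask: LabelMask) -> dict:
    """Volume in mL per (side, region): voxel count × voxel volume / 1000."""
    if mask.spacing_mm is None:
        raise ValueError("mask has no spacing")
    vox_mm3 = float(np.prod(mask.spacing_mm))
    out = {}
    for key, labels in REGION_LABELS.items():
        n = int(_region_mask(mask, labels).sum())
        out[key] = n * vox_mm3 / 1000.0
    return out


def region_means(map_vol: ImageVolume, mask: LabelMask) -> dict:
    """Mean map value per region; NaN voxels excluded; empty regions → None."""
    if map_vol.data.shape != mask.labels.shape:
        raise ValueError("map and mask grids differ")
    out = {}
    for key, labels in REGION_LABELS.items():
        sel = _region_mask(mask, labels)
        vals = map_vol.data[sel]
        finite = vals[np.isfinite(vals)]
        out[key] = {"mean": float(finite.mean()) if finite.size else None,
                    "voxels": int(finite.size),
                    "nan_voxels": int(vals.size - finite.size)}
    return out


def build_feature_report(registered, masks: dict,
                         volumes: dict) -> RegionReport:
    """Assemble the pipeline's quantitative report.

    ``registered`` is a :class:`~renalmpr.registration.RegisteredStudy`
    (may be None when no low-contrast maps are present); ``masks`` maps
    contrast → direct 5-class :class:`LabelMask` and must include Dixon;
    ``volumes`` maps contrast → native-unit :class:`ImageVolume`.  Each
    mean row records its mask provenance ("direct" or "propagated");
    empty regions are reported as missing, never as 0.  Quantification
    always uses native (unnormalized) intensities.
    """
    if REFERENCE_CONTRAST not in masks:
        raise ValueError("Dixon mask required for the feature report")
    report = RegionReport(volumes_mL=region_volumes(masks[REFERENCE_CONTRAST]))
    available = {c: (m, "direct") for c, m in masks.items()}
    if registered is not None:
        for c in LOW_CONTRAST:
            if c in registered.propagated_masks:
                available[c] = (registered.propagated_masks[c], "propagated")
    for contrast, (mask, source) in available.items():
        if contrast not in volumes:
            continue
        for (side, region), rec in region_means(volumes[contrast],
                                                mask).items():
            if rec["mean"] is None:
                continue
            report.rows.append({
                "contrast": contrast, "side": side, "region": region,
                "mean": rec["mean"], "unit": CONTRAST_UNITS.get(contrast, ""),
                "voxels": rec["voxels"], "nan_voxels": rec["nan_voxels"],
                "mask_source": source})
    return report


def feature_report_from_study(study, registered=None,
                              predicted_masks: dict | None = None
                              ) -> RegionReport:
    """Report for a phantom/cohort study: convenience entry point.

    Uses ``predicted_masks`` (direct 5-class segmentations) when given,
    else the study's ground-truth masks; RBF/ADC means use propagated
    masks whenever ``registered`` provides them.
    """
    masks = dict(predicted_masks) if predicted_masks else dict(study.masks)
    if REFERENCE_CONTRAST not in masks:
        raise ValueError("Dixon mask required")
    report = RegionReport(volumes_mL=region_volumes(masks[REFERENCE_CONTRAST]))
    for contrast, vol in study.volumes.items():
        if contrast in LOW_CONTRAST:
            if registered is not None and \
                    contrast in registered.propagated_masks:
                mask, source = registered.propagated_masks[contrast], \
                    "propagated"
            else:
                continue
        else:
            if contrast not in masks:
                continue
            mask, source = masks[contrast], "direct"
        for (side, region), rec in region_means(vol, mask).items():
            if rec["mean"] is None:
                continue
            report.rows.append({
                "contrast": contrast, "side": side, "region": region,
                "mean": rec["mean"], "unit": CONTRAST_UNITS.get(contrast, ""),
                "voxels": rec["voxels"], "nan_voxels": rec["nan_voxels"],
                "mask_source": source})
    return report
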