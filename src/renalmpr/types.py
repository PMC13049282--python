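"""Shared domain containers for the renal multiparametric pipeline.

Conventions used throughout the package:

* volumes are ``(slices, rows, cols)`` with coronal slices along the first
  axis; all 2-D processing iterates over that axis;
* ``spacing_mm`` is ordered like the array axes (slice, row, col);
* displacement fields are 2-D per-slice, ``(2, H, W)`` with channel 0 the
  row displacement and channel 1 the column displacement in pixels, in the
  backward/sampling convention ``warped(x) = moving(x + u(x))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONTRASTS = ("DIXON", "T1", "T2", "T2STAR", "RBF", "ADC")
#: contrasts with clear cortico-medullary contrast (directly segmentable)
HIGH_CONTRAST = ("DIXON", "T1", "T2", "T2STAR")
#: perfusion/diffusion maps where cortex and medulla are near-isointense
LOW_CONTRAST = ("RBF", "ADC")
REFERENCE_CONTRAST = "DIXON"

#: native units of each parametric map, reported alongside region means
CONTRAST_UNITS = {"DIXON": "a.u.", "T1": "ms", "T2": "ms", "T2STAR": "ms",
                  "RBF": "mL/100g/min", "ADC": "1e-6 mm^2/s"}


@dataclass(frozen=True)
class ClassScheme:
    """A contiguous integer labeling starting at 0 (background)."""
    name: str
    labels: tuple[str, ...]

    @property
    def n_classes(self) -> int:
        return len(self.labels)


KIDNEY3 = ClassScheme("KIDNEY3", ("background", "left_kidney", "right_kidney"))
SUBREGION5 = ClassScheme("SUBREGION5", ("background", "left_medulla",
                                        "left_cortex", "right_medulla",
                                        "right_cortex"))

#: SUBREGION5 label → KIDNEY3 label
COLLAPSE_5_TO_3 = {0: 0, 1: 1, 2: 1, 3: 2, 4: 2}


def collapse_to_kidney3(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels)
    for src, dst in COLLAPSE_5_TO_3.items():
        out[labels == src] = dst
    return out


@dataclass
class ImageVolume:
    """A single-contrast 3-D scalar grid with spacing and contrast tag."""
    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    contrast: str
    native_shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume.data must be 3-D (slices, rows, cols)")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing entries must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageVolume.data must be finite")
        if self.native_shape is None:
            self.native_shape = self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class LabelMask:
    """Integer grid over a class scheme."""
    labels: np.ndarray
    scheme: ClassScheme
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int16)
        present = set(np.unique(self.labels).tolist())
        allowed = set(range(self.scheme.n_classes))
        if not present <= allowed:
            raise ValueError(
                f"labels {sorted(present - allowed)} outside scheme "
                f"{self.scheme.name}")

    def binary(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class DisplacementField:
    """Per-slice 2-D displacement field (pixels, backward convention)."""
    u: np.ndarray
    slice_index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 3 or self.u.shape[0] != 2:
            raise ValueError("DisplacementField.u must be (2, H, W)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape[1:]

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.u ** 2).sum(axis=0)).max())
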