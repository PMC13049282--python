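"""Evaluation statistics for segmentation, registration and agreement.

Implements the full metric suite the pipeline is judged by: Dice
similarity (DSC), boundary Hausdorff distance in millimeters, hard-binned
normalized mutual information, a PCA-based deformation index over an
aligned image series, the percentage of non-positive Jacobian
determinants of a displacement field, and manual-vs-automated agreement
statistics (bias, Bland–Altman limits of agreement, ICC(2,1) with an
F-based 95% CI, Pearson r).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree
from scipy.stats import f as f_dist

from .types import DisplacementField, LabelMask
from .registration import nmi_similarity  # shared hard-binned estimator

__all__ = ["dice_score", "dice_per_class", "hausdorff_mm", "nmi_similarity",
           "dpca_index", "jacobian_nonpositive_pct", "agreement_stats",
           "AgreementStats"]


def _as_binary(x) -> np.ndarray:
    if isinstance(x, LabelMask):
        return x.labels > 0
    return np.asarray(x) != 0


def dice_score(a, b) -> float:
    """2|A∩B| / (|A|+|B|) on binary grids (LabelMask foreground accepted).

    Both-empty is defined as 1 (with a warning flag); single-empty is 0.
    """
    A, B = _as_binary(a), _as_binary(b)
    if A.shape != B.shape:
        raise ValueError("shape mismatch")
    denom = A.sum() + B.sum()
    if denom == 0:
        warnings.warn("both masks empty: Dice defined as 1")
        return 1.0
    return float(2.0 * (A & B).sum() / denom)


def dice_per_class(a: LabelMask, b: LabelMask) -> dict[int, float]:
    """Dice per non-background class of the shared scheme."""
    if a.labels.shape != b.labels.shape:
        raise ValueError("shape mismatch")
    return {c: dice_score(a.labels == c, b.labels == c)
            for c in range(1, a.scheme.n_classes)}


def _boundary_coords(mask: np.ndarray, spacing) -> np.ndarray:
    inner = binary_erosion(mask, border_value=0)
    bd = mask & ~inner
    coords = np.argwhere(bd).astype(np.float64)
    return coords * np.asarray(spacing)[: mask.ndim]


def hausdorff_mm(a, b, spacing, percentile: float | None = None) -> float:
    """Symmetric Hausdorff distance between boundary voxel sets, in mm.

    The strict maximum by default; ``percentile`` (e.g. 95) selects the
    robust variant.  Euclidean distances in physical units via ``spacing``.
    """
    A, B = _as_binary(a), _as_binary(b)
    if A.shape != B.shape:
        raise ValueError("shape mismatch")
    if not A.any():
        raise ValueError("first mask is empty")
    if not B.any():
        raise ValueError("second mask is empty")
    ca, cb = _boundary_coords(A, spacing), _boundary_coords(B, spacing)
    d_ab = cKDTree(cb).query(ca)[0]
    d_ba = cKDTree(ca).query(cb)[0]
    if percentile is None:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile),
                     np.percentile(d_ba, percentile)))


def dpca_index(series, topK: int = 1, form: str = "residual") -> float:
    """Spectral misalignment index of an aligned image series.

    Builds the L×L correlation matrix of the vectorized images and
    eigendecomposes it.  ``form="residual"`` (default) returns the sum of
    eigenvalues beyond the top K — 0 for a perfectly coherent (rank-1)
    series, approaching L−K for independent images; lower is better.
    ``form="topk_ratio"`` returns Σ top-K λ / Σ λ (≤ 1, higher is better).
    """
    mats = [np.ravel(np.asarray(g, dtype=np.float64)) for g in series]
    if len(mats) < 2:
        raise ValueError("need at least two images")
    for i, v in enumerate(mats):
        if v.std() == 0:
            raise ValueError(f"image {i} is constant: correlation undefined")
    corr = np.corrcoef(np.stack(mats))
    lam = np.sort(np.linalg.eigvalsh(corr))[::-1]
    lam = np.clip(lam, 0, None)
    if form == "residual":
        return float(lam[topK:].sum())
    if form == "topk_ratio":
        return float(lam[:topK].sum() / lam.sum())
    raise ValueError(f"unknown form {form!r}")


def jacobian_nonpositive_pct(field: DisplacementField | np.ndarray) -> float:
    """Percent of pixels with det(I + ∇u) ≤ 0 (folding indicator).

    Central differences in the interior, one-sided at the borders.
    """
    u = field.u if isinstance(field, DisplacementField) else np.asarray(field)
    if u.shape[1] < 2 or u.shape[2] < 2:
        raise ValueError("field must be at least 2×2")
    dr_r, dr_c = np.gradient(u[0])
    dc_r, dc_c = np.gradient(u[1])
    det = (1.0 + dr_r) * (1.0 + dc_c) - dr_c * dc_r
    return float(100.0 * (det <= 0).mean())


@dataclass
class AgreementStats:
    bias: float
    loa: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    pearson_r: float
    n: int
    flags: list = field(default_factory=list)


def _icc21(manual: np.ndarray, automated: np.ndarray, alpha: float = 0.05):
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""
    Y = np.stack([manual, automated], axis=1)
    n, k = Y.shape
    grand = Y.mean()
    row_m = Y.mean(axis=1)
    col_m = Y.mean(axis=0)
    ss_total = ((Y - grand) ** 2).sum()
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return float("nan"), (float("nan"), float("nan"))
    icc = (msr - mse) / denom
    # F-based CI (Shrout & Fleiss); Satterthwaite df for the lower/upper F
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f1 = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f2 = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        lower = upper = icc
    return float(icc), (float(lower), float(upper))


def agreement_stats(manual, automated) -> AgreementStats:
    """Bias, Bland–Altman limits of agreement, ICC(2,1) + 95% CI, Pearson r.

    Differences are automated − manual; LoA = bias ± 1.96·SD(differences).
    """
    m = np.asarray(manual, dtype=np.float64)
    a = np.asarray(automated, dtype=np.float64)
    if m.shape != a.shape or m.ndim != 1:
        raise ValueError("manual and automated must be paired 1-D arrays")
    n = len(m)
    if n < 2:
        raise ValueError("need at least 2 pairs for bias")
    flags = []
    diff = a - m
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    if n < 3:
        raise ValueError("ICC requires at least 3 pairs")
    if m.std() == 0 and a.std() == 0:
        flags.append("zero-variance input: ICC undefined")
        icc, ci = float("nan"), (float("nan"), float("nan"))
        r = 1.0 if np.allclose(m, a) else float("nan")
    else:
        icc, ci = _icc21(m, a)
        if np.isnan(icc):
            flags.append("degenerate ANOVA: ICC undefined")
        with np.errstate(invalid="ignore"):
            r = float(np.corrcoef(m, a)[0, 1])
    if np.allclose(m, a):
        icc, ci, r = 1.0, (1.0, 1.0), 1.0
    return AgreementStats(bias, loa, icc, ci, r, n, flags)
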