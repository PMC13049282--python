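"""Synthetic multiparametric renal phantom studies.

Emulates what a multiparametric renal MR protocol delivers to the
post-processing pipeline: two kidney-shaped objects per volume with a
cortical shell, medullary lobes and a renal pelvis; one volume per
contrast with contrast-specific intensity profiles (strong
cortico-medullary contrast for Dixon/T1/T2/T2*, near-isointense for
RBF/ADC); per-contrast spatial misalignment (random in-plane affine plus a
Gaussian-smoothed random deformation); additive Gaussian noise.

Because anatomy is defined by closed-form ellipsoid membership, a
misaligned contrast is rendered by evaluating the anatomy at transformed
coordinates — so its ground-truth mask and the ground-truth displacement
field relating it to the reference are exact, which is what makes every
downstream stage (segmentation, registration, propagation,
quantification) testable without any acquired data.

No MR physics is simulated (no Bloch equations, no ASL kinetics); the
intensity table is configuration, not a claim about tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .types import (CONTRASTS, HIGH_CONTRAST, REFERENCE_CONTRAST, SUBREGION5,
                    DisplacementField, ImageVolume, LabelMask)

#: default per-contrast mean intensities (background, cortex, medulla, pelvis)
DEFAULT_INTENSITY_TABLE = {
    "DIXON": (50.0, 200.0, 120.0, 80.0),
    "T1": (40.0, 150.0, 210.0, 90.0),
    "T2": (30.0, 180.0, 240.0, 100.0),
    "T2STAR": (35.0, 160.0, 110.0, 70.0),
    "RBF": (20.0, 140.0, 138.0, 60.0),
    "ADC": (25.0, 130.0, 127.0, 50.0),
}

DEFAULT_NOISE_SD = {"DIXON": 5.0, "T1": 5.0, "T2": 5.0, "T2STAR": 5.0,
                    "RBF": 6.0, "ADC": 6.0}


@dataclass
class AffineRange:
    """Bounds for the random per-contrast misalignment (uniform draws)."""
    translate_px: float = 4.0
    rotate_deg: float = 5.0
    scale: tuple[float, float] = (0.97, 1.03)

    @classmethod
    def none(cls) -> "AffineRange":
        return cls(0.0, 0.0, (1.0, 1.0))


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (32, 256, 256)
    spacing_mm: tuple[float, float, float] = (3.0, 1.5, 1.5)
    contrasts: tuple[str, ...] = CONTRASTS
    intensity_table: dict = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_TABLE))
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    misalign_affine_range: AffineRange = field(default_factory=AffineRange)
    deform_amplitude_px: float = 3.0
    deform_smoothness_px: float = 12.0
    seed: int = 0

    @classmethod
    def tiny(cls, **overrides) -> "PhantomSpec":
        """Small fast preset (8×64×64) for tests and CPU-bound experiments."""
        kw = dict(grid_shape=(8, 64, 64), spacing_mm=(3.0, 1.5, 1.5))
        kw.update(overrides)
        return cls(**kw)

    def validate(self):
        if any(g < 8 for g in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 8")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing entries must be positive")
        for k in self.contrasts:
            if k not in self.intensity_table:
                raise ValueError(f"intensity_table missing contrast {k}")
            if len(self.intensity_table[k]) != 4:
                raise ValueError(
                    f"intensity_table[{k}] must give (background, cortex, "
                    "medulla, pelvis)")
            sd = self.noise_sd.get(k, 0.0)
            if sd < 0:
                raise ValueError("noise_sd must be nonnegative")
            gap = abs(self.intensity_table[k][1] - self.intensity_table[k][2])
            if k in HIGH_CONTRAST and gap < 3 * sd:
                raise ValueError(
                    f"{k} is high-contrast: cortex/medulla means must differ "
                    f"by >= 3*noise_sd ({gap:.1f} < {3 * sd:.1f})")
            if k not in HIGH_CONTRAST and gap >= max(sd, 1e-12):
                raise ValueError(
                    f"{k} is low-contrast: cortex/medulla means must differ "
                    f"by < noise_sd ({gap:.1f} >= {sd:.1f})")
        if self.deform_amplitude_px < 0:
            raise ValueError("deform_amplitude_px must be >= 0")
        if self.deform_smoothness_px <= 0:
            raise ValueError("deform_smoothness_px must be > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


@dataclass
class SyntheticStudy:
    volumes: dict[str, ImageVolume]
    masks: dict[str, LabelMask]
    true_fields: dict[str, list[DisplacementField]]
    spec: PhantomSpec


# --------------------------------------------------------------------------
# anatomy
# --------------------------------------------------------------------------

def _kidney_geometry(grid_shape):
    S, H, W = grid_shape
    semi = (0.38 * S, 0.30 * H, 0.14 * W)
    if min(semi[1], semi[2]) < 2.0:
        raise ValueError(
            f"degenerate geometry: kidney in-plane radius "
            f"{min(semi[1], semi[2]):.2f} px < 2 px for grid {grid_shape}")
    centers = {"left": (S / 2, H / 2, 0.30 * W),
               "right": (S / 2, H / 2, 0.70 * W)}
    return centers, semi


def anatomy_labels(grid_shape, ss, rr, cc):
    """Closed-form region membership at (possibly fractional) coordinates.

    Returns ``(labels5, pelvis)``: the 5-class label array (background,
    left/right medulla and cortex) and a pelvis indicator (pelvis voxels sit
    inside the kidney outline but are excluded from the parenchyma labels —
    medullary masks are everything inside the kidney that is not cortex or
    pelvis).
    """
    centers, (a_s, a_r, a_c) = _kidney_geometry(grid_shape)
    labels = np.zeros(np.broadcast(ss, rr, cc).shape, dtype=np.int16)
    pelvis = np.zeros_like(labels, dtype=bool)
    for side, (s0, r0, c0) in centers.items():
        ds, dr, dc = ss - s0, rr - r0, cc - c0
        rho = np.sqrt((ds / a_s) ** 2 + (dr / a_r) ** 2 + (dc / a_c) ** 2)
        kidney = rho <= 1.0
        theta = np.arctan2(dr, dc)
        phase = 0.0 if side == "left" else np.pi / 3
        lobes = 0.55 * (1.0 + 0.18 * np.sin(3 * theta + phase))
        medulla = kidney & (rho <= lobes)
        # pelvis: small medial ellipsoid carved out of the parenchyma
        med_sign = 1.0 if side == "left" else -1.0
        pc = c0 + med_sign * 0.45 * a_c
        prho = np.sqrt((ds / (0.45 * a_s)) ** 2 + (dr / (0.30 * a_r)) ** 2
                       + ((cc - pc) / (0.35 * a_c)) ** 2)
        pel = kidney & (prho <= 1.0)
        cortex = kidney & ~medulla & ~pel
        medulla = medulla & ~pel
        m_lab, c_lab = (1, 2) if side == "left" else (3, 4)
        labels[medulla] = m_lab
        labels[cortex] = c_lab
        labels[pel] = 0
        pelvis |= pel
    return labels, pelvis


def _render(spec: PhantomSpec, contrast: str, labels5: np.ndarray,
            pelvis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    bg, cortex, medulla, pel_i = spec.intensity_table[contrast]
    img = np.full(labels5.shape, bg, dtype=np.float64)
    img[np.isin(labels5, (1, 3))] = medulla
    img[np.isin(labels5, (2, 4))] = cortex
    img[pelvis] = pel_i
    sd = spec.noise_sd.get(contrast, 0.0)
    if sd > 0:
        img = img + rng.normal(0.0, sd, size=img.shape)
    return img


# --------------------------------------------------------------------------
# deformations
# --------------------------------------------------------------------------

def random_smooth_field(shape_hw, amplitude_px: float, smoothness_px: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Gaussian-smoothed white-noise field rescaled to max |u| = amplitude.

    Diffeomorphic for small amplitude relative to the smoothing scale; the
    fields stay fold-free (non-positive Jacobian fraction 0) for
    ``amplitude_px <= smoothness_px / 3`` in practice, and this is the
    regime the defaults use.
    """
    u = rng.standard_normal((2,) + tuple(shape_hw))
    u = np.stack([gaussian_filter(u[i], smoothness_px, mode="reflect")
                  for i in range(2)])
    mag = np.sqrt((u ** 2).sum(axis=0)).max()
    if amplitude_px == 0 or mag == 0:
        return np.zeros_like(u)
    return u * (amplitude_px / mag)


def _sample_affine(rng: np.random.Generator, rang: AffineRange):
    """Uniformly sampled in-plane affine (rotation·scale, translation)."""
    t = rng.uniform(-rang.translate_px, rang.translate_px, size=2)
    th = np.deg2rad(rng.uniform(-rang.rotate_deg, rang.rotate_deg))
    sc = rng.uniform(rang.scale[0], rang.scale[1])
    A = sc * np.array([[np.cos(th), -np.sin(th)],
                       [np.sin(th), np.cos(th)]])
    return A, t


def _jacobian_nonpositive_fraction(u: np.ndarray) -> float:
    """Fraction of pixels with det(I + ∇u) <= 0 (central differences)."""
    du_r = np.gradient(u[0])
    du_c = np.gradient(u[1])
    det = (1 + du_r[0]) * (1 + du_c[1]) - du_r[1] * du_c[0]
    return float((det <= 0).mean())


def apply_synthetic_deformation(volume: ImageVolume, mask: LabelMask,
                                amplitude_px: float, smoothness_px: float,
                                seed: int):
    """Warp a volume+mask by a random smooth in-plane field; return truth.

    The same 2-D field is applied to every coronal slice.  Returns the
    warped image (linear interpolation), warped mask (nearest) and the
    ground-truth field, whose metadata records the non-positive Jacobian
    fraction (with a ``folding`` warning if it is > 0).
    """
    if amplitude_px < 0:
        raise ValueError("amplitude_px must be >= 0")
    rng = np.random.default_rng(seed)
    H, W = volume.data.shape[1:]
    u = random_smooth_field((H, W), amplitude_px, smoothness_px, rng)
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    coords = np.stack([rr + u[0], cc + u[1]])
    img_out = np.stack([map_coordinates(sl, coords, order=1, mode="constant")
                        for sl in volume.data])
    msk_out = np.stack([map_coordinates(sl, coords, order=0, mode="constant",
                                        cval=0)
                        for sl in mask.labels])
    meta = {"amplitude_px": amplitude_px, "smoothness_px": smoothness_px,
            "seed": seed,
            "nonpositive_jacobian_fraction": _jacobian_nonpositive_fraction(u)}
    if meta["nonpositive_jacobian_fraction"] > 0:
        meta["warning"] = "folding: non-positive Jacobian determinant present"
    warped_vol = ImageVolume(img_out, volume.spacing_mm, volume.contrast,
                             volume.native_shape)
    warped_mask = LabelMask(msk_out.astype(mask.labels.dtype), mask.scheme,
                            mask.spacing_mm)
    return warped_vol, warped_mask, DisplacementField(u, metadata=meta)


# --------------------------------------------------------------------------
# study generation
# --------------------------------------------------------------------------

def generate_phantom_study(spec: PhantomSpec) -> SyntheticStudy:
    """Generate a full misaligned multiparametric study with ground truth.

    The reference contrast (Dixon) is rendered on the identity grid.  Every
    other contrast k is rendered at transformed coordinates
    ``T_k(x) = A_k(x + u_k(x))`` (smooth deformation followed by an affine
    about the image center), so its mask is exact and the stored true field
    ``u_true = T_k − id`` satisfies ``warp(reference_mask, u_true) ≈ mask_k``
    up to nearest-neighbor discretization.  Identical seeds give
    bit-identical studies.
    """
    spec.validate()
    S, H, W = spec.grid_shape
    rng = np.random.default_rng(spec.seed)
    rr, cc = np.meshgrid(np.arange(H, dtype=np.float64),
                         np.arange(W, dtype=np.float64), indexing="ij")
    ss = np.arange(S, dtype=np.float64)[:, None, None]
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])

    volumes, masks, true_fields = {}, {}, {}
    for contrast in spec.contrasts:
        sub = np.random.default_rng(rng.integers(2 ** 31))
        if contrast == REFERENCE_CONTRAST:
            Tr, Tc = rr, cc
            u_true = np.zeros((2, H, W))
        else:
            A, t = _sample_affine(sub, spec.misalign_affine_range)
            u = random_smooth_field((H, W), spec.deform_amplitude_px,
                                    spec.deform_smoothness_px, sub)
            pr, pc = rr + u[0] - center[0], cc + u[1] - center[1]
            Tr = A[0, 0] * pr + A[0, 1] * pc + t[0] + center[0]
            Tc = A[1, 0] * pr + A[1, 1] * pc + t[1] + center[1]
            u_true = np.stack([Tr - rr, Tc - cc])
        labels, pelvis = anatomy_labels(spec.grid_shape,
                                        np.broadcast_to(ss, (S, H, W)),
                                        np.broadcast_to(Tr, (S, H, W)),
                                        np.broadcast_to(Tc, (S, H, W)))
        img = _render(spec, contrast, labels, pelvis, sub)
        volumes[contrast] = ImageVolume(img, spec.spacing_mm, contrast)
        masks[contrast] = LabelMask(labels, SUBREGION5, spec.spacing_mm)
        if contrast != REFERENCE_CONTRAST:
            true_fields[contrast] = [DisplacementField(u_true.copy(), s)
                                     for s in range(S)]
    return SyntheticStudy(volumes, masks, true_fields, spec)
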