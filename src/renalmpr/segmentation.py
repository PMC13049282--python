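"""Fine-tuning of the backbone for renal segmentation, and inference.

Two networks are trained in practice: a 3-class model (background,
left/right kidney) covering every contrast, and a 5-class model
(background, left/right medulla and cortex) for the high-contrast images
(ADC is excluded from 5-class training: its cortico-medullary contrast
does not support labels).  Training minimizes a class-weighted Tversky
loss (α=0.3 penalizing false positives, β=0.7 false negatives) with
inverse-frequency class weights, on-the-fly augmentation (rotation,
scaling, elastic deformation, brightness/contrast) and Adam with
polynomial learning-rate decay; the foreground Dice on held-out slices is
the validation metric and the best-validation weights are returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .nn import Tensor, Adam
from .backbone import UNetConfig, UNet, ParameterSet
from .types import (ClassScheme, ImageVolume, LabelMask, KIDNEY3, SUBREGION5,
                    HIGH_CONTRAST, collapse_to_kidney3)
from .phantom import random_smooth_field
from .preproc import CropRecord, restore_native_geometry

TVERSKY_ALPHA = 0.3
TVERSKY_BETA = 0.7
TVERSKY_EPS = 1e-6
#: floor frequency used when a class is absent from the batch
FREQ_FLOOR = 1e-6


@dataclass
class SoftPrediction:
    probs: np.ndarray          # (C, H, W), per-pixel simplex
    scheme: ClassScheme


def inverse_frequency_weights(mask_batch, scheme: ClassScheme,
                              floor: float = FREQ_FLOOR) -> np.ndarray:
    """w_c ∝ 1/freq_c over the batch, normalized to sum to n_classes."""
    counts = np.zeros(scheme.n_classes)
    for m in mask_batch:
        labels = m.labels if isinstance(m, LabelMask) else np.asarray(m)
        counts += np.bincount(labels.ravel(), minlength=scheme.n_classes)
    freq = counts / counts.sum()
    w = 1.0 / np.maximum(freq, floor)
    return w * (scheme.n_classes / w.sum())


def _onehot(labels: np.ndarray, n: int) -> np.ndarray:
    return np.stack([(labels == c).astype(np.float64) for c in range(n)])


def tversky_loss(pred, target, alpha: float = TVERSKY_ALPHA,
                 beta: float = TVERSKY_BETA, weights=None,
                 eps: float = TVERSKY_EPS):
    """Weighted Tversky loss on soft probabilities vs a label mask.

    Per class: TI_c = (TP_c + ε) / (TP_c + α·FP_c + β·FN_c + ε) on soft
    probabilities against the one-hot target; the loss is
    Σ_c w_c (1 − TI_c) / Σ_c w_c.  With α = β = 0.5 this is the soft-Dice
    complement.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be nonnegative")
    if isinstance(pred, SoftPrediction):
        pred = pred.probs
    if isinstance(target, LabelMask):
        target = target.labels
    probs = pred
    C = probs.shape[0]
    pdim = probs.data.ndim if isinstance(probs, Tensor) else np.ndim(probs)
    t = np.asarray(target)
    onehot = t.astype(np.float64) if t.ndim == pdim else _onehot(t, C)
    if weights is None:
        weights = np.ones(C)
    total, wsum = None, float(np.sum(weights))
    for c in range(C):
        p, t = probs[c], onehot[c]
        tp = (p * t).sum()
        fp = (p * (1.0 - t)).sum()
        fn = ((1.0 - p) * t).sum()
        ti = (tp + eps) / (tp + alpha * fp + beta * fn + eps)
        term = (1.0 - ti) * float(weights[c])
        total = term if total is None else total + term
    return total * (1.0 / wsum)


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

def augment_pair(img: np.ndarray, labels: np.ndarray,
                 rng: np.random.Generator,
                 rot_deg: float = 15.0, scale=(0.85, 1.25),
                 elastic_amp: float = 2.0, elastic_smooth: float = 8.0,
                 brightness: float = 0.2, contrast=(0.8, 1.2)):
    """Random rotation/scale/elastic + intensity jitter (image linear, mask NN)."""
    H, W = img.shape
    th = np.deg2rad(rng.uniform(-rot_deg, rot_deg))
    sc = rng.uniform(*scale)
    A = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]) / sc
    ctr = np.array([(H - 1) / 2, (W - 1) / 2])
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    u = random_smooth_field((H, W), elastic_amp, elastic_smooth, rng)
    pr, pc = rr - ctr[0] + u[0], cc - ctr[1] + u[1]
    coords = np.stack([A[0, 0] * pr + A[0, 1] * pc + ctr[0],
                       A[1, 0] * pr + A[1, 1] * pc + ctr[1]])
    img_a = map_coordinates(img, coords, order=1, mode="constant")
    lab_a = map_coordinates(labels, coords, order=0, mode="constant", cval=0)
    img_a = img_a * rng.uniform(*contrast) + rng.uniform(-brightness,
                                                         brightness)
    return img_a, lab_a


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _norm_slice(sl: np.ndarray) -> np.ndarray:
    sd = sl.std()
    return (sl - sl.mean()) / sd if sd > 0 else np.zeros_like(sl)


def _scheme_labels(labels5: np.ndarray, scheme: ClassScheme) -> np.ndarray:
    if scheme.name == KIDNEY3.name:
        return collapse_to_kidney3(labels5)
    return labels5


def training_slices(studies, scheme: ClassScheme, contrasts=None):
    """(image, labels) slice pairs; 5-class training excludes ADC."""
    pairs = []
    for st in studies:
        for contrast, vol in st.volumes.items():
            if contrasts is not None and contrast not in contrasts:
                continue
            if scheme.name == SUBREGION5.name and contrast == "ADC":
                continue
            labels = _scheme_labels(st.masks[contrast].labels, scheme)
            for s in range(vol.data.shape[0]):
                if labels[s].sum() == 0:
                    continue
                pairs.append((_norm_slice(vol.data[s]), labels[s]))
    return pairs


def _foreground_dice(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    a, b = pred_labels > 0, true_labels > 0
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * (a & b).sum() / denom


def train_segmentation(init: ParameterSet | None, studies,
                       scheme: ClassScheme, epochs: int = 500,
                       iters_per_epoch: int = 250, lr: float = 0.01,
                       seed: int = 0, cfg: UNetConfig | None = None,
                       batch: int = 8, augment: bool = True,
                       val_fraction: float = 0.25,
                       contrasts=None) -> ParameterSet:
    """Fine-tune (or train from scratch) a segmentation network.

    ``init`` may hold contrastive-pretrained backbone weights; layers whose
    shapes do not match (the head) keep their fresh initialization.
    Deterministic under a fixed seed.
    """
    pairs = training_slices(studies, scheme, contrasts)
    if not pairs:
        raise ValueError("empty training set")
    if cfg is None:
        cfg = UNetConfig(in_channels=1, out_channels=scheme.n_classes)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_val = max(1, int(round(val_fraction * len(pairs)))) \
        if len(pairs) > 1 else 0
    val = [pairs[i] for i in order[:n_val]]
    train = [pairs[i] for i in order[n_val:]] or pairs

    weights = inverse_frequency_weights([p[1] for p in train], scheme)
    net = UNet(cfg, seed=seed)
    if init is not None:
        sd = net.state_dict()
        sd.update({k: np.asarray(v) for k, v in init.state.items()
                   if k in sd and sd[k].shape == np.asarray(v).shape})
        net.load_state_dict(sd)
    total = epochs * iters_per_epoch
    opt = Adam(net.parameters(), lr=lr, total_steps=total)
    from .nn import functional as F

    best_dice, best_state, val_log = -1.0, net.state_dict(), []
    for ep in range(epochs):
        net.train()
        for _ in range(iters_per_epoch):
            idx = rng.integers(len(train), size=min(batch, len(train)))
            imgs, labs = [], []
            for i in idx:
                im, lb = train[i]
                if augment:
                    im, lb = augment_pair(im, lb, rng)
                imgs.append(im)
                labs.append(lb)
            x = Tensor(np.stack(imgs)[:, None])
            probs = F.softmax_channels(net(x))
            loss = None
            for bi, lb in enumerate(labs):
                li = tversky_loss(probs[bi], lb, weights=weights)
                loss = li if loss is None else loss + li
            loss = loss * (1.0 / len(labs))
            net.zero_grad()
            loss.backward()
            opt.step()
        # validation Dice (foreground) on held-out slices
        net.eval()
        scores = []
        for im, lb in (val or train):
            logits = net(Tensor(im[None, None])).data[0]
            scores.append(_foreground_dice(logits.argmax(axis=0), lb))
        vd = float(np.mean(scores))
        val_log.append(vd)
        if vd > best_dice:
            best_dice, best_state = vd, net.state_dict()
    net.load_state_dict(best_state)
    ps = ParameterSet.from_module(net, cfg, seed=seed)
    ps.config["_val_dice"] = val_log
    ps.config["_scheme"] = scheme.name
    return ps


def predict_masks(params: ParameterSet, vol: ImageVolume,
                  scheme: ClassScheme, rec: CropRecord | None = None,
                  cfg: UNetConfig | None = None) -> LabelMask:
    """Per-slice softmax-argmax inference over a preprocessed volume.

    Argmax ties break toward the lower class index.  If a
    :class:`CropRecord` is given the mask is restored to native geometry.
    """
    if cfg is None:
        cfg = UNetConfig(**{k: v for k, v in params.config.items()
                            if not k.startswith("_")})
    net = UNet(cfg, seed=params.seed)
    params.load_into(net)
    net.eval()
    S, H, W = vol.data.shape
    cfg.check_input(H, W)
    out = np.zeros((S, H, W), dtype=np.int16)
    for s in range(S):
        logits = net(Tensor(_norm_slice(vol.data[s])[None, None])).data[0]
        out[s] = logits.argmax(axis=0)
    mask = LabelMask(out, scheme, vol.spacing_mm)
    if rec is not None:
        mask = restore_native_geometry(mask, rec)
    return mask
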