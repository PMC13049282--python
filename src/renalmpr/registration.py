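"""Pairwise registration of every contrast onto the Dixon reference.

Two cascaded stages, both driven by the shared 2-D backbone:

* an **affine stage**: encoder features → 1×1 conv → 2×2 max-pool →
  dense(16) → dense(6); the 6 outputs are deltas about the identity and
  are converted into a dense displacement field;
* a **non-rigid stage**: the full U-Net on the (fixed, affine-corrected
  moving) pair, with a displacement head of 16 then 2 filters (ReLU
  between, zero-initialized output) so training starts at zero
  displacement.  The trained affine stage is frozen during non-rigid
  training.

Losses: negative normalized mutual information (soft-binned Parzen
estimator during training, hard-binned for evaluation), a soft-Dice
guidance term on the left/right kidney masks, an L1 smoothness penalty on
the spatial gradient of the displacement, and a bidirectional consistency
term comparing each moving image with its forward-then-inverse warp, the
inverse being obtained by fixed-point iteration.  The total non-rigid
loss is ``L_NMI + λ1·L_DSC + λ2·L_smooth + λ3·L_consistency`` with
defaults λ1=1, λ2=0.1, λ3=100.

Displacement convention everywhere (fields, NIfTI export): backward /
sampling, in pixels — ``warped(x) = moving(x + u(x))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.ndimage import map_coordinates

from .nn import Tensor, stack as t_stack, concat as t_concat
from .nn import functional as F
from .backbone import UNetConfig, AffineNet, NonRigidNet, ParameterSet
from .types import (DisplacementField, ImageVolume, LabelMask, KIDNEY3,
                    REFERENCE_CONTRAST, collapse_to_kidney3)

LAMBDA_DSC = 1.0
LAMBDA_SMOOTH = 0.1
LAMBDA_CONSISTENCY = 100.0
NMI_BINS = 32
_EPS = 1e-12


# --------------------------------------------------------------------------
# fields and warping
# --------------------------------------------------------------------------

def affine_params_to_field(p: np.ndarray, grid_shape) -> DisplacementField:
    """Dense field of the affine map (I+dA | b) about the image center.

    ``p`` is the 6-vector (dA00, dA01, b_row, dA10, dA11, b_col); the
    all-zero encoding is the identity and yields the zero field.
    """
    p = np.asarray(p, dtype=np.float64).reshape(6)
    H, W = grid_shape
    rr, cc = np.meshgrid(np.arange(H, dtype=np.float64),
                         np.arange(W, dtype=np.float64), indexing="ij")
    pr, pc = rr - (H - 1) / 2.0, cc - (W - 1) / 2.0
    u = np.stack([p[0] * pr + p[1] * pc + p[2],
                  p[3] * pr + p[4] * pc + p[5]])
    return DisplacementField(u)


def _affine_field_tensor(p: Tensor, H: int, W: int) -> Tensor:
    """Differentiable version of :func:`affine_params_to_field` (B, 6)→(B,2,H,W)."""
    rr, cc = np.meshgrid(np.arange(H, dtype=np.float64),
                         np.arange(W, dtype=np.float64), indexing="ij")
    pr = Tensor((rr - (H - 1) / 2.0)[None])
    pc = Tensor((cc - (W - 1) / 2.0)[None])
    B = p.shape[0]

    def coef(i):
        return p[:, i].reshape(B, 1, 1)

    u_row = coef(0) * pr + coef(1) * pc + coef(2)
    u_col = coef(3) * pr + coef(4) * pc + coef(5)
    return t_stack([u_row, u_col], axis=1)


def warp(img_or_mask: np.ndarray, field: DisplacementField | np.ndarray,
         mode: str = "linear") -> np.ndarray:
    """Backward-warp a 2-D grid: out(x) = input(x + u(x)).

    ``linear`` (bilinear, zero border) for images, ``nearest`` (background
    border) for masks.
    """
    u = field.u if isinstance(field, DisplacementField) else np.asarray(field)
    arr = np.asarray(img_or_mask)
    H, W = arr.shape
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    coords = np.stack([rr + u[0], cc + u[1]])
    if mode == "linear":
        return map_coordinates(arr.astype(np.float64), coords, order=1,
                               mode="constant", cval=0.0)
    if mode == "nearest":
        return map_coordinates(arr, coords, order=0, mode="constant", cval=0)
    raise ValueError(f"unknown warp mode {mode!r}")


def compose_fields(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Field of warp(warp(·, outer), inner): u = inner + outer(x + inner)."""
    H, W = inner.shape[1:]
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    coords = np.stack([rr + inner[0], cc + inner[1]])
    outer_at = np.stack([map_coordinates(outer[i], coords, order=1,
                                         mode="nearest") for i in range(2)])
    return inner + outer_at


def fixed_point_inverse(u: DisplacementField | np.ndarray,
                        max_iters: int = 20,
                        tol_px: float = 0.01,
                        relax: float = 0.0) -> DisplacementField:
    """Invert a displacement field by fixed-point iteration.

    Iterates ``v_{k+1}(x) = −u(x + v_k(x))`` from v₀ = 0 with bilinear
    interpolation of u (border-replicated).  Raises if the update grows
    for three consecutive iterations (folding diagnosis).  ``relax`` > 0
    damps the update (v ← (1−relax)·v_new + relax·v), which converges on
    fields near the contraction limit of the plain iteration.
    """
    uu = u.u if isinstance(u, DisplacementField) else np.asarray(u)
    H, W = uu.shape[1:]
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    v = np.zeros_like(uu)
    prev_update, grow = np.inf, 0
    for it in range(max_iters):
        coords = np.stack([rr + v[0], cc + v[1]])
        u_at = np.stack([map_coordinates(uu[i], coords, order=1,
                                         mode="nearest") for i in range(2)])
        v_new = -u_at if relax == 0 else (1 - relax) * (-u_at) + relax * v
        update = float(np.abs(v_new - v).max())
        v = v_new
        if update > prev_update:
            grow += 1
            if grow >= 3:
                raise RuntimeError(
                    "fixed-point inversion diverged (update grew 3 "
                    "iterations in a row): the field likely folds "
                    "(non-positive Jacobian determinant)")
        else:
            grow = 0
        prev_update = update
        if update < tol_px:
            break
    return DisplacementField(v, metadata={"iters": it + 1,
                                          "last_update_px": update})


# --------------------------------------------------------------------------
# similarity: normalized mutual information
# --------------------------------------------------------------------------

def _hard_nmi(a: np.ndarray, b: np.ndarray, bins: int = NMI_BINS) -> float:
    """Plug-in NMI = 2·MI/(Ha+Hb) on quantile-edged joint histograms."""
    a, b = np.ravel(a), np.ravel(b)

    def digitize(x):
        vals = np.unique(x)
        if len(vals) == 1:
            return np.zeros(x.shape, dtype=np.intp), 1
        if len(vals) <= bins:
            # discrete data: one bin per distinct value (exact histogram)
            return np.searchsorted(vals, x), len(vals)
        edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)))
        return np.clip(np.searchsorted(edges, x, side="right") - 1,
                       0, len(edges) - 2), len(edges) - 1

    ia, na = digitize(a)
    ib, nb = digitize(b)
    joint = np.zeros((na, nb))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= joint.sum()
    pa, pb = joint.sum(axis=1), joint.sum(axis=0)
    ha = float(-(pa[pa > 0] * np.log(pa[pa > 0])).sum())
    hb = float(-(pb[pb > 0] * np.log(pb[pb > 0])).sum())
    if ha == 0.0 and hb == 0.0:
        warnings.warn("both images constant: NMI defined as 1")
        return 1.0
    if ha == 0.0 or hb == 0.0:
        warnings.warn("one image constant: NMI defined as 0")
        return 0.0
    nz = joint > 0
    mi = float((joint[nz] * (np.log(joint[nz])
                             - np.log(np.outer(pa, pb)[nz]))).sum())
    return 2.0 * mi / (ha + hb)


def nmi_similarity(a: np.ndarray, b: np.ndarray,
                   bins: int = NMI_BINS) -> float:
    """Hard-binned NMI similarity in [0, 1] (shared with the metrics suite)."""
    if np.shape(a) != np.shape(b):
        raise ValueError("shape mismatch")
    return _hard_nmi(np.asarray(a, float), np.asarray(b, float), bins)


def _soft_assign(values: Tensor | np.ndarray, lo: float, hi: float,
                 bins: int) -> Tensor:
    """Parzen soft binning: (n,1) values → (n, bins) normalized weights."""
    centers = (np.arange(bins) + 0.5) / bins
    sigma = 0.5 / bins
    scale = max(hi - lo, _EPS)
    if not isinstance(values, Tensor):
        values = Tensor(values)
    x = (values - lo) * (1.0 / scale)
    d = x - Tensor(centers[None, :])
    w = (d * d * (-0.5 / sigma ** 2)).exp()
    return w / (w.sum(axis=1, keepdims=True) + _EPS)


def _soft_nmi_pair(fixed: np.ndarray, warped: Tensor,
                   bins: int = NMI_BINS) -> Tensor:
    """Differentiable NMI between a fixed array and a warped Tensor."""
    n = fixed.size
    lo_f, hi_f = float(fixed.min()), float(fixed.max())
    lo_m = float(warped.data.min())
    hi_m = float(warped.data.max())
    wf = _soft_assign(fixed.reshape(-1, 1), lo_f, hi_f, bins).data
    wm = _soft_assign(warped.reshape(n, 1), lo_m, hi_m, bins)
    joint = Tensor(wf.T * (1.0 / n)).matmul(wm)
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    ha = -(pa * (pa + _EPS).log()).sum()
    hb = -(pb * (pb + _EPS).log()).sum()
    mi = (joint * ((joint + _EPS).log()
                   - (pa.reshape(-1, 1) * pb.reshape(1, -1) + _EPS).log())).sum()
    return (mi * 2.0) / (ha + hb + _EPS)


def nmi_loss(fixed: np.ndarray, warped_set, bins: int = NMI_BINS,
             estimator: str = "hard"):
    """−mean(NMI(fixed, warped_i)); ``estimator`` "hard" (eval) or "soft".

    The soft path accepts Tensors and is differentiable.
    """
    warped_set = list(warped_set)
    if not warped_set:
        raise ValueError("need at least one warped image")
    if estimator == "hard":
        vals = [nmi_similarity(fixed, w, bins) for w in warped_set]
        return -float(np.mean(vals))
    if estimator == "soft":
        total = None
        for w in warped_set:
            v = _soft_nmi_pair(np.asarray(fixed, float), w, bins)
            total = v if total is None else total + v
        return -(total * (1.0 / len(warped_set)))
    raise ValueError(f"unknown estimator {estimator!r}")


# --------------------------------------------------------------------------
# regularization and guidance losses
# --------------------------------------------------------------------------

def soft_dice(pred, target, eps: float = 1e-6):
    """Soft Dice between a probability map and a (soft) target, any backend."""
    inter = (pred * target).sum()
    denom = pred.sum() + target.sum()
    return (inter * 2.0 + eps) / (denom + eps)


def registration_dice_loss(fixed_onehot, warped_soft, kidney_classes=(1, 2)):
    """1 − mean soft Dice over the left/right kidney channels.

    ``fixed_onehot`` and ``warped_soft`` are (C, H, W) per-class grids
    (numpy or Tensor for the warped side).
    """
    if fixed_onehot.shape[0] < max(kidney_classes) + 1:
        raise ValueError("missing class channels for kidney Dice")
    if warped_soft.shape[0] < max(kidney_classes) + 1:
        raise ValueError("missing class channels for kidney Dice")
    total = None
    for c in kidney_classes:
        d = soft_dice(warped_soft[c], fixed_onehot[c]
                      if not isinstance(fixed_onehot, Tensor)
                      else fixed_onehot[c])
        total = d if total is None else total + d
    return 1.0 - total * (1.0 / len(kidney_classes))


def smoothness_loss(fields) -> float | Tensor:
    """Mean absolute forward-difference gradient of the fields.

    Per field: mean of |∂u/∂row| and |∂u/∂col| over all difference
    entries and both channels; averaged over the field set.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("need at least one field")
    total = None
    for f in fields:
        u = f.u if isinstance(f, DisplacementField) else f
        dr = u[:, 1:, :] - u[:, :-1, :]
        dc = u[:, :, 1:] - u[:, :, :-1]
        if isinstance(u, Tensor):
            n = dr.data.size + dc.data.size
            val = (dr.abs().sum() + dc.abs().sum()) * (1.0 / n)
        else:
            val = (np.abs(dr).sum() + np.abs(dc).sum()) / (dr.size + dc.size)
        total = val if total is None else total + val
    return total * (1.0 / len(fields))


def consistency_loss(images, forward_fields, inverse_fields):
    """Mean squared error between each image and its forward+inverse warp."""
    images = list(images)
    fwd = [f.u if isinstance(f, DisplacementField) else f
           for f in forward_fields]
    inv = [f.u if isinstance(f, DisplacementField) else f
           for f in inverse_fields]
    if not (len(images) == len(fwd) == len(inv)):
        raise ValueError("images and field sets must have equal length")
    vals = []
    for img, uf, ui in zip(images, fwd, inv):
        if img.shape != uf.shape[1:] or img.shape != ui.shape[1:]:
            raise ValueError("image/field size mismatch")
        bi = warp(warp(img, uf, "linear"), ui, "linear")
        vals.append(float(((img - bi) ** 2).mean()))
    return float(np.mean(vals))


def total_nonrigid_loss(fixed, warped_set, fixed_masks, warped_masks,
                        fields, inverses, images=None,
                        lam_dsc: float = LAMBDA_DSC,
                        lam_smooth: float = LAMBDA_SMOOTH,
                        lam_cons: float = LAMBDA_CONSISTENCY) -> float:
    """Evaluation-mode total loss: NMI + λ1·DSC + λ2·smooth + λ3·consistency.

    ``images`` defaults to ``warped_set``'s pre-warp inputs being
    unavailable here, so the consistency term uses the provided images (the
    affine-corrected moving images in training).
    """
    if images is None:
        images = warped_set
    nmi = nmi_loss(fixed, warped_set, estimator="hard")
    dsc = float(np.mean([registration_dice_loss(fm, wm)
                         for fm, wm in zip(fixed_masks, warped_masks)]))
    smooth = float(smoothness_loss(fields))
    cons = consistency_loss(images, fields, inverses)
    return nmi + lam_dsc * dsc + lam_smooth * smooth + lam_cons * cons


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _norm_slice(sl: np.ndarray) -> np.ndarray:
    sd = sl.std()
    return (sl - sl.mean()) / sd if sd > 0 else np.zeros_like(sl)


def _onehot(labels: np.ndarray, n: int) -> np.ndarray:
    return np.stack([(labels == c).astype(np.float64) for c in range(n)])


@dataclass
class _RegSample:
    fixed: np.ndarray           # normalized fixed slice (H, W)
    moving: np.ndarray          # normalized moving slice (H, W)
    fixed_mask3: np.ndarray     # (3, H, W) one-hot kidney masks
    moving_mask3: np.ndarray    # (3, H, W) one-hot kidney masks


def _study_samples(studies) -> list[_RegSample]:
    samples = []
    for study in studies:
        fvol = study.volumes[REFERENCE_CONTRAST]
        fmask = collapse_to_kidney3(study.masks[REFERENCE_CONTRAST].labels)
        for contrast, vol in study.volumes.items():
            if contrast == REFERENCE_CONTRAST:
                continue
            mmask = collapse_to_kidney3(study.masks[contrast].labels)
            for s in range(vol.data.shape[0]):
                if fmask[s].sum() == 0 and mmask[s].sum() == 0:
                    continue
                samples.append(_RegSample(
                    _norm_slice(fvol.data[s]), _norm_slice(vol.data[s]),
                    _onehot(fmask[s], 3), _onehot(mmask[s], 3)))
    if not samples:
        raise ValueError("empty training set")
    return samples


def _warp_batch(imgs: np.ndarray, field: Tensor) -> Tensor:
    return F.grid_sample_bilinear(Tensor(imgs), field)


def _batch_reg_loss(field: Tensor, batch: list[_RegSample],
                    nonrigid: bool = False,
                    moving_override: np.ndarray | None = None):
    """Shared loss assembly for both stages on one mini-batch."""
    B = len(batch)
    H, W = batch[0].fixed.shape
    moving = moving_override if moving_override is not None else \
        np.stack([s.moving for s in batch])[:, None]
    mmasks = np.stack([s.moving_mask3 for s in batch])
    warped_img = _warp_batch(moving, field)
    warped_mask = F.grid_sample_bilinear(Tensor(mmasks), field)
    loss = None
    for i, s in enumerate(batch):
        nmi = _soft_nmi_pair(s.fixed, warped_img[i, 0])
        dsc = registration_dice_loss(s.fixed_mask3, warped_mask[i])
        li = -nmi + LAMBDA_DSC * dsc
        loss = li if loss is None else loss + li
    loss = loss * (1.0 / B)
    if nonrigid:
        loss = loss + LAMBDA_SMOOTH * smoothness_loss([field[i] for i in range(B)])
        # consistency: inverse fields treated as constants (fixed-point)
        cons = None
        for i in range(B):
            try:
                u_inv = fixed_point_inverse(field.data[i], max_iters=10,
                                            tol_px=0.05).u
            except RuntimeError:
                # transient folding during optimization: fall back to the
                # first-order inverse; the consistency penalty then drives
                # the field back toward invertibility
                u_inv = -field.data[i]
            bi = F.grid_sample_bilinear(
                F.grid_sample_bilinear(Tensor(moving[i:i + 1]),
                                       field[i:i + 1]),
                Tensor(u_inv[None]))
            diff = bi - Tensor(moving[i:i + 1])
            c = (diff * diff).mean()
            cons = c if cons is None else cons + c
        loss = loss + LAMBDA_CONSISTENCY * (cons * (1.0 / B))
    return loss, warped_img


def train_registration(stage: str, init: ParameterSet | None, studies,
                       epochs: int = 1, iters_per_epoch: int = 100,
                       lr: float = 1e-3, batch: int = 8, seed: int = 0,
                       cfg: UNetConfig | None = None,
                       affine_params: ParameterSet | None = None):
    """Train the affine or non-rigid stage on phantom/cohort studies.

    The affine stage minimizes NMI + Dice; the non-rigid stage the full
    four-term loss, with the affine stage frozen.  Returns a
    :class:`ParameterSet`; runs are reproducible under a fixed seed.
    """
    if stage not in ("affine", "nonrigid"):
        raise ValueError("stage must be 'affine' or 'nonrigid'")
    samples = _study_samples(studies)
    H, W = samples[0].fixed.shape
    if cfg is None:
        cfg = UNetConfig(in_channels=2, out_channels=2)
    rng = np.random.default_rng(seed)
    total = epochs * iters_per_epoch

    if stage == "affine":
        net = AffineNet(cfg, input_size=W, seed=seed)
    else:
        if affine_params is None:
            raise ValueError("non-rigid training requires trained affine "
                             "weights (affine_params)")
        aff_cfg = _clean_cfg(affine_params.config)
        aff_net = AffineNet(aff_cfg, input_size=W, seed=affine_params.seed)
        affine_params.load_into(aff_net)
        aff_net.eval()
        net = NonRigidNet(cfg, seed=seed)
    if init is not None:
        try:
            net.load_state_dict(init.state)
        except KeyError:
            # partial init (e.g. pretrained encoder/decoder only)
            sd = net.state_dict()
            sd.update({k: v for k, v in init.state.items() if k in sd
                       and sd[k].shape == np.asarray(v).shape})
            net.load_state_dict(sd)
    from .nn import Adam
    opt = Adam(net.parameters(), lr=lr, total_steps=total)
    history = []
    for _ in range(total):
        idx = rng.integers(len(samples), size=min(batch, len(samples)))
        bt = [samples[i] for i in idx]
        fixed = np.stack([s.fixed for s in bt])[:, None]
        moving = np.stack([s.moving for s in bt])[:, None]
        if stage == "affine":
            x = np.concatenate([fixed, moving], axis=1)
            p = net(Tensor(x))
            field = _affine_field_tensor(p, H, W)
            loss, _ = _batch_reg_loss(field, bt)
        else:
            pa = aff_net(Tensor(np.concatenate([fixed, moving], axis=1)))
            ufa = _affine_field_tensor(pa, H, W).data
            mov_corr = np.stack([warp(moving[i, 0], ufa[i], "linear")
                                 for i in range(len(bt))])[:, None]
            x = np.concatenate([fixed, mov_corr], axis=1)
            field = net(Tensor(x))
            # Dice guidance needs the affine-corrected moving masks
            bt_corr = []
            for i, s in enumerate(bt):
                m3 = np.stack([warp(ch, ufa[i], "linear")
                               for ch in s.moving_mask3])
                bt_corr.append(_RegSample(s.fixed, mov_corr[i, 0],
                                          s.fixed_mask3, m3))
            loss, _ = _batch_reg_loss(field, bt_corr, nonrigid=True,
                                      moving_override=mov_corr)
        net.zero_grad()
        loss.backward()
        opt.step()
        history.append(loss.item())
    ps = ParameterSet.from_module(net, cfg, seed=seed)
    ps.config = {k: v for k, v in ps.config.items()}
    ps.config["_loss_history"] = history[-5:]
    return ps


# --------------------------------------------------------------------------
# inference: register a full study
# --------------------------------------------------------------------------

@dataclass
class RegisteredStudy:
    aligned: dict = dfield(default_factory=dict)      # contrast → ImageVolume
    fields: dict = dfield(default_factory=dict)       # contrast → per-slice dict
    propagated_masks: dict = dfield(default_factory=dict)
    skipped: list = dfield(default_factory=list)
    log: list = dfield(default_factory=list)


def _clean_cfg(cfgd: dict) -> UNetConfig:
    return UNetConfig(**{k: v for k, v in cfgd.items()
                         if not k.startswith("_")})


def register_study(affine_params: ParameterSet,
                   nonrigid_params: ParameterSet | None,
                   study) -> RegisteredStudy:
    """Align every contrast of a study to Dixon and propagate Dixon masks.

    Per contrast and slice: predict the affine field, warp, predict the
    non-rigid field on the affine-corrected pair, compose, invert the
    composite by fixed-point iteration, and warp the Dixon 5-class mask by
    the inverse (nearest-neighbor) into the moving contrast's frame.
    Missing contrasts are skipped with a log entry.
    """
    if REFERENCE_CONTRAST not in study.volumes:
        raise ValueError("reference contrast (Dixon) missing from study")
    fvol = study.volumes[REFERENCE_CONTRAST]
    dixon_mask = study.masks[REFERENCE_CONTRAST]
    H, W = fvol.data.shape[1:]
    aff_cfg = _clean_cfg(affine_params.config)
    aff_net = AffineNet(aff_cfg, input_size=W, seed=affine_params.seed)
    affine_params.load_into(aff_net)
    aff_net.eval()
    nr_net = None
    if nonrigid_params is not None:
        nr_net = NonRigidNet(_clean_cfg(nonrigid_params.config),
                             seed=nonrigid_params.seed)
        nonrigid_params.load_into(nr_net)
        nr_net.eval()

    out = RegisteredStudy()
    from .types import CONTRASTS
    for contrast in CONTRASTS:
        if contrast == REFERENCE_CONTRAST:
            continue
        if contrast not in study.volumes:
            out.skipped.append(contrast)
            out.log.append(f"{contrast}: missing, skipped")
            continue
        vol = study.volumes[contrast]
        S = vol.data.shape[0]
        aligned = np.zeros_like(vol.data)
        prop = np.zeros(vol.data.shape, dtype=np.int16)
        per_slice = []
        for s in range(S):
            fsl = _norm_slice(fvol.data[s])
            msl = _norm_slice(vol.data[s])
            x = np.stack([fsl, msl])[None]
            pa = aff_net(Tensor(x)).data[0]
            u_aff = affine_params_to_field(pa, (H, W)).u
            if nr_net is not None:
                mov_corr = warp(msl, u_aff, "linear")
                xn = np.stack([fsl, mov_corr])[None]
                u_def = nr_net(Tensor(xn)).data[0]
                u_comp = compose_fields(u_aff, u_def)
            else:
                u_def = np.zeros_like(u_aff)
                u_comp = u_aff
            try:
                u_inv = fixed_point_inverse(u_comp, max_iters=20, tol_px=0.01)
            except RuntimeError:
                try:
                    # damped retry for fields at the edge of contraction
                    u_inv = fixed_point_inverse(u_comp, max_iters=60,
                                                tol_px=0.01, relax=0.5)
                except RuntimeError:
                    u_inv = DisplacementField(
                        -u_comp, s, {"warning": "first-order inverse: "
                                     "composite field folds"})
                    out.log.append(f"{contrast}[{s}]: folding composite "
                                   "field, first-order inverse used")
            aligned[s] = warp(vol.data[s], u_comp, "linear")
            prop[s] = warp(dixon_mask.labels[s], u_inv, "nearest")
            per_slice.append({"affine": DisplacementField(u_aff, s),
                              "nonrigid": DisplacementField(u_def, s),
                              "composite": DisplacementField(u_comp, s),
                              "inverse": u_inv})
        out.aligned[contrast] = ImageVolume(aligned, vol.spacing_mm,
                                            contrast, vol.native_shape)
        out.fields[contrast] = per_slice
        out.propagated_masks[contrast] = LabelMask(prop, dixon_mask.scheme,
                                                   vol.spacing_mm)
        out.log.append(f"{contrast}: registered {S} slices")
    return out
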