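"""Constrained contrastive pre-training of the segmentation backbone.

T2 and T2* images carry strong cues about renal tissue (water content,
perfusion, oxygenation), so they drive the self-supervised stage: per
pixel, the stacked T2/T2* channels are reduced by PCA (P=20 retained
components) and clustered by k-means (K=4) into a *constraint map* that
encodes which pixels look alike.  A projection head on the U-Net embeds
each pixel into an N=64-channel space; 100 random 4×4 patches per slice
are labeled by the dominant constraint-map cluster inside them, and a
supervised-contrastive loss (L2-normalized cosine similarity, temperature
τ=0.1) pulls together patch embeddings that share a label.

After pre-training the projection head is discarded; the encoder/decoder
weights initialize the segmentation networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .nn import Tensor, Module, Conv2d, Adam, stack as t_stack
from .backbone import UNetConfig, UNet, ParameterSet

DEFAULT_P = 20
DEFAULT_K = 4
DEFAULT_TAU = 0.1
DEFAULT_N_CHANNELS = 64
DEFAULT_PATCH = 4
DEFAULT_PATCH_COUNT = 100
CONSTRAINT_SOURCES = ("T2", "T2STAR")


@dataclass
class ConstraintMap:
    labels: np.ndarray                     # (H, W) ints in 0..K-1
    K: int = DEFAULT_K
    P: int = DEFAULT_P
    source_contrasts: tuple = CONSTRAINT_SOURCES


@dataclass
class PatchBatch:
    corners: np.ndarray                    # (M, 2) top-left row/col
    size: int
    labels: np.ndarray                     # (M,) dominant cluster per patch

    @property
    def count(self) -> int:
        return len(self.labels)

    @property
    def centers(self) -> np.ndarray:
        return self.corners + (self.size - 1) / 2.0


@dataclass
class EmbeddingGrid:
    values: np.ndarray                     # (N, H, W)
    normalized: bool = False

    def normalize(self) -> "EmbeddingGrid":
        n = np.sqrt((self.values ** 2).sum(axis=0, keepdims=True))
        return EmbeddingGrid(self.values / np.maximum(n, 1e-12), True)


def build_constraint_map(feature_stack: np.ndarray, P: int = DEFAULT_P,
                         K: int = DEFAULT_K, seed: int = 0) -> ConstraintMap:
    """PCA (retain P components) + k-means (K clusters) over pixels.

    Pixels are observations, channels variables.  Cluster indices are
    canonicalized by ascending mean channel intensity of their member
    pixels, so the labeling is stable under channel permutation (label
    identity is still only meaningful up to permutation).
    """
    C, H, W = feature_stack.shape
    X = feature_stack.reshape(C, -1).T
    if np.allclose(X.std(axis=0), 0):
        warnings.warn("constant feature stack: single-cluster constraint map")
        return ConstraintMap(np.zeros((H, W), dtype=np.int32), K, P)
    ncomp = min(P, C, X.shape[0])
    Z = PCA(n_components=ncomp, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(Z)
    raw = km.labels_
    # canonical relabeling by mean original intensity per cluster
    means = np.array([X[raw == k].mean() if (raw == k).any() else np.inf
                      for k in range(K)])
    order = np.argsort(means, kind="stable")
    remap = np.empty(K, dtype=np.int32)
    remap[order] = np.arange(K)
    return ConstraintMap(remap[raw].reshape(H, W), K, P)


def sample_labeled_patches(cmap: ConstraintMap,
                           count: int = DEFAULT_PATCH_COUNT,
                           p: int = DEFAULT_PATCH,
                           seed: int = 0) -> PatchBatch:
    """Uniformly sample fully-inside p×p patches; label by majority vote.

    Ties are broken toward the lowest label index.
    """
    H, W = cmap.labels.shape
    if H < p or W < p:
        raise ValueError(f"grid {cmap.labels.shape} smaller than patch {p}")
    rng = np.random.default_rng(seed)
    corners = np.stack([rng.integers(0, H - p + 1, size=count),
                        rng.integers(0, W - p + 1, size=count)], axis=1)
    labels = np.array([dominant_label(cmap.labels, r, c, p)
                       for r, c in corners])
    return PatchBatch(corners, p, labels)


def dominant_label(labels: np.ndarray, r: int, c: int, p: int) -> int:
    """Most frequent value in the window; np.bincount argmax breaks ties low."""
    window = labels[r:r + p, c:c + p].ravel()
    return int(np.bincount(window).argmax())


def _normalize_rows(z: Tensor) -> Tensor:
    n = ((z * z).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    return z / n


def patch_embeddings(emb, patches: PatchBatch) -> Tensor:
    """Mean pixel embedding per patch window, re-normalized → (M, N)."""
    t = emb if isinstance(emb, Tensor) else Tensor(np.asarray(emb))
    p = patches.size
    rows = [t[:, r:r + p, c:c + p].mean(axis=(1, 2))
            for r, c in patches.corners]
    return _normalize_rows(t_stack(rows, axis=0))


def constrained_contrastive_loss(emb, patches: PatchBatch,
                                 tau: float = DEFAULT_TAU):
    """Supervised-contrastive loss over patch embeddings.

    For each anchor i with positive set P(i) (patches sharing its dominant
    label): Lᵢ = −(1/|P(i)|) Σ_{p∈P(i)} log[exp(zᵢ·z_p/τ) / Σ_{a≠i}
    exp(zᵢ·z_a/τ)]; the loss is the mean over anchors with non-empty P(i);
    anchors without positives are skipped.

    ``emb`` is an :class:`EmbeddingGrid` (or (N,H,W) array/Tensor of
    normalized pixel embeddings).
    """
    if patches.count == 0:
        raise ValueError("zero patches")
    if patches.count < 2:
        raise ValueError("need at least two patches")
    if isinstance(emb, EmbeddingGrid):
        if not emb.normalized:
            emb = emb.normalize()
        emb = emb.values
    z = patch_embeddings(emb, patches)
    M = patches.count
    sim = z.matmul(z.transpose((1, 0))) * (1.0 / tau)
    off_diag = 1.0 - np.eye(M)
    denom = (sim.exp() * Tensor(off_diag)).sum(axis=1)
    log_denom = denom.log()
    same = (patches.labels[:, None] == patches.labels[None, :]).astype(float)
    pos = same * off_diag
    counts = pos.sum(axis=1)
    anchors = counts > 0
    if not anchors.any():
        raise ValueError("no anchor has a positive: all labels unique")
    inv_counts = np.where(anchors, 1.0 / np.maximum(counts, 1), 0.0)
    per_anchor = ((sim - log_denom.reshape(M, 1)) * Tensor(pos)).sum(axis=1)
    loss = -(per_anchor * Tensor(inv_counts)).sum() * (1.0 / anchors.sum())
    return loss


def within_label_similarity(emb, patches: PatchBatch) -> float:
    """Mean cosine similarity between same-label patch embeddings (probe)."""
    z = patch_embeddings(emb, patches).data
    sim = z @ z.T
    same = (patches.labels[:, None] == patches.labels[None, :])
    np.fill_diagonal(same, False)
    if not same.any():
        return float("nan")
    return float(sim[same].mean())


class _CCLNet(Module):
    """U-Net + two-layer 1×1 projection head emitting N channels."""

    def __init__(self, cfg: UNetConfig, n_channels: int = DEFAULT_N_CHANNELS,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed + 7)
        self.unet = UNet(cfg, seed=seed)
        ch0 = cfg.channels()[0]
        self.ph1 = Conv2d(ch0, n_channels, 1, rng)
        self.ph2 = Conv2d(n_channels, n_channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.unet.features(x)
        return self.ph2(self.ph1(h).leaky_relu(0.01))


def _norm_slice(sl: np.ndarray) -> np.ndarray:
    sd = sl.std()
    return (sl - sl.mean()) / sd if sd > 0 else np.zeros_like(sl)


def pretrain_encoder(studies, cfg: UNetConfig | None = None,
                     epochs: int = 200, iters_per_epoch: int | None = None,
                     lr: float = 1e-3, batch: int = 8, seed: int = 0,
                     n_channels: int = DEFAULT_N_CHANNELS,
                     tau: float = DEFAULT_TAU,
                     patch_count: int = DEFAULT_PATCH_COUNT,
                     patch_size: int = DEFAULT_PATCH,
                     sources: tuple = CONSTRAINT_SOURCES) -> ParameterSet:
    """Optimize the constrained contrastive loss; return backbone weights.

    Constraint maps are built once per slice from the stacked source
    contrasts; each training sample is one source-contrast slice paired
    with its slice's constraint map and a fresh random patch batch.
    The returned :class:`ParameterSet` holds the U-Net encoder/decoder
    weights only (projection head dropped) plus a loss history.
    """
    if cfg is None:
        cfg = UNetConfig(in_channels=1, out_channels=1)
    for st in studies:
        for src in sources:
            if src not in st.volumes:
                raise ValueError(f"study missing constraint source {src}")
    samples = []  # (slice_image, ConstraintMap)
    for si, st in enumerate(studies):
        S = st.volumes[sources[0]].data.shape[0]
        for s in range(S):
            stack_ = np.stack([_norm_slice(st.volumes[src].data[s])
                               for src in sources])
            if st.masks[sources[0]].labels[s].sum() == 0:
                continue
            cmap = build_constraint_map(stack_, seed=seed + 31 * si + s)
            for src in sources:
                samples.append((_norm_slice(st.volumes[src].data[s]), cmap))
    if not samples:
        raise ValueError("no training slices found")
    net = _CCLNet(cfg, n_channels, seed=seed)

    def _probe_similarity() -> float:
        """Mean within-label cosine similarity on the first training slice."""
        img, cmap = samples[0]
        patches = sample_labeled_patches(cmap, count=patch_count,
                                         p=patch_size, seed=seed + 997)
        emb = net(Tensor(img[None, None])).data[0]
        n = np.sqrt((emb ** 2).sum(axis=0, keepdims=True))
        return within_label_similarity(emb / np.maximum(n, 1e-12), patches)

    sim_before = _probe_similarity()
    if iters_per_epoch is None:
        iters_per_epoch = max(1, len(samples) // batch)
    total = epochs * iters_per_epoch
    opt = Adam(net.parameters(), lr=lr, total_steps=total)
    rng = np.random.default_rng(seed)
    history = []
    for it in range(total):
        idx = rng.integers(len(samples), size=min(batch, len(samples)))
        loss = None
        for i in idx:
            img, cmap = samples[i]
            patches = sample_labeled_patches(
                cmap, count=patch_count, p=patch_size,
                seed=int(rng.integers(2 ** 31)))
            emb = net(Tensor(img[None, None]))[0]
            # per-pixel L2 normalization
            n = ((emb * emb).sum(axis=0, keepdims=True) + 1e-12).sqrt()
            li = constrained_contrastive_loss(emb / n, patches, tau)
            loss = li if loss is None else loss + li
        loss = loss * (1.0 / len(idx))
        net.zero_grad()
        loss.backward()
        opt.step()
        history.append(loss.item())
    ps = ParameterSet.from_module(net.unet, cfg, seed=seed)
    ps.config["_loss_history"] = history
    ps.config["_probe_sim"] = (float(sim_before), float(_probe_similarity()))
    ps.config["_ccl"] = {"P": DEFAULT_P, "K": DEFAULT_K, "tau": tau,
                         "patch": patch_size, "count": patch_count,
                         "N": n_channels, "seed": seed}
    return ps
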