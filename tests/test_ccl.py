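"""Constraint maps, patch sampling and the contrastive loss."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from renalmpr.ccl import (build_constraint_map, sample_labeled_patches,
                          constrained_contrastive_loss, dominant_label,
                          patch_embeddings, within_label_similarity,
                          ConstraintMap, PatchBatch, EmbeddingGrid)


class TestConstraintMap:
    def test_four_pure_signatures_recovered_exactly(self):
        """Noise-free 4-region stack: clusters coincide with the regions.

        Verified against the ground-truth partition (ARI = 1) and against
        a brute-force nearest-centroid assignment.
        """
        truth = np.repeat(np.repeat(np.arange(4).reshape(2, 2), 8, 0), 8, 1)
        sigs = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        stack = sigs[truth].transpose(2, 0, 1)  # (2, 16, 16)
        cmap = build_constraint_map(stack, seed=0)
        assert adjusted_rand_score(truth.ravel(),
                                   cmap.labels.ravel()) == 1.0
        # brute-force nearest-centroid assignment reproduces the labeling
        X = stack.reshape(2, -1).T
        cents = np.stack([X[cmap.labels.ravel() == k].mean(axis=0)
                          for k in range(4)])
        nearest = np.argmin(((X[:, None] - cents[None]) ** 2).sum(-1), axis=1)
        assert np.array_equal(nearest, cmap.labels.ravel())

    def test_constant_stack_single_cluster_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            cmap = build_constraint_map(np.ones((3, 8, 8)), seed=0)
        assert set(np.unique(cmap.labels)) == {0}

    def test_defaults_K4_P20(self):
        cmap = build_constraint_map(np.random.default_rng(0)
                                    .standard_normal((2, 8, 8)), seed=0)
        assert cmap.K == 4 and cmap.P == 20

    def test_stable_under_channel_permutation(self, rng):
        stack = rng.standard_normal((4, 12, 12))
        a = build_constraint_map(stack, seed=0)
        b = build_constraint_map(stack[::-1].copy(), seed=0)
        assert adjusted_rand_score(a.labels.ravel(), b.labels.ravel()) == 1.0


class TestPatchSampling:
    def test_uniform_map_gives_uniform_labels(self):
        cmap = ConstraintMap(np.full((16, 16), 2, dtype=np.int32))
        pb = sample_labeled_patches(cmap, count=20, seed=0)
        assert (pb.labels == 2).all()
        # fully inside the grid
        assert (pb.corners >= 0).all() and (pb.corners + pb.size <= 16).all()

    def test_tie_breaks_to_lowest_label(self):
        """4×4 window split 8/8 between labels 2 and 3 → label 2."""
        window = np.zeros((4, 4), dtype=np.int32)
        window[:2] = 2
        window[2:] = 3
        assert dominant_label(window, 0, 0, 4) == 2

    def test_grid_smaller_than_patch_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            sample_labeled_patches(
                ConstraintMap(np.zeros((3, 3), dtype=np.int32)), p=4)


def _two_cluster_batch(M=8):
    """M patches in two label-pure groups with orthogonal embeddings."""
    H = 8
    emb = np.zeros((2, H, H))
    emb[0, :, :4] = 1.0   # left half → e1
    emb[1, :, 4:] = 1.0   # right half → e2
    corners = np.array([[r, c] for r in (0, 4) for c in (0, 1, 4, 5)])
    labels = np.array([0 if c < 4 else 1 for _, c in corners])
    return emb, PatchBatch(corners[:M], 2, labels[:M])


class TestContrastiveLoss:
    def test_identical_embeddings_same_label_gives_log_M_minus_1(self):
        M = 6
        emb = np.ones((3, 8, 8)) / np.sqrt(3)
        pb = PatchBatch(np.zeros((M, 2), dtype=int) + np.arange(M)[:, None] % 4,
                        2, np.zeros(M, dtype=int))
        loss = constrained_contrastive_loss(emb, pb, tau=0.1)
        assert abs(loss.item() - np.log(M - 1)) < 1e-9

    def test_invariant_to_positive_scaling(self):
        emb, pb = _two_cluster_batch()
        l1 = constrained_contrastive_loss(
            EmbeddingGrid(emb).normalize(), pb).item()
        l2 = constrained_contrastive_loss(
            EmbeddingGrid(emb * 7.3).normalize(), pb).item()
        assert abs(l1 - l2) < 1e-9

    def test_pure_clustering_beats_shuffled_and_matches_brute_force(self):
        emb, pb = _two_cluster_batch()
        tau = 0.1
        pure = constrained_contrastive_loss(
            EmbeddingGrid(emb).normalize(), pb, tau).item()
        shuffled = PatchBatch(pb.corners, pb.size,
                              np.array([0, 1, 0, 1, 1, 0, 1, 0]))
        mixed = constrained_contrastive_loss(
            EmbeddingGrid(emb).normalize(), shuffled, tau).item()
        assert pure < mixed

        # brute-force pairwise summation oracle
        z = patch_embeddings(EmbeddingGrid(emb).normalize().values, pb).data
        M = len(z)
        total, n_anchor = 0.0, 0
        for i in range(M):
            pos = [j for j in range(M)
                   if j != i and pb.labels[j] == pb.labels[i]]
            if not pos:
                continue
            n_anchor += 1
            denom = sum(np.exp(z[i] @ z[a] / tau) for a in range(M) if a != i)
            total += -np.mean([np.log(np.exp(z[i] @ z[p] / tau) / denom)
                               for p in pos])
        assert abs(pure - total / n_anchor) < 1e-9

    def test_invariant_to_patch_order_and_embedding_rotation(self, rng):
        emb, pb = _two_cluster_batch()
        base = constrained_contrastive_loss(
            EmbeddingGrid(emb).normalize(), pb).item()
        perm = rng.permutation(len(pb.labels))
        pb2 = PatchBatch(pb.corners[perm], pb.size, pb.labels[perm])
        assert abs(base - constrained_contrastive_loss(
            EmbeddingGrid(emb).normalize(), pb2).item()) < 1e-9
        # global rotation preserves cosine similarities
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = np.einsum("ij,jhw->ihw", R, emb)
        assert abs(base - constrained_contrastive_loss(
            EmbeddingGrid(rot).normalize(), pb).item()) < 1e-9

    def test_zero_patches_rejected(self):
        with pytest.raises(ValueError):
            constrained_contrastive_loss(
                np.ones((2, 8, 8)),
                PatchBatch(np.zeros((0, 2), dtype=int), 2,
                           np.zeros(0, dtype=int)))


def test_within_label_similarity_probe_orders_embeddings():
    emb, pb = _two_cluster_batch()
    good = within_label_similarity(EmbeddingGrid(emb).normalize().values, pb)
    noisy = np.random.default_rng(0).standard_normal(emb.shape)
    bad = within_label_similarity(EmbeddingGrid(noisy).normalize().values, pb)
    assert good > bad
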