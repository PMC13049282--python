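"""Evaluation metrics against brute-force and third-party oracles."""

import numpy as np
import pytest

from renalmpr.metrics import (dice_score, dice_per_class, hausdorff_mm,
                              nmi_similarity, dpca_index,
                              jacobian_nonpositive_pct, agreement_stats)
from renalmpr.phantom import random_smooth_field
from renalmpr.registration import warp
from renalmpr.types import DisplacementField


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.random((6, 6)) > 0.5
        assert dice_score(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0], b[2] = True, True
        assert dice_score(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:4], b[2:6] = True, True
        assert dice_score(a, b) == 0.5  # 2·2/(4+4)

    def test_both_empty_flagged_one(self):
        with pytest.warns(UserWarning, match="empty"):
            assert dice_score(np.zeros((3, 3), bool),
                              np.zeros((3, 3), bool)) == 1.0

    def test_symmetric_and_padding_invariant(self, rng):
        a = rng.random((5, 5)) > 0.4
        b = rng.random((5, 5)) > 0.6
        assert dice_score(a, b) == dice_score(b, a)
        ap = np.pad(a, 3)
        bp = np.pad(b, 3)
        assert dice_score(ap, bp) == dice_score(a, b)


class TestHausdorff:
    def test_identical_masks_zero_mm(self, rng):
        m = np.zeros((8, 8), bool)
        m[2:6, 2:6] = True
        assert hausdorff_mm(m, m, (1.5, 1.5)) == 0.0

    def test_two_voxels_three_apart(self):
        a = np.zeros((1, 8, 8), bool)
        b = np.zeros((1, 8, 8), bool)
        a[0, 2, 2], b[0, 5, 2] = True, True
        assert hausdorff_mm(a, b, (3.0, 1.5, 1.5)) == pytest.approx(4.5)

    def test_empty_mask_names_side(self):
        m = np.ones((4, 4), bool)
        with pytest.raises(ValueError, match="second"):
            hausdorff_mm(m, np.zeros((4, 4), bool), (1.0, 1.0))

    def test_matches_brute_force_on_random_shapes(self, rng):
        """Exhaustive max-min over boundary pairs on small random masks."""
        from scipy.ndimage import binary_erosion
        for _ in range(10):
            a = rng.random((10, 10)) > 0.6
            b = rng.random((10, 10)) > 0.6
            if not a.any() or not b.any():
                continue
            sp = (2.0, 0.5)
            got = hausdorff_mm(a, b, sp)
            def boundary(m):
                return np.argwhere(m & ~binary_erosion(m, border_value=0)) \
                    * np.array(sp)
            ca, cb = boundary(a), boundary(b)
            d = np.sqrt(((ca[:, None] - cb[None]) ** 2).sum(-1))
            assert got == pytest.approx(max(d.min(1).max(), d.min(0).max()))

    def test_spacing_equivariance(self, rng):
        a = rng.random((8, 8)) > 0.5
        b = rng.random((8, 8)) > 0.5
        if a.any() and b.any():
            assert hausdorff_mm(a, b, (2.0, 2.0)) == \
                pytest.approx(2 * hausdorff_mm(a, b, (1.0, 1.0)))


class TestDPCA:
    def test_identical_images_residual_zero(self, rng):
        img = rng.standard_normal((16, 16))
        series = [img + 1e-9 * rng.standard_normal(img.shape)
                  for _ in range(5)]
        assert dpca_index(series, topK=1) < 1e-6

    def test_independent_noise_residual_near_L_minus_K(self, rng):
        L, K = 6, 1
        series = [rng.standard_normal((80, 80)) for _ in range(L)]
        assert abs(dpca_index(series, topK=K) - (L - K)) < 0.25

    def test_topk_ratio_form_bounded(self, rng):
        series = [rng.standard_normal((20, 20)) for _ in range(4)]
        r = dpca_index(series, topK=2, form="topk_ratio")
        assert 0 < r <= 1

    def test_misalignment_increases_index(self, rng):
        """Aligned copies of one texture score lower than shifted copies."""
        base = rng.standard_normal((48, 48))
        from scipy.ndimage import gaussian_filter, shift
        base = gaussian_filter(base, 2.0)
        aligned = [base + 0.05 * rng.standard_normal(base.shape)
                   for _ in range(4)]
        shifted = [shift(b, (2.0 * i, -1.5 * i), order=1)
                   for i, b in enumerate(aligned)]
        assert dpca_index(aligned, topK=1) < dpca_index(shifted, topK=1)

    def test_constant_image_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            dpca_index([np.ones((4, 4)), rng.standard_normal((4, 4))])


class TestJacobian:
    def test_zero_field_no_folding(self):
        assert jacobian_nonpositive_pct(np.zeros((2, 8, 8))) == 0.0

    def test_one_axis_fold_everywhere(self):
        """u_row = −2·row: det(I+∇u) = −1 at every pixel."""
        u = np.zeros((2, 8, 8))
        u[0] = -2.0 * np.arange(8)[:, None]
        assert jacobian_nonpositive_pct(u) == 100.0

    def test_matches_brute_force_determinant_scan(self, rng):
        u = random_smooth_field((12, 12), 4.0, 2.0, rng)
        got = jacobian_nonpositive_pct(u)
        dr = np.gradient(u[0])
        dc = np.gradient(u[1])
        count = 0
        for i in range(12):
            for j in range(12):
                det = (1 + dr[0][i, j]) * (1 + dc[1][i, j]) \
                    - dr[1][i, j] * dc[0][i, j]
                count += det <= 0
        assert got == pytest.approx(100.0 * count / 144)


class TestAgreement:
    def test_identical_measurements(self):
        s = agreement_stats([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert s.bias == 0.0 and s.loa == (0.0, 0.0)
        assert s.icc == 1.0 and s.pearson_r == 1.0

    def test_constant_offset(self):
        s = agreement_stats([1.0, 2.0, 3.0], [2.5, 3.5, 4.5])
        assert s.bias == pytest.approx(1.5)
        assert s.loa[1] - s.loa[0] == pytest.approx(0.0)

    def test_icc_matches_anova_mean_squares_oracle(self, rng):
        """6 random pairs: ICC(2,1) from hand-computed two-way ANOVA."""
        m = rng.normal(50, 10, 6)
        a = m + rng.normal(0, 3, 6)
        s = agreement_stats(m, a)
        Y = np.stack([m, a], axis=1)
        n, k = Y.shape
        msr = k * ((Y.mean(1) - Y.mean()) ** 2).sum() / (n - 1)
        msc = n * ((Y.mean(0) - Y.mean()) ** 2).sum() / (k - 1)
        mse = (((Y - Y.mean(1, keepdims=True) - Y.mean(0) + Y.mean()) ** 2)
               .sum()) / ((n - 1) * (k - 1))
        icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert s.icc == pytest.approx(icc, abs=1e-12)

    def test_icc_and_ci_match_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        m = rng.normal(100, 20, 8)
        a = m + rng.normal(2, 5, 8)
        s = agreement_stats(m, a)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(8), 2),
            "raters": ["m", "a"] * 8,
            "score": np.stack([m, a], 1).ravel()})
        res = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="score")
        row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        assert s.icc == pytest.approx(row["ICC"], abs=1e-9)
        ci = row[[c for c in res.columns if c.startswith("CI95")][0]]
        assert s.icc_ci[0] == pytest.approx(ci[0], abs=0.01)
        assert s.icc_ci[1] == pytest.approx(ci[1], abs=0.01)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            agreement_stats([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_flagged(self):
        s = agreement_stats([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert s.icc == 1.0  # identical inputs override the degenerate ANOVA
        s2 = agreement_stats([3.0, 3.0, 3.0], [4.0, 4.0, 4.0])
        assert np.isnan(s2.icc) and s2.flags
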