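"""Field algebra, warping, similarity and loss components for registration."""

import numpy as np
import pytest

from renalmpr.nn import Tensor
from renalmpr.registration import (affine_params_to_field, warp,
                                   fixed_point_inverse, compose_fields,
                                   nmi_similarity, nmi_loss, _soft_nmi_pair,
                                   registration_dice_loss, smoothness_loss,
                                   consistency_loss, total_nonrigid_loss,
                                   soft_dice, LAMBDA_DSC, LAMBDA_SMOOTH,
                                   LAMBDA_CONSISTENCY)
from renalmpr.phantom import random_smooth_field
from renalmpr.types import DisplacementField


class TestAffineField:
    def test_identity_params_zero_field(self):
        f = affine_params_to_field(np.zeros(6), (32, 32))
        assert np.allclose(f.u, 0.0)

    def test_pure_translation_constant_field(self):
        f = affine_params_to_field([0, 0, 3.0, 0, 0, -2.0], (16, 16))
        assert np.allclose(f.u[0], 3.0) and np.allclose(f.u[1], -2.0)

    def test_rotation_matches_per_pixel_matrix_oracle(self):
        """90° rotation about center, checked pixel-by-pixel."""
        H = W = 256
        # A = R(90°): dA = R − I
        p = [-1.0, -1.0, 0.0, 1.0, -1.0, 0.0]
        f = affine_params_to_field(p, (H, W))
        c = np.array([(H - 1) / 2, (W - 1) / 2])
        R = np.array([[0.0, -1.0], [1.0, 0.0]])
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        xy = np.stack([rr - c[0], cc - c[1]])
        expect = np.einsum("ij,jhw->ihw", R, xy) - xy
        assert np.allclose(f.u, expect)
        corner = f.u[:, 0, 0]
        assert np.allclose(corner, R @ (-c) + c)


class TestWarp:
    def test_zero_field_identity(self, rng):
        img = rng.standard_normal((12, 12))
        z = DisplacementField(np.zeros((2, 12, 12)))
        assert np.allclose(warp(img, z, "linear"), img)
        assert np.array_equal(warp(img.astype(int), z, "nearest"),
                              img.astype(int))

    def test_integer_translation_nearest_is_shift(self, rng):
        img = rng.integers(0, 9, (8, 8))
        u = np.zeros((2, 8, 8))
        u[0] = 2.0   # sample from 2 rows below
        out = warp(img, u, "nearest")
        assert np.array_equal(out[:6], img[2:])
        assert (out[6:] == 0).all()  # background border policy

    def test_linear_warp_of_ramp_matches_analytic(self, rng):
        """Bilinear warp of a bilinear ramp = ramp evaluated at x+u."""
        H = W = 16
        rr, cc = np.meshgrid(np.arange(H, dtype=float),
                             np.arange(W, dtype=float), indexing="ij")
        ramp = 2.0 * rr + 3.0 * cc + 1.0
        u = random_smooth_field((H, W), 1.5, 4.0, rng)
        out = warp(ramp, u, "linear")
        expect = 2.0 * (rr + u[0]) + 3.0 * (cc + u[1]) + 1.0
        interior = (rr + u[0] >= 0) & (rr + u[0] <= H - 1) & \
                   (cc + u[1] >= 0) & (cc + u[1] <= W - 1)
        assert np.allclose(out[interior], expect[interior], atol=1e-9)

    def test_invalid_mode_rejected(self, rng):
        with pytest.raises(ValueError, match="mode"):
            warp(rng.standard_normal((4, 4)), np.zeros((2, 4, 4)), "cubic")


class TestNMI:
    def test_self_similarity_is_one(self, rng):
        img = rng.standard_normal((32, 32))
        assert abs(nmi_similarity(img, img) - 1.0) < 1e-12
        assert abs(nmi_loss(img, [img]) + 1.0) < 1e-12

    def test_independent_noise_near_zero(self, rng):
        a = rng.standard_normal((128, 128))
        b = rng.standard_normal((128, 128))
        assert nmi_similarity(a, b, bins=32) <= 0.05

    def test_matches_exhaustive_joint_histogram(self, rng):
        """8×8 integer images vs a brute-force plug-in computation."""
        a = rng.integers(0, 4, (8, 8)).astype(float)
        b = rng.integers(0, 4, (8, 8)).astype(float)
        got = nmi_similarity(a, b, bins=4)
        joint = np.zeros((4, 4))
        for x, y in zip(a.ravel().astype(int), b.ravel().astype(int)):
            joint[x, y] += 1
        joint /= joint.sum()
        pa, pb = joint.sum(1), joint.sum(0)
        H = lambda p: -(p[p > 0] * np.log(p[p > 0])).sum()
        mi = sum(joint[i, j] * np.log(joint[i, j] / (pa[i] * pb[j]))
                 for i in range(4) for j in range(4) if joint[i, j] > 0)
        assert abs(got - 2 * mi / (H(pa) + H(pb))) < 1e-12

    def test_symmetric_and_invariant_to_monotone_remap(self, rng):
        a = rng.standard_normal((64, 64))
        b = a + 0.5 * rng.standard_normal((64, 64))
        assert abs(nmi_similarity(a, b) - nmi_similarity(b, a)) < 1e-12
        # strictly monotone remap; quantile bin edges make NMI invariant
        assert abs(nmi_similarity(np.exp(a), b) -
                   nmi_similarity(a, b)) < 1e-12

    def test_degenerate_constant_images(self):
        with pytest.warns(UserWarning, match="constant"):
            assert nmi_similarity(np.ones((4, 4)), np.ones((4, 4))) == 1.0
        with pytest.warns(UserWarning, match="constant"):
            assert nmi_similarity(np.ones((4, 4)),
                                  np.arange(16.0).reshape(4, 4)) == 0.0

    def test_soft_estimator_tracks_hard_on_alignment(self, rng):
        """Soft NMI is higher for aligned than shuffled pairs."""
        img = rng.standard_normal((32, 32))
        aligned = _soft_nmi_pair(img, Tensor(img + 0.01)).item()
        shuffled = _soft_nmi_pair(img, Tensor(
            rng.permutation(img.ravel()).reshape(32, 32))).item()
        assert aligned > shuffled


class TestGuidanceLosses:
    def test_dice_loss_zero_for_identical_onehot(self):
        onehot = np.zeros((3, 6, 6))
        onehot[0] = 1.0
        onehot[0, 2:4, 2:4] = 0.0
        onehot[1, 2:4, 2:3] = 1.0
        onehot[2, 2:4, 3:4] = 1.0
        assert registration_dice_loss(onehot, onehot) < 1e-5

    def test_dice_loss_one_for_disjoint(self):
        a = np.zeros((3, 4, 4))
        b = np.zeros((3, 4, 4))
        a[1, 0], a[2, 1] = 1.0, 1.0
        b[1, 2], b[2, 3] = 1.0, 1.0
        assert registration_dice_loss(a, b) > 1.0 - 1e-4

    def test_dice_loss_matches_duplicate_implementation(self, rng):
        a = rng.random((3, 5, 5))
        b = rng.random((3, 5, 5))
        got = registration_dice_loss(a, b)
        ds = []
        for c in (1, 2):
            inter = (a[c] * b[c]).sum()
            ds.append((2 * inter + 1e-6) /
                      (a[c].sum() + b[c].sum() + 1e-6))
        assert abs(got - (1 - np.mean(ds))) < 1e-6

    def test_missing_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="class"):
            registration_dice_loss(rng.random((2, 4, 4)),
                                   rng.random((3, 4, 4)))

    def test_smoothness_constant_field_zero(self):
        assert smoothness_loss([np.ones((2, 8, 8)) * 4.2]) == 0.0

    def test_smoothness_unit_ramp(self):
        u = np.zeros((2, 6, 6))
        u[0] = np.arange(6)[:, None]
        got = smoothness_loss([u])
        # forward differences: |∂u_row/∂row| = 1 on (H-1)*W entries,
        # everything else 0; normalized over all difference entries
        n = 2 * (5 * 6 + 6 * 5)
        assert abs(got - (5 * 6) / n) < 1e-12

    def test_smoothness_matches_brute_force(self, rng):
        u = rng.standard_normal((2, 7, 9))
        got = smoothness_loss([u])
        total, n = 0.0, 0
        for ch in range(2):
            for i in range(6):
                for j in range(9):
                    total += abs(u[ch, i + 1, j] - u[ch, i, j])
                    n += 1
            for i in range(7):
                for j in range(8):
                    total += abs(u[ch, i, j + 1] - u[ch, i, j])
                    n += 1
        assert abs(got - total / n) < 1e-10


class TestFixedPointInverse:
    def test_zero_field(self):
        v = fixed_point_inverse(np.zeros((2, 8, 8)))
        assert np.allclose(v.u, 0.0)
        assert v.metadata["iters"] == 1

    def test_constant_translation_inverts_exactly(self):
        u = np.zeros((2, 16, 16))
        u[0], u[1] = 2.5, -1.25
        v = fixed_point_inverse(u)
        # interior pixels see the exact constant; borders replicate
        assert np.allclose(v.u[0], -2.5) and np.allclose(v.u[1], 1.25)

    def test_composition_residual_small_on_smooth_fields(self, rng):
        """Residual max‖u(x+v(x)) + v(x)‖ < 0.1 px (direct composition)."""
        for k in range(5):
            u = random_smooth_field((64, 64), 3.0, 12.0,
                                    np.random.default_rng(100 + k))
            v = fixed_point_inverse(u, max_iters=30, tol_px=1e-3)
            comp = compose_fields(u, v.u)
            interior = (slice(4, 60), slice(4, 60))
            res = np.sqrt((comp[(slice(None),) + interior] ** 2).sum(axis=0))
            assert res.max() < 0.1

    def test_inverse_of_inverse_recovers_field(self, rng):
        # the residual is limited by bilinear interpolation of the field,
        # not the fixed-point tolerance
        u = random_smooth_field((48, 48), 2.0, 10.0, rng)
        v = fixed_point_inverse(u, max_iters=40, tol_px=1e-4)
        w = fixed_point_inverse(v.u, max_iters=40, tol_px=1e-4)
        interior = (slice(None), slice(6, 42), slice(6, 42))
        assert np.abs(w.u[interior] - u[interior]).max() < 0.01


def _windowed_field(shape, amp, smooth, rng):
    """Smooth random field tapered to zero at the borders (Hann window),
    so the zero-padding border policy plays no role in the check."""
    u = random_smooth_field(shape, amp, smooth, rng)
    return u * (np.hanning(shape[0])[:, None] * np.hanning(shape[1]))


class TestConsistencyAndTotal:
    def test_zero_fields_zero_loss(self, rng):
        img = rng.standard_normal((16, 16))
        z = np.zeros((2, 16, 16))
        assert consistency_loss([img], [z], [z]) == 0.0

    def test_constant_image_invariant(self, rng):
        img = np.full((32, 32), 3.3)
        u = _windowed_field((32, 32), 2.0, 10.0, rng)
        v = fixed_point_inverse(u).u
        # resampling a constant with in-grid sampling is exact
        assert consistency_loss([img], [u], [v]) < 1e-20

    def test_forward_then_inverse_nearly_identity(self, rng):
        H = W = 64
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        img = np.sin(rr / 6.0) * np.cos(cc / 7.0)
        u = _windowed_field((H, W), 3.0, 12.0, rng)
        v = fixed_point_inverse(u, max_iters=40, tol_px=1e-4).u
        assert consistency_loss([img], [u], [v]) < 1e-3 * img.var()

    def test_total_loss_is_hand_sum_of_components(self, rng):
        img_f = rng.standard_normal((24, 24))
        img_m = rng.standard_normal((24, 24))
        u = random_smooth_field((24, 24), 2.0, 8.0, rng)
        v = fixed_point_inverse(u).u
        warped = warp(img_m, u, "linear")
        fm = np.zeros((3, 24, 24))
        fm[1, 4:12, 4:12] = 1.0
        fm[2, 12:20, 12:20] = 1.0
        wm = np.stack([warp(fm[c], u, "linear") for c in range(3)])
        total = total_nonrigid_loss(img_f, [warped], [fm], [wm], [u], [v],
                                    images=[img_m])
        hand = (nmi_loss(img_f, [warped])
                + LAMBDA_DSC * registration_dice_loss(fm, wm)
                + LAMBDA_SMOOTH * smoothness_loss([u])
                + LAMBDA_CONSISTENCY * consistency_loss([img_m], [u], [v]))
        assert abs(total - hand) < 1e-10

    def test_lambda_defaults(self):
        assert (LAMBDA_DSC, LAMBDA_SMOOTH, LAMBDA_CONSISTENCY) == (1, 0.1, 100)

    def test_identity_on_identical_inputs_gives_minus_one(self, rng):
        img = rng.standard_normal((16, 16))
        z = np.zeros((2, 16, 16))
        fm = np.zeros((3, 16, 16))
        fm[1, 2:8, 2:8] = 1.0
        fm[2, 8:14, 8:14] = 1.0
        total = total_nonrigid_loss(img, [img], [fm], [fm], [z], [z],
                                    images=[img])
        assert abs(total + 1.0) < 1e-9
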