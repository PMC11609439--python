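"""Class-region normalization, FR refinement, region masks and the FCA loss."""

import numpy as np
import pytest

from unwseg.autodiff import Tensor
from unwseg.fca import (FCA, ClassAffine, class_region_normalize,
                        highlight_class, FeatureRefine, RegionMaskHead,
                        region_normalize, fca_loss)
from unwseg.primitives import instance_normalize


def region_norm_oracle(F, labels, beta=0.0):
    """Loop reference: standardize each (sample, channel, class) region."""
    out = F.astype(np.float64).copy()
    N, K, H, W = F.shape
    for n in range(N):
        for c in np.unique(labels[n]):
            sel = labels[n] == c
            for k in range(K):
                vals = F[n, k][sel]
                mu = vals.mean()
                var = ((vals - mu) ** 2).mean()
                out[n, k][sel] = (vals - mu) / np.sqrt(var + beta)
    return out


class TestClassRegionNormalize:
    def test_row_example(self):
        F = np.array([[[[1.0, 3.0, 10.0, 14.0]]]])
        labels = np.array([[[0, 0, 1, 1]]])
        out = class_region_normalize(F, labels, beta=0)
        np.testing.assert_allclose(out, [[[[-1.0, 1.0, -1.0, 1.0]]]],
                                   atol=1e-12)

    def test_single_global_class_reduces_to_instance_norm(self, rng):
        F = rng.standard_normal((2, 3, 6, 5))
        labels = np.zeros((2, 6, 5), dtype=int)
        np.testing.assert_allclose(class_region_normalize(F, labels,
                                                          beta=1e-4),
                                   instance_normalize(F, beta=1e-4),
                                   atol=1e-6)

    def test_matches_loop_oracle_on_random_maps(self, rng):
        # beta > 0: a random region can be a single pixel (zero variance)
        for _ in range(100):
            F = rng.standard_normal((2, 3, 4, 4))
            labels = rng.integers(0, 3, size=(2, 4, 4))
            got = class_region_normalize(F, labels, beta=1e-3)
            want = region_norm_oracle(F, labels, beta=1e-3)
            np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-9)

    def test_region_stats_standardized(self, rng):
        F = rng.standard_normal((2, 4, 8, 8))
        labels = rng.integers(0, 2, size=(2, 8, 8))
        out = class_region_normalize(F, labels, beta=0)
        for n in range(2):
            for c in range(2):
                sel = labels[n] == c
                region = out[n, :, sel]
                np.testing.assert_allclose(region.mean(axis=0), 0, atol=1e-10)
                np.testing.assert_allclose(region.var(axis=0), 1, atol=1e-6)

    def test_affine_applied_per_class_channel(self, rng):
        F = rng.standard_normal((1, 2, 4, 4))
        labels = np.zeros((1, 4, 4), dtype=int)
        labels[0, 2:] = 1
        affine = ClassAffine(2, 2)
        affine.scale.data = np.array([[2.0, 3.0], [4.0, 5.0]],
                                     dtype=np.float32)
        affine.shift.data = np.array([[1.0, -1.0], [0.5, 0.0]],
                                     dtype=np.float32)
        out = class_region_normalize(F, labels, affine=affine, beta=0)
        plain = class_region_normalize(F, labels, beta=0)
        for c, rows in ((0, slice(0, 2)), (1, slice(2, 4))):
            for k in range(2):
                np.testing.assert_allclose(
                    out[0, k, rows],
                    plain[0, k, rows] * affine.scale.data[c, k]
                    + affine.shift.data[c, k], rtol=1e-5, atol=1e-6)

    def test_absent_class_leaves_features_finite(self, rng):
        F = rng.standard_normal((2, 2, 4, 4))
        labels = np.zeros((2, 4, 4), dtype=int)
        labels[1] = 1  # class 1 absent from sample 0, class 0 from sample 1
        out = class_region_normalize(F, labels, beta=0.01)
        assert np.isfinite(out).all()

    def test_misaligned_shapes_rejected(self):
        with pytest.raises(ValueError):
            class_region_normalize(np.zeros((1, 2, 4, 4)),
                                   np.zeros((1, 3, 3), dtype=int))


class TestHighlight:
    def test_identity_and_zero_masks(self, rng):
        F = rng.standard_normal((2, 3, 4, 4))
        M = np.zeros((2, 2, 4, 4))
        M[:, 0] = 1.0
        maps = highlight_class(F, M)
        np.testing.assert_array_equal(maps[0], F)
        np.testing.assert_array_equal(maps[1], 0.0)

    def test_binary_partition_sums_to_input(self, rng):
        F = rng.standard_normal((2, 3, 4, 4))
        lab = rng.integers(0, 3, size=(2, 4, 4))
        M = np.moveaxis(np.eye(3)[lab], -1, 1)
        maps = highlight_class(F, M)
        np.testing.assert_allclose(sum(maps), F, atol=1e-12)


class TestFeatureRefine:
    def test_zero_conv_gives_half_gate(self, rng):
        fr = FeatureRefine(np.random.default_rng(0))
        fr.conv.weight.data[:] = 0
        fr.conv.bias.data[:] = 0
        Fc = rng.standard_normal((1, 3, 4, 4))
        Mc = rng.random((1, 1, 4, 4))
        out = fr(Tensor(Fc), Tensor(Mc))
        np.testing.assert_allclose(out.data, 1.5 * Fc, rtol=1e-6)

    def test_channel_pooling_matches_loop(self, rng):
        from unwseg.autodiff import channel_max
        Fc = rng.standard_normal((2, 5, 3, 3))
        mx = channel_max(Tensor(Fc)).data
        mn = Fc.mean(axis=1, keepdims=True)
        for n in range(2):
            for i in range(3):
                for j in range(3):
                    assert mx[n, 0, i, j] == max(Fc[n, k, i, j]
                                                 for k in range(5))
                    assert mn[n, 0, i, j] == pytest.approx(
                        sum(Fc[n, k, i, j] for k in range(5)) / 5)

    def test_output_shape(self, rng):
        fr = FeatureRefine(np.random.default_rng(1))
        Fc = rng.standard_normal((2, 4, 6, 6))
        out = fr(Tensor(Fc), Tensor(np.ones((2, 1, 6, 6))))
        assert out.shape == Fc.shape


class TestRegionMask:
    def test_zero_head_is_empty_at_default_threshold(self, rng):
        head = RegionMaskHead(np.random.default_rng(0))
        head.conv.weight.data[:] = 0
        head.conv.bias.data[:] = 0
        mask = head(Tensor(rng.standard_normal((1, 3, 4, 4))))
        assert mask.sum() == 0  # sigmoid(0) = 0.5 < t = 0.8

    def test_bias_above_logit_of_t_includes_pixels(self, rng):
        head = RegionMaskHead(np.random.default_rng(0))
        head.conv.weight.data[:] = 0
        head.conv.bias.data[:] = np.log(0.8 / 0.2) + 0.01
        mask = head(Tensor(rng.standard_normal((1, 3, 4, 4))))
        assert mask.all()

    def test_threshold_monotonicity(self, rng):
        Fc = rng.standard_normal((2, 4, 6, 6))
        head = RegionMaskHead(np.random.default_rng(3), t=0.8)
        m08 = head(Tensor(Fc))
        head.t = 0.9
        m09 = head(Tensor(Fc))
        assert (m09 <= m08).all()

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            RegionMaskHead(np.random.default_rng(0), t=1.5)


class TestRegionNormalize:
    def test_all_ones_mask_equals_global_class_norm(self, rng):
        F = rng.standard_normal((2, 3, 4, 4))
        mask = np.ones((2, 1, 4, 4), dtype=int)
        got = region_normalize(F, mask, beta=1e-4)
        want = instance_normalize(F, beta=1e-4)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_all_zero_mask_is_identity(self, rng):
        F = rng.standard_normal((2, 3, 4, 4))
        out = region_normalize(F, np.zeros((2, 1, 4, 4), dtype=int))
        np.testing.assert_array_equal(out, F)

    def test_partial_mask_row_example(self):
        F = np.array([[[[1.0, 3.0, 10.0, 14.0]]]])
        mask = np.array([[[[0, 0, 1, 1]]]])
        out = region_normalize(F, mask, beta=0)
        np.testing.assert_allclose(out, [[[[1.0, 3.0, -1.0, 1.0]]]],
                                   atol=1e-12)

    def test_masked_out_positions_bit_identical(self, rng):
        F = rng.standard_normal((2, 3, 8, 8))
        F[0, 0, 0, 0] = -0.0  # signed zero survives pass-through
        mask = (rng.random((2, 1, 8, 8)) > 0.5).astype(int)
        out = region_normalize(F, mask, beta=1e-5)
        outside = ~mask.astype(bool)[:, 0]
        for n in range(2):
            for k in range(3):
                a = np.asarray(out)[n, k][outside[n]]
                b = F[n, k][outside[n]]
                assert a.tobytes() == b.tobytes()

    def test_nonbinary_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            region_normalize(rng.standard_normal((1, 2, 4, 4)),
                             np.full((1, 1, 4, 4), 0.5))


class TestFcaLoss:
    def test_perfect_prediction_and_alignment_is_zero(self, rng):
        lab = rng.integers(0, 2, size=(1, 4, 4))
        M = np.moveaxis(np.eye(2)[lab], -1, 1)
        F = rng.standard_normal((1, 3, 4, 4))
        assert fca_loss(M, lab, F, F) == pytest.approx(0.0, abs=1e-12)

    def test_half_confidence_single_pixel_is_ln2(self):
        M = np.array([[[[0.5]], [[0.5]]]])
        lab = np.zeros((1, 1, 1), dtype=int)
        F = np.ones((1, 2, 1, 1))
        assert fca_loss(M, lab, F, F) == pytest.approx(np.log(2), rel=1e-12)

    def test_l1_term_normalized_by_elements(self, rng):
        lab = np.zeros((1, 2, 2), dtype=int)
        M = np.moveaxis(np.eye(2)[lab], -1, 1)
        F = np.zeros((1, 2, 2, 2))
        G = np.full((1, 2, 2, 2), 3.0)
        assert fca_loss(M, lab, F, G) == pytest.approx(3.0)

    def test_decreases_to_ce_floor_as_alignment_improves(self, rng):
        lab = rng.integers(0, 2, size=(1, 3, 3))
        M = np.full((1, 2, 3, 3), 0.5)
        F = rng.standard_normal((1, 2, 3, 3))
        G = rng.standard_normal((1, 2, 3, 3))
        losses = [fca_loss(M, lab, F + t * (G - F), G)
                  for t in (0.0, 0.5, 0.9, 1.0)]
        assert losses == sorted(losses, reverse=True)
        assert losses[-1] == pytest.approx(np.log(2), rel=1e-9)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            fca_loss(np.full((1, 2, 1, 1), 1.5), np.zeros((1, 1, 1), int),
                     np.ones((1, 1, 1, 1)), np.ones((1, 1, 1, 1)))


class TestFcaForward:
    def _fca(self, K=6, C=2, seed=0):
        return FCA(C, K, np.random.default_rng(seed))

    def test_inference_returns_fbar_only(self, rng):
        fca = self._fca()
        F = rng.standard_normal((2, 6, 8, 8)).astype(np.float32)
        M = np.full((2, 2, 8, 8), 0.5, dtype=np.float32)
        F_bar, FC, loss = fca(F, M)
        assert F_bar.shape == F.shape
        assert FC is None and loss is None
        assert np.isfinite(F_bar.data).all()

    def test_training_call_returns_finite_loss(self, rng):
        fca = self._fca()
        F = rng.standard_normal((2, 6, 8, 8)).astype(np.float32)
        lab = rng.integers(0, 2, size=(2, 8, 8))
        M = np.moveaxis(np.eye(2, dtype=np.float32)[lab], -1, 1)
        F_bar, FC, loss = fca(Tensor(F), Tensor(M), lab)
        assert np.isfinite(float(loss.data))
        assert np.isfinite(F_bar.data).all() and np.isfinite(FC.data).all()

    def test_fbar_equals_branch_sum_outside_all_masks(self, rng):
        """Pass-through: only masked-in positions deviate from the FR sum."""
        fca = self._fca(seed=4)
        F = rng.standard_normal((1, 6, 8, 8)).astype(np.float32)
        M = np.full((1, 2, 8, 8), 0.5, dtype=np.float32)
        branches = highlight_class(Tensor(F), Tensor(M))
        refined, masks = [], []
        for c, Fc in enumerate(branches):
            Fcc = fca.refiners[c](Fc, Tensor(M[:, c:c + 1]))
            refined.append(Fcc)
            masks.append(fca.mask_heads[c](Fcc))
        F_bar, _, _ = fca(F, M)
        untouched = ~np.any(np.concatenate(masks, axis=1).astype(bool),
                            axis=1)
        expect = sum(r.data for r in refined)
        np.testing.assert_array_equal(
            F_bar.data[:, :, untouched[0]], expect[:, :, untouched[0]])

    def test_deterministic_given_parameters(self, rng):
        fca = self._fca(seed=5)
        F = rng.standard_normal((1, 6, 8, 8)).astype(np.float32)
        M = np.full((1, 2, 8, 8), 0.5, dtype=np.float32)
        a = fca(F, M)[0].data
        b = fca(F, M)[0].data
        np.testing.assert_array_equal(a, b)

    def test_wrong_label_shape_rejected(self, rng):
        fca = self._fca()
        F = rng.standard_normal((1, 6, 8, 8)).astype(np.float32)
        M = np.full((1, 2, 8, 8), 0.5, dtype=np.float32)
        with pytest.raises(ValueError):
            fca(F, M, np.zeros((1, 4, 4), dtype=int))
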