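"""X-Grad-CAM: channel weights, maps, normalization, gradient oracles."""

import numpy as np
import pytest

from pathcam.att_cnn import ModelSpec, build_model, compute_class_weights
from pathcam.xgradcam import (FeatureMapBundle, activation_map,
                              normalize_and_upsample,
                              normalize_pair_and_upsample, xgrad_weights)


def _bundle(F, G, class_index=1):
    return FeatureMapBundle(np.asarray(F, float), np.asarray(G, float),
                            np.zeros((np.asarray(F).shape[0], 2)), class_index)


def test_single_pixel_weight_equals_gradient():
    # K=1, one pixel, F=f != 0, S = w*f  ->  alpha = (f/f) * w = w
    F = np.full((1, 1, 1, 1), 3.0)
    G = np.full((1, 1, 1, 1), -1.7)
    np.testing.assert_allclose(xgrad_weights(_bundle(F, G)), [[-1.7]])


def test_uniform_map_with_sum_scorer_gives_unit_weight():
    # F = c0 on N pixels, S = sum(F): each term (c0/(N c0)) * 1, summed -> 1
    F = np.full((1, 1, 4, 5), 0.37)
    G = np.ones_like(F)
    np.testing.assert_allclose(xgrad_weights(_bundle(F, G)), [[1.0]])


def test_zero_feature_map_yields_zero_weight():
    F = np.zeros((1, 2, 3, 3))
    G = np.ones_like(F)
    np.testing.assert_allclose(xgrad_weights(_bundle(F, G)), [[0.0, 0.0]])


def test_linear_scorer_recovers_exact_channel_weights():
    """For S_c = sum_k w_k sum_xy F_k, the weights are exactly w and the
    weighted activation sums conserve the score."""
    rng = np.random.default_rng(0)
    F = rng.random((3, 4, 5, 2))
    w = rng.standard_normal(4)
    G = np.broadcast_to(w[None, :, None, None], F.shape)
    alpha = xgrad_weights(_bundle(F, G))
    np.testing.assert_allclose(alpha, np.tile(w, (3, 1)), atol=1e-10)
    score = np.einsum("nk,nk->n", alpha, F.sum(axis=(2, 3)))
    np.testing.assert_allclose(score, F.sum(axis=(2, 3)) @ w, atol=1e-10)


def test_activation_map_weighted_sum_hand_case():
    F = np.array([[[[1.0, 2.0], [3.0, 4.0]],
                   [[5.0, 6.0], [7.0, 8.0]]]])
    alpha = np.array([[2.0, -1.0]])
    expected = 2 * F[0, 0] - F[0, 1]
    np.testing.assert_array_equal(activation_map(_bundle(F, F), alpha)[0],
                                  expected)


def test_activation_map_zero_weights_zero_map():
    F = np.random.default_rng(1).random((2, 3, 4, 4))
    M = activation_map(_bundle(F, F), np.zeros((2, 3)))
    np.testing.assert_array_equal(M, 0.0)


def test_weight_length_mismatch_rejected():
    F = np.zeros((1, 3, 2, 2))
    with pytest.raises(ValueError, match="weights"):
        activation_map(_bundle(F, F), np.zeros((1, 2)))


def test_constant_map_normalizes_to_zero():
    out = normalize_and_upsample(np.full((3, 3), 2.5), (6, 6))
    np.testing.assert_array_equal(out, 0.0)


def test_normalization_preserves_argmax_without_upsampling():
    rng = np.random.default_rng(2)
    M = rng.standard_normal((5, 5))
    out = normalize_and_upsample(M, (5, 5))
    assert np.unravel_index(out.argmax(), out.shape) == \
        np.unravel_index(M.argmax(), M.shape)
    assert out.min() == 0.0 and out.max() == 1.0


def test_bilinear_upsampling_matches_hand_computation():
    """2x2 -> 4x4 align-corners grid: value(y, x) = 2y + x on the unit
    square, sampled at {0, 1/3, 2/3, 1}."""
    M = np.array([[0.0, 1.0], [2.0, 3.0]])
    out = normalize_and_upsample(M / 3.0, (4, 4)) * 1.0  # M/3 already in [0,1]
    g = np.array([0, 1 / 3, 2 / 3, 1.0])
    expected = (2 * g[:, None] + g[None, :]) / 3.0
    np.testing.assert_allclose(out, expected, atol=1e-6)


def test_normalized_map_invariant_under_positive_affine():
    rng = np.random.default_rng(3)
    M = rng.standard_normal((4, 6))
    a = normalize_and_upsample(M, (8, 12))
    b = normalize_and_upsample(3.7 * M + 11.0, (8, 12))
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_pair_normalization_shares_scale():
    rng = np.random.default_rng(4)
    M1 = rng.random((2, 5, 3)) + 1.0
    M0 = rng.random((2, 5, 3))        # strictly below M1's range top
    L1, L0 = normalize_pair_and_upsample(M1, M0, (5, 3))
    assert L1.max() == pytest.approx(1.0)
    assert L0.min() == pytest.approx(0.0)
    # relative ordering between the two maps is preserved
    assert ((M1 > M0) == (L1 > L0)).all()


@pytest.fixture(scope="module")
def toy_setup():
    spec = ModelSpec(in_channels=2, image_height=8, image_width=2,
                     n_covariates=0, conv_filters=4, dense_units=6,
                     dropout=0.0, seed=1)
    model = build_model(spec)
    # nudge weights away from init symmetry
    rng = np.random.default_rng(5)
    for k in model.params:
        model.params[k] += 0.05 * rng.standard_normal(model.params[k].shape)
    x = rng.random((1, 2, 8, 2))
    return spec, model, x


class TestEndToEndOracle:
    """Full X-Grad-CAM against a brute-force finite-difference pipeline on a
    toy model (2 channels, 8x2 images)."""

    @staticmethod
    def _tail_logits(model, spec, relu_out):
        """Independent re-implementation of pool -> dense -> logits."""
        p = model.params
        n, F, H, W = relu_out.shape
        ph, pw = min(2, H), min(2, W)
        Hp, Wp = H // ph, W // pw
        pooled = np.zeros((n, F, Hp, Wp))
        for i in range(Hp):
            for j in range(Wp):
                win = relu_out[:, :, i * ph:(i + 1) * ph, j * pw:(j + 1) * pw]
                pooled[:, :, i, j] = win.mean(axis=(2, 3)) + win.max(axis=(2, 3))
        u = pooled.reshape(n, -1)
        hid = np.maximum(u @ p["fc1_W"] + p["fc1_b"], 0.0)
        return hid @ p["fc2_W"] + p["fc2_b"]

    def test_feature_gradients_match_finite_differences(self, toy_setup):
        spec, model, x = toy_setup
        _, cache = model.forward(x)
        relu = cache["relu"]
        feats, grads, _ = model.features_and_logit_gradient(x, None, 1,
                                                            layer="conv")
        eps = 1e-5
        rng = np.random.default_rng(6)
        # avoid ReLU zeros: tied maxima in a pooling window put the central
        # difference on a kink where the one-sided derivatives differ
        valid = np.flatnonzero(relu.reshape(-1) > 1e-3)
        flat_idx = rng.choice(valid, size=min(40, valid.size), replace=False)
        for idx in flat_idx:
            pert = relu.copy().reshape(-1)
            pert[idx] += eps
            up = self._tail_logits(model, spec, pert.reshape(relu.shape))[0, 1]
            pert[idx] -= 2 * eps
            dn = self._tail_logits(model, spec, pert.reshape(relu.shape))[0, 1]
            fd = (up - dn) / (2 * eps)
            an = grads.reshape(-1)[idx]
            assert an == pytest.approx(fd, rel=1e-3, abs=1e-6)

    def test_full_map_matches_bruteforce_loops(self, toy_setup):
        spec, model, x = toy_setup
        feats, grads, _ = model.features_and_logit_gradient(x, None, 1,
                                                            layer="conv")
        alpha = xgrad_weights(FeatureMapBundle(feats, grads,
                                               np.zeros((1, 2)), 1))
        M = activation_map(FeatureMapBundle(feats, grads,
                                            np.zeros((1, 2)), 1), alpha)
        # brute force: explicit loops over channels and pixels
        K, H, W = feats.shape[1:]
        alpha_bf = np.zeros(K)
        for k in range(K):
            denom = feats[0, k].sum()
            if denom != 0:
                for i in range(H):
                    for j in range(W):
                        alpha_bf[k] += (feats[0, k, i, j] / denom) * grads[0, k, i, j]
        M_bf = np.zeros((H, W))
        for k in range(K):
            M_bf += alpha_bf[k] * feats[0, k]
        np.testing.assert_allclose(alpha[0], alpha_bf, rtol=1e-3, atol=1e-10)
        np.testing.assert_allclose(M[0], M_bf, rtol=1e-3, atol=1e-10)

    def test_zero_input_zero_bias_gives_zero_features(self, toy_setup):
        spec, model, x = toy_setup
        model2 = build_model(spec)
        model2.set_params(model.params)
        model2.params["conv_b"][:] = 0.0
        feats, _, _ = model2.features_and_logit_gradient(
            np.zeros_like(x), None, 1, layer="conv")
        np.testing.assert_allclose(feats, 0.0, atol=1e-12)

    def test_invalid_layer_lists_valid_ones(self, toy_setup):
        spec, model, x = toy_setup
        with pytest.raises(ValueError, match="conv, attended_input"):
            model.features_and_logit_gradient(x, None, 1, layer="bogus")
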