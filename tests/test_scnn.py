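"""Super-resolution network: upscaling, convolution, ISTA layer, training."""

import numpy as np
import pytest

from pulmotex.scnn import (
    SCNNConfig,
    bicubic_upscale,
    conv_relu,
    enhance_image,
    init_params,
    ista_sparse_code,
    lasso_objective,
    lipschitz_bound,
    loss_and_gradients,
    mse_loss,
    scnn_forward,
    soft_threshold,
    train_scnn,
)
from pulmotex.types import GrayImage

TINY = SCNNConfig(
    factor=2, f1=3, n1=4, m_atoms=6, n2=4, f4=3, patch=2, stride=1, k_iters=3, alpha0=0.05
)


class TestBicubic:
    def test_output_shape(self):
        out = bicubic_upscale(GrayImage(np.zeros((8, 8))), 2)
        assert out.pixels.shape == (16, 16)

    def test_constant_preserved(self):
        out = bicubic_upscale(GrayImage(np.full((8, 8), 3.7)), 3)
        assert np.allclose(out.pixels, 3.7, atol=1e-9)

    def test_smooth_signal_roundtrip_beats_shuffled(self):
        ramp = np.add.outer(np.linspace(0, 1, 16), np.linspace(0, 1, 16)) * 100
        img = GrayImage(ramp)
        low = GrayImage(ramp.reshape(8, 2, 8, 2).mean(axis=(1, 3)))
        up = bicubic_upscale(low, 2).pixels
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(ramp.ravel()).reshape(16, 16)
        assert np.mean((up - ramp) ** 2) < np.mean((up - shuffled) ** 2)

    def test_bad_factor_rejected(self):
        with pytest.raises(ValueError):
            bicubic_upscale(GrayImage(np.zeros((8, 8))), 5)


class TestConv:
    def test_identity_1x1(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 8, 8))
        out = conv_relu(x, np.ones((1, 1, 1, 1)), np.zeros(1), relu=False)
        assert np.allclose(out, x)

    def test_relu_zeroes_negative_preactivation(self):
        x = np.ones((1, 8, 8))
        out = conv_relu(x, -np.ones((1, 1, 3, 3)), np.zeros(1), relu=True)
        assert np.all(out == 0)

    def test_matches_quadruple_loop_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 9, 9))
        filt = rng.normal(size=(3, 2, 5, 5))
        bias = rng.normal(size=3)
        out = conv_relu(x, filt, bias, relu=False)
        oracle = np.zeros((3, 5, 5))
        for o in range(3):
            for r in range(5):
                for c in range(5):
                    acc = bias[o]
                    for ch in range(2):
                        for u in range(5):
                            for v in range(5):
                                acc += x[ch, r + u, c + v] * filt[o, ch, u, v]
                    oracle[o, r, c] = acc
        assert np.allclose(out, oracle, atol=1e-10)

    def test_filter_larger_than_input_rejected(self):
        with pytest.raises(ValueError):
            conv_relu(np.zeros((1, 4, 4)), np.zeros((1, 1, 5, 5)), np.zeros(1))


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "v,theta,expected", [(1.2, 0.5, 0.7), (-0.3, 0.5, 0.0), (-2.0, 0.5, -1.5)]
    )
    def test_worked_values(self, v, theta, expected):
        assert soft_threshold(np.array([v]), theta)[0] == pytest.approx(expected)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.array([1.0]), -0.1)


class TestISTA:
    def test_orthonormal_dictionary_closed_form(self):
        """With an orthonormal dictionary the lasso minimiser is the
        soft-thresholded projection; one ISTA step from zero hits it."""
        D = np.eye(2)
        z = ista_sparse_code(np.array([1.0, 0.2]), D, 0.5, 1, L=1.0)
        assert np.allclose(z, [0.5, 0.0], atol=1e-8)

    def test_full_shrinkage_returns_zero(self):
        rng = np.random.default_rng(0)
        D = rng.normal(size=(6, 4))
        D /= np.linalg.norm(D, axis=0)
        x = rng.normal(size=6)
        alpha = float(np.abs(D.T @ x).max()) * lipschitz_bound(D) + 1.0
        assert np.all(ista_sparse_code(x, D, alpha, 5) == 0)

    def test_objective_nonincreasing_over_iterations(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n, m = rng.integers(4, 10), rng.integers(4, 10)
            D = rng.normal(size=(n, m))
            D /= np.linalg.norm(D, axis=0)
            x = rng.normal(size=n)
            objs = [
                lasso_objective(x, D, ista_sparse_code(x, D, 0.1, k), 0.1)
                for k in range(1, 6)
            ]
            assert all(a >= b - 1e-10 for a, b in zip(objs, objs[1:]))

    def test_converges_to_reference_solver(self):
        """Long ISTA agrees with an independently coded proximal-gradient
        solver run to tight tolerance."""
        rng = np.random.default_rng(2)
        D = rng.normal(size=(8, 5))
        D /= np.linalg.norm(D, axis=0)
        x = rng.normal(size=8)
        alpha = 0.05
        L = lipschitz_bound(D)
        z_ref = np.zeros(5)
        for _ in range(20000):  # reference: plain proximal gradient
            g = D.T @ (D @ z_ref - x)
            w = z_ref - g / L
            z_ref = np.sign(w) * np.maximum(np.abs(w) - alpha / L, 0)
        z = ista_sparse_code(x, D, alpha, 20000)
        assert np.allclose(z, z_ref, atol=1e-6)


class TestForwardAndLoss:
    def test_output_shape_matches_upscaled_input(self):
        params = init_params(TINY, seed=0)
        out = scnn_forward(GrayImage(np.random.default_rng(0).uniform(0, 1, (8, 8))), params)
        assert out.pixels.shape == (16, 16)

    def test_deterministic_forward(self):
        params = init_params(TINY, seed=1)
        img = GrayImage(np.random.default_rng(1).uniform(0, 1, (8, 8)))
        a = scnn_forward(img, params)
        b = scnn_forward(img, params)
        assert np.array_equal(a.pixels, b.pixels)

    @pytest.mark.parametrize(
        "pred,target,expected",
        [
            (np.zeros((4, 4)), np.zeros((4, 4)), 0.0),
            (np.ones((4, 4)), np.zeros((4, 4)), 1.0),
            (np.concatenate([np.full(8, 2.0), np.zeros(8)]).reshape(4, 4), np.zeros((4, 4)), 2.0),
        ],
    )
    def test_mse_values(self, pred, target, expected):
        assert mse_loss(pred, target) == pytest.approx(expected)

    def test_mse_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((4, 4)), np.zeros((4, 5)))


class TestInit:
    def test_biases_zero_and_reproducible(self):
        p1 = init_params(TINY, seed=4)
        p2 = init_params(TINY, seed=4)
        assert np.all(p1.b1 == 0) and p1.b4 == 0
        assert np.array_equal(p1.F1, p2.F1) and np.array_equal(p1.Dlow, p2.Dlow)

    def test_filter_sd_matches_spec(self):
        cfg = SCNNConfig(n1=200, f1=9)  # ~16k weights
        p = init_params(cfg, seed=0)
        assert 0.0005 < p.F1.std() < 0.0015

    def test_dictionary_columns_unit_norm(self):
        p = init_params(TINY, seed=0)
        assert np.allclose(np.linalg.norm(p.Dlow, axis=0), 1.0)
        assert np.allclose(np.linalg.norm(p.DHigh, axis=0), 1.0)

    def test_lipschitz_bound_dominates_gram(self):
        p = init_params(TINY, seed=2)
        eig = np.linalg.eigvalsh(p.Dlow.T @ p.Dlow)[-1]
        assert p.L >= eig


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        """Central finite differences on a tiny network agree with the
        analytic backward pass to 1e-4 relative, block by block."""
        rng = np.random.default_rng(0)
        params = init_params(TINY, seed=1)
        # move off the prescribed near-zero init so activations are alive
        # and away from ReLU/shrinkage kinks
        params.F1 = rng.normal(0, 0.5, params.F1.shape)
        params.b1 = rng.normal(0, 0.1, params.b1.shape)
        params.F3 = rng.normal(0, 0.5, params.F3.shape)
        params.b3 = rng.normal(0, 0.1, params.b3.shape)
        params.F4 = rng.normal(0, 0.5, params.F4.shape)
        params.b4 = 0.13
        params.refresh_lipschitz()
        low = rng.uniform(0.2, 0.8, (8, 8))
        high = rng.uniform(0.2, 0.8, (16, 16))
        _, grads = loss_and_gradients(params, [low], [high])
        eps = 1e-6
        for name in params._BLOCKS:
            val = getattr(params, name)
            if np.isscalar(val):
                entries = [None]
            else:
                entries = rng.choice(val.size, min(5, val.size), replace=False)
            for i in entries:
                if i is None:
                    setattr(params, name, val + eps)
                    lp, _ = loss_and_gradients(params, [low], [high])
                    setattr(params, name, val - eps)
                    lm, _ = loss_and_gradients(params, [low], [high])
                    setattr(params, name, val)
                    analytic = grads[name]
                else:
                    flat = val.ravel()
                    orig = flat[i]
                    flat[i] = orig + eps
                    lp, _ = loss_and_gradients(params, [low], [high])
                    flat[i] = orig - eps
                    lm, _ = loss_and_gradients(params, [low], [high])
                    flat[i] = orig
                    analytic = grads[name].ravel()[i]
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - analytic) <= 1e-4 * max(abs(fd), abs(analytic), 1e-8), name


@pytest.fixture(scope="module")
def patch_pairs():
    from pulmotex.synthetic import generate_phantom

    rng = np.random.default_rng(0)
    img, _ = generate_phantom("malignant", 128, seed=1)
    pairs = []
    for _ in range(16):
        r, c = rng.integers(0, 112, 2)
        hi = GrayImage(img.pixels[r : r + 16, c : c + 16])
        lo = GrayImage(hi.pixels.reshape(8, 2, 8, 2).mean(axis=(1, 3)))
        pairs.append((lo, hi))
    return pairs


class TestTraining:
    def test_zero_learning_rate_flat_trace(self, patch_pairs):
        cfg = SCNNConfig(
            factor=2, f1=5, n1=4, m_atoms=8, n2=4, f4=3, patch=2, stride=1,
            learning_rate=0.0, epochs=3,
        )
        _, trace = train_scnn(patch_pairs, cfg, seed=0)
        assert np.ptp(trace) == 0.0

    def test_same_seed_same_trace(self, patch_pairs):
        cfg = SCNNConfig(
            factor=2, f1=5, n1=4, m_atoms=8, n2=4, f4=3, patch=2, stride=1,
            learning_rate=1e-3, epochs=3,
        )
        _, t1 = train_scnn(patch_pairs, cfg, seed=5)
        _, t2 = train_scnn(patch_pairs, cfg, seed=5)
        assert np.array_equal(t1, t2)

    def test_too_few_pairs_rejected(self, patch_pairs):
        with pytest.raises(ValueError):
            train_scnn(patch_pairs[:4], SCNNConfig(), seed=0)

    def test_enhance_respects_intensity_range(self, patch_pairs):
        params = init_params(
            SCNNConfig(factor=2, f1=5, n1=4, m_atoms=8, n2=4, f4=3, patch=2, stride=1),
            seed=0,
        )
        out = enhance_image(patch_pairs[0][0], params)
        assert out.pixels.min() >= 0 and out.pixels.max() <= 255
        assert out.pixels.shape == (16, 16)
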