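"""Grad-CAM and Deep-SHAP contracts on constructed and random models."""

import numpy as np
import pytest

from apneaflow.cnn import CNNRegressor, ModelConfig
from apneaflow.explain import (
    _forward_with_grads,
    _normalize_resize,
    deep_shap,
    grad_cam_aggregate,
    grad_cam_layer,
    localization_score,
)
from apneaflow.simulate import EventAnnotation


def make_passthrough_bn(blk):
    """Make inference batch-norm the identity."""
    blk["bn"].running_mean[:] = 0.0
    blk["bn"].running_var[:] = 1.0 - blk["bn"].eps
    blk["bn"].gamma[:] = 1.0
    blk["bn"].beta[:] = 0.0


def make_linear_model(w: np.ndarray, c: float) -> CNNRegressor:
    """A CNN whose output is exactly w'x + c: the +/- channel pair splits the
    signal, ReLU passes each part, and the head recombines them linearly."""
    L = w.size
    cfg = ModelConfig(n_blocks=1, n_filters=2, pool=1, r_drop=0.0,
                      input_length=L, dtype="float64")
    m = CNNRegressor(cfg, seed=0)
    blk = m.blocks[0]
    blk["conv"].W[:] = 0.0
    blk["conv"].W[cfg.kernel // 2, 0, 0] = 1.0
    blk["conv"].W[cfg.kernel // 2, 0, 1] = -1.0
    blk["conv"].b[:] = 0.0
    make_passthrough_bn(blk)
    head = np.zeros((L, 2))
    head[:, 0] = w
    head[:, 1] = -w
    m.head.W = head.reshape(1, -1)
    m.head.b = np.array([c])
    return m


@pytest.fixture(scope="module")
def small_model():
    """Random (untrained) small CNN; attribution contracts are weight-free."""
    cfg = ModelConfig(n_blocks=3, n_filters=6, r_drop=0.1, input_length=480)
    return CNNRegressor(cfg, seed=9)


class TestGradCam:
    def test_layer_maps_nonnegative_and_correct_length(self, small_model):
        rng = np.random.default_rng(0)
        x = rng.normal(size=480)
        # post-ReLU (pre-pool) maps live at the block's incoming length
        lengths = [480, 240, 120]
        for b in range(3):
            cam = grad_cam_layer(small_model, x, b)
            assert cam.shape == (lengths[b],)
            assert np.all(cam >= 0)

    def test_invalid_block_index(self, small_model):
        with pytest.raises(ValueError):
            grad_cam_layer(small_model, np.zeros(480), 3)

    def test_zero_head_gives_zero_maps(self):
        cfg = ModelConfig(n_blocks=2, n_filters=4, r_drop=0.0, input_length=64)
        m = CNNRegressor(cfg, seed=0)
        m.head.W[:] = 0.0
        x = np.random.default_rng(1).normal(size=64)
        for b in range(2):
            assert np.all(grad_cam_layer(m, x, b) == 0)
        assert np.all(grad_cam_aggregate(m, x) == 0)

    def test_aggregate_in_unit_interval_with_input_length(self, small_model):
        rng = np.random.default_rng(2)
        for _ in range(5):
            final = grad_cam_aggregate(small_model, rng.normal(size=480))
            assert final.shape == (480,)
            assert final.min() >= 0.0 and final.max() <= 1.0

    def test_single_block_aggregate_equals_own_map(self):
        cfg = ModelConfig(n_blocks=1, n_filters=4, r_drop=0.0, input_length=64)
        m = CNNRegressor(cfg, seed=3)
        x = np.random.default_rng(3).normal(size=64)
        cam = grad_cam_layer(m, x, 0)
        assert np.allclose(grad_cam_aggregate(m, x), _normalize_resize(cam, 64), atol=1e-7)

    def test_normalize_resize_behaviour(self):
        assert np.array_equal(_normalize_resize(np.zeros(10), 20), np.zeros(20))
        # same-length map: pure min-max normalization
        out = _normalize_resize(np.array([1.0, 3.0, 2.0]), 3)
        assert np.allclose(out, [0.0, 1.0, 0.5])
        # resizing interpolates linearly and stays inside [0, 1]
        out6 = _normalize_resize(np.array([1.0, 3.0, 2.0]), 6)
        expected = np.interp(np.linspace(0, 1, 6), np.linspace(0, 1, 3), [0.0, 1.0, 0.5])
        assert np.allclose(out6, expected)
        # averaging normalized maps: {0-map, 1-map, 1-map} -> 2/3
        assert np.allclose(np.mean([np.zeros(6), np.ones(6), np.ones(6)], axis=0), 2 / 3)

    def test_feature_map_gradients_match_finite_differences(self):
        """Perturb post-ReLU feature maps directly and re-run the network
        tail; the backpropagated gradients must match."""
        cfg = ModelConfig(n_blocks=2, n_filters=3, r_drop=0.0,
                          input_length=64, dtype="float64")
        m = CNNRegressor(cfg, seed=5)
        x = np.random.default_rng(5).normal(size=64)
        out, activations, act_grads = _forward_with_grads(m, x)

        def tail_output(block_index, a):
            h = a[None, :, :]
            h = m.blocks[block_index]["pool"].forward(h, training=False)
            for blk in m.blocks[block_index + 1 :]:
                h = blk["conv"].forward(h, training=False)
                h = blk["bn"].forward(h, training=False)
                h = np.maximum(h, 0.0)
                h = blk["pool"].forward(h, training=False)
            return float((h.reshape(1, -1) @ m.head.W.T + m.head.b)[0, 0])

        def differentiable(A, i, j, pool=2):
            """Avoid non-smooth points: tied pooling windows (e.g. two ReLU
            zeros) where one-sided derivatives differ."""
            lo = (i // pool) * pool
            window = A[lo : lo + pool, j]
            others = np.delete(window, i - lo)
            return bool(np.all(np.abs(others - window[i - lo]) > 1e-6))

        rng = np.random.default_rng(6)
        eps = 1e-6
        for b in range(2):
            A = activations[b]
            checked = 0
            while checked < 5:
                i, j = rng.integers(0, A.shape[0]), rng.integers(0, A.shape[1])
                if not differentiable(A, i, j):
                    continue
                checked += 1
                ap, am = A.copy(), A.copy()
                ap[i, j] += eps
                am[i, j] -= eps
                fd = (tail_output(b, ap) - tail_output(b, am)) / (2 * eps)
                assert abs(fd - act_grads[b][i, j]) < 1e-4


class TestDeepShap:
    def test_linear_model_analytic_shapley(self):
        """For f(x) = w'x + c the SHAP values are exactly w_i (x_i - mu_i)."""
        rng = np.random.default_rng(7)
        L = 64
        w = rng.normal(size=L)
        model = make_linear_model(w, c=0.7)
        x = rng.normal(size=L)
        background = rng.normal(size=(20, L))
        phi = deep_shap(model, x, background)
        mu = background.mean(axis=0)
        assert np.allclose(phi, w * (x - mu), atol=1e-10)

    def test_identical_background_gives_zero_attribution(self, small_model):
        x = np.random.default_rng(8).normal(size=480)
        phi = deep_shap(small_model, x, x[None, :])
        assert np.allclose(phi, 0.0, atol=1e-6)
        assert abs(phi.sum()) < 1e-6

    def test_completeness_random_model(self, small_model):
        """Attributions sum to f(x) - E_b f(b) for arbitrary weights."""
        rng = np.random.default_rng(9)
        background = rng.normal(size=(15, 480))
        f_b = small_model.predict(background).mean()
        for _ in range(5):
            x = rng.normal(size=480)
            phi = deep_shap(small_model, x, background)  # checks internally too
            delta = float(small_model.predict(x[None, :])[0]) - f_b
            assert abs(phi.sum() - delta) <= 1e-3 * max(1.0, abs(delta))

    def test_constant_output_model_zero_attribution(self):
        cfg = ModelConfig(n_blocks=1, n_filters=2, pool=1, r_drop=0.0, input_length=32)
        m = CNNRegressor(cfg, seed=0)
        m.head.W[:] = 0.0
        m.head.b[:] = 3.5
        rng = np.random.default_rng(10)
        phi = deep_shap(m, rng.normal(size=32), rng.normal(size=(5, 32)))
        assert np.allclose(phi, 0.0, atol=1e-7)

    def test_background_length_mismatch_rejected(self, small_model):
        with pytest.raises(ValueError, match="length"):
            deep_shap(small_model, np.zeros(480), np.zeros((3, 100)))


class TestLocalization:
    ann = [EventAnnotation(100.0, 10.0, "apnea"), EventAnnotation(300.0, 12.0, "hypopnea")]

    def test_uniform_attribution_ratio_one(self):
        score = localization_score(np.ones(2400), self.ann, 0.0, 10)
        assert score.ratio == pytest.approx(1.0)

    def test_event_only_attribution_flagged_infinite(self):
        values = np.zeros(2400)
        values[380:460] = 1.0  # 95-115 s at 4 Hz, inside the apnea +/- margin
        score = localization_score(values, self.ann, 0.0, 10)
        assert np.isinf(score.ratio) and score.undefined

    def test_shap_kind_uses_magnitude(self):
        values = np.full(2400, -2.0)
        score = localization_score(values, self.ann, 0.0, 10, kind="shap")
        assert score.ratio == pytest.approx(1.0)

    def test_eventless_segment_rejected(self):
        with pytest.raises(ValueError, match="no respiratory events"):
            localization_score(np.ones(2400), self.ann, 1200.0, 10)
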