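"""Layer primitives against brute-force oracles, and training contracts."""

import numpy as np
import pytest

from stresswin import CnnSpec, TrainConfig, conv2d, leaky_relu, maxpool, to_4d
from stresswin import cnn as cnn_mod
from stresswin.labeling import NON_STRESS, STRESS


def brute_conv2d(x, kernels):
    """Triple-loop cross-correlation, the definitional oracle."""
    h, w, cin = x.shape
    cout, _, kh, kw = kernels.shape
    out = np.zeros((h - kh + 1, w - kw + 1, cout))
    for d in range(cout):
        for i in range(h - kh + 1):
            for j in range(w - kw + 1):
                acc = 0.0
                for dl in range(cin):
                    for ki in range(kh):
                        for kj in range(kw):
                            acc += kernels[d, dl, ki, kj] * x[i + ki, j + kj, dl]
                out[i, j, d] = acc
    return out


def brute_maxpool(x, window=(2, 2), stride=(1, 1)):
    h, w, c = x.shape
    ph, pw = window
    sh, sw = stride
    ho = (h - ph) // sh + 1
    wo = (w - pw) // sw + 1
    out = np.zeros((ho, wo, c))
    for i in range(ho):
        for j in range(wo):
            out[i, j] = x[i * sh : i * sh + ph, j * sw : j * sw + pw].max(axis=(0, 1))
    return out


class TestConv2d:
    def test_zero_kernel_gives_zero_map(self):
        x = np.random.default_rng(0).standard_normal((19, 20, 1))
        k = np.zeros((16, 1, 3, 3))
        out = conv2d(x, k)
        assert out.shape == (17, 18, 16)
        assert np.all(out == 0)

    def test_identity_kernel(self):
        x = np.random.default_rng(1).standard_normal((19, 20, 1))
        k = np.ones((1, 1, 1, 1))
        np.testing.assert_allclose(conv2d(x, k), x)

    @pytest.mark.parametrize("shape,kshape", [((5, 5, 1), (3, 3)), ((8, 8, 3), (3, 3)), ((7, 6, 2), (2, 2))])
    def test_matches_brute_force(self, shape, kshape):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(shape)
        k = rng.standard_normal((4, shape[2], *kshape))
        np.testing.assert_allclose(conv2d(x, k), brute_conv2d(x, k), atol=1e-6)

    def test_kernel_larger_than_input_rejected(self):
        with pytest.raises(ValueError, match="larger than input"):
            conv2d(np.zeros((2, 2, 1)), np.zeros((1, 1, 3, 3)))


class TestLeakyRelu:
    @pytest.mark.parametrize("x,expected", [(2.0, 2.0), (-1.0, -0.01), (0.0, 0.0)])
    def test_pointwise_values(self, x, expected):
        assert leaky_relu(np.array(x)) == pytest.approx(expected)

    def test_elementwise_definition(self):
        x = np.random.default_rng(0).standard_normal(100)
        out = leaky_relu(x, slope=0.01)
        np.testing.assert_allclose(out, np.where(x > 0, x, 0.01 * x))


class TestMaxpool:
    def test_constant_map_shrinks_by_one(self):
        x = np.full((5, 6, 2), 3.0)
        out, _ = maxpool(x)
        assert out.shape == (4, 5, 2)
        assert np.all(out == 3.0)

    def test_two_by_two(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(2, 2, 1)
        out, _ = maxpool(x)
        assert out.shape == (1, 1, 1)
        assert out[0, 0, 0] == 4.0

    @pytest.mark.parametrize("shape", [(5, 5, 1), (8, 8, 3), (6, 9, 2)])
    def test_matches_brute_force(self, shape):
        x = np.random.default_rng(3).standard_normal(shape)
        out, _ = maxpool(x)
        np.testing.assert_allclose(out, brute_maxpool(x), atol=1e-12)

    def test_window_larger_than_input_rejected(self):
        with pytest.raises(ValueError, match="larger than input"):
            maxpool(np.zeros((1, 1, 1)), window=(2, 2))


class TestArchitecture:
    def test_shape_trace_and_flat_width(self):
        spec = CnnSpec()
        assert spec.shape_trace() == [
            (19, 20, 1), (17, 18, 16), (15, 16, 16), (14, 15, 16),
            (13, 14, 10), (12, 13, 10), (11, 12, 10),
        ]
        assert spec.n_flat_features == 1320

    def test_inconsistent_stack_rejected(self):
        with pytest.raises(ValueError, match="shapes do not chain"):
            CnnSpec(input_shape=(4, 4, 1)).shape_trace()


def _toy_data(n=320, seed=0, separation=3.0):
    """Windows whose channel-0 mean separates the classes."""
    rng = np.random.default_rng(seed)
    y = np.where(rng.random(n) < 0.5, STRESS, NON_STRESS).astype(object)
    slices = []
    for yi in y:
        s = rng.standard_normal((19, 20))
        s[0] += separation if yi == STRESS else -separation
        slices.append(s)
    return to_4d(slices, subject_id="toy"), y


@pytest.fixture(scope="module")
def toy_model():
    tensor, y = _toy_data()
    spec = CnnSpec(seed=1)
    cfg = TrainConfig(seed=1, epochs=30)  # tiny set, so many cheap epochs
    return cnn_mod.train(spec, cfg, tensor, y), tensor, y


class TestForward:
    def test_probabilities_sum_to_one(self, toy_model):
        model, tensor, _ = toy_model
        probs = cnn_mod.forward(model, tensor)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_duplicated_window_identical_rows(self, toy_model):
        model, tensor, _ = toy_model
        dup = tensor.subset(np.array([0, 0, 0]))
        probs = cnn_mod.forward(model, dup)
        np.testing.assert_array_equal(probs[0], probs[1])
        np.testing.assert_array_equal(probs[0], probs[2])

    def test_wrong_shape_rejected(self, toy_model):
        model, _, _ = toy_model
        bad = to_4d([np.zeros((19, 21))])
        with pytest.raises(ValueError, match="does not match spec"):
            cnn_mod.forward(model, bad)

    def test_feature_extraction_shape(self, toy_model):
        model, tensor, y = toy_model
        table = cnn_mod.extract_cnn_features(model, tensor, labels=y)
        assert table.frame.shape == (tensor.n_windows, 1320)


class TestTraining:
    def test_same_seed_identical_weights(self):
        tensor, y = _toy_data(n=64, seed=2)
        spec, cfg = CnnSpec(seed=3), TrainConfig(seed=3, epochs=2)
        m1 = cnn_mod.train(spec, cfg, tensor, y)
        m2 = cnn_mod.train(spec, cfg, tensor, y)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_loss_finite_every_epoch_and_learns_separable(self, toy_model):
        model, tensor, y = toy_model
        assert all(np.isfinite(h["train_loss"]) for h in model.history)
        assert len(model.history) == 30
        pred = cnn_mod.predict_labels(model, tensor)
        assert (pred == y).mean() >= 0.9  # strongly separable training set

    def test_zero_learning_rate_leaves_weights_at_init(self):
        tensor, y = _toy_data(n=64, seed=4)
        spec = CnnSpec(seed=5)
        frozen = cnn_mod.train(spec, TrainConfig(seed=5, epochs=1, learning_rate=0.0), tensor, y)
        rng = np.random.default_rng(np.random.SeedSequence([5, 5]))
        init = cnn_mod._init_params(spec, rng)
        for k in init:
            np.testing.assert_array_equal(frozen.params[k], init[k])

    def test_single_class_rejected(self):
        tensor, y = _toy_data(n=32, seed=6)
        y[:] = STRESS
        with pytest.raises(ValueError, match="single class"):
            cnn_mod.train(CnnSpec(), TrainConfig(epochs=1), tensor, y)

    def test_dropout_active_in_train_mode_only(self):
        tensor, y = _toy_data(n=8, seed=7)
        spec = CnnSpec(seed=8)
        rng = np.random.default_rng(0)
        params = cnn_mod._init_params(spec, np.random.default_rng(1))
        x = cnn_mod._tensor_to_batch(tensor)
        p_train1, _, _ = cnn_mod._forward_pass(params, spec, x, train=True, rng=np.random.default_rng(2))
        p_train2, _, _ = cnn_mod._forward_pass(params, spec, x, train=True, rng=np.random.default_rng(3))
        p_eval1, _, _ = cnn_mod._forward_pass(params, spec, x, train=False)
        p_eval2, _, _ = cnn_mod._forward_pass(params, spec, x, train=False)
        assert not np.allclose(p_train1, p_train2)  # random masks differ
        np.testing.assert_array_equal(p_eval1, p_eval2)  # eval is mask-free

    def test_model_round_trips_through_disk(self, toy_model, tmp_path):
        model, tensor, _ = toy_model
        model.save(tmp_path / "model")
        back = cnn_mod.TrainedModel.load(tmp_path / "model")
        np.testing.assert_array_equal(
            cnn_mod.forward(back, tensor), cnn_mod.forward(model, tensor)
        )
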