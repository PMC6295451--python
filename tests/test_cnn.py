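"""CNN forward passes vs loop oracles; analytic gradients vs finite differences."""

import numpy as np
import pytest

from seizurecnn import cnn
from seizurecnn.cnn import (
    CNNConfig,
    backward,
    conv_forward,
    fc_forward,
    forward,
    init_model,
    load_model,
    mean_pool,
    mse_loss,
    predict,
    save_model,
    train,
)
from seizurecnn.exceptions import ConfigurationError, DataError

# ---------------------------------------------------------------- oracles


def conv_oracle(x, kernels, bias):
    """Quadruple-nested-loop valid cross-correlation, stride 1."""
    c, w = x.shape
    m, k, _ = kernels.shape
    out = np.zeros((m, c - k + 1, w - k + 1))
    for mm in range(m):
        for i in range(c - k + 1):
            for j in range(w - k + 1):
                acc = 0.0
                for a in range(k):
                    for b in range(k):
                        acc += x[i + a, j + b] * kernels[mm, a, b]
                out[mm, i, j] = acc + bias[mm]
    return out


def pool_oracle(maps, p=2):
    m, h, w = maps.shape
    out = np.zeros((m, h // p, w // p))
    for mm in range(m):
        for i in range(h // p):
            for j in range(w // p):
                out[mm, i, j] = maps[mm, i * p : (i + 1) * p, j * p : (j + 1) * p].mean()
    return out


def fc_oracle(flat, w, b):
    z = np.array([np.dot(w[c], flat) + b[c] for c in range(len(b))])
    return 1.0 / (1.0 + np.exp(-z))


def small_model(seed=0, input_shape=(8, 12), n_classes=2, **kw):
    cfg = CNNConfig(input_shape=input_shape, n_classes=n_classes, seed=seed, **kw)
    return init_model(cfg)


# --------------------------------------------------------- forward passes


class TestConvForward:
    def test_zero_kernels_give_zero_maps(self):
        model = small_model()
        model.kernels[:] = 0.0
        model.conv_bias[:] = 0.0
        out = conv_forward(np.random.default_rng(0).normal(size=(8, 12)), model)
        assert out.shape == (6, 4, 8)
        assert np.all(out == 0.0)

    def test_delta_kernel_is_identity_with_offset(self):
        model = small_model(input_shape=(6, 256))
        model.kernels[:] = 0.0
        model.conv_bias[:] = 0.0
        model.kernels[0, 0, 0] = 1.0  # delta at (0,0)
        x = np.random.default_rng(1).normal(size=(6, 256))
        out = conv_forward(x, model)
        assert out.shape == (6, 2, 252)
        np.testing.assert_array_equal(out[0], x[:2, :252])

    def test_matches_loop_oracle_on_many_seeded_instances(self):
        rng = np.random.default_rng(2024)
        model = small_model(input_shape=(7, 10))
        for _ in range(100):
            x = rng.normal(size=(7, 10))
            model.kernels = rng.normal(size=(6, 5, 5))
            model.conv_bias = rng.normal(size=6)
            got = conv_forward(x, model)
            want = conv_oracle(x, model.kernels, model.conv_bias)
            assert np.max(np.abs(got - want)) <= 1e-12

    def test_input_smaller_than_kernel_raises(self):
        model = small_model()
        with pytest.raises(DataError):
            conv_forward(np.zeros((3, 12)), model)
        with pytest.raises(ConfigurationError):
            CNNConfig(input_shape=(4, 12), n_classes=2)


class TestMeanPool:
    def test_constant_map_stays_constant(self):
        assert np.all(mean_pool(np.full((1, 4, 6), 3.25)) == 3.25)

    def test_2x2_block_mean(self):
        out = mean_pool(np.array([[[1.0, 2.0], [3.0, 4.0]]]))
        assert out.shape == (1, 1, 1)
        assert out[0, 0, 0] == 2.5

    def test_odd_trailing_row_and_column_truncated(self):
        maps = np.arange(3 * 5 * 7, dtype=float).reshape(3, 5, 7)
        assert mean_pool(maps).shape == (3, 2, 3)

    def test_matches_loop_oracle_on_many_seeded_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            maps = rng.normal(size=(6, rng.integers(2, 9), rng.integers(2, 9)))
            np.testing.assert_array_equal(mean_pool(maps), pool_oracle(maps))


class TestFcForward:
    def test_zero_weights_give_half_scores(self):
        model = small_model()
        model.fc_weights[:] = 0.0
        model.fc_bias[:] = 0.0
        scores = fc_forward(np.zeros((6,) + model.config.pooled_shape), model)
        np.testing.assert_array_equal(scores, [0.5, 0.5])

    def test_large_bias_saturates_to_one(self):
        model = small_model()
        model.fc_weights[:] = 0.0
        model.fc_bias[:] = 50.0
        scores = fc_forward(np.zeros((6,) + model.config.pooled_shape), model)
        assert np.all(np.abs(scores - 1.0) <= 1e-15)

    def test_matches_formula_oracle_on_many_seeded_instances(self):
        rng = np.random.default_rng(11)
        model = small_model()
        d = model.config.n_features
        for _ in range(100):
            pooled = rng.normal(size=(6,) + model.config.pooled_shape)
            model.fc_weights = rng.normal(size=(2, d))
            model.fc_bias = rng.normal(size=2)
            got = fc_forward(pooled, model)
            want = fc_oracle(pooled.reshape(-1), model.fc_weights, model.fc_bias)
            assert np.max(np.abs(got - want)) <= 1e-12
            assert np.all((got > 0) & (got < 1))

    def test_dimension_mismatch_raises(self):
        model = small_model()
        with pytest.raises(DataError):
            fc_forward(np.zeros(5), model)


class TestMseLoss:
    def test_exact_match_is_zero(self):
        assert mse_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == 0.0

    def test_half_scores_binary(self):
        assert mse_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0])) == 0.25

    def test_matches_formula_oracle(self, rng):
        s, t = rng.uniform(size=3), np.array([0.0, 1.0, 0.0])
        assert mse_loss(s, t) == pytest.approx(np.sum((s - t) ** 2) / 3, abs=1e-15)


# --------------------------------------------------------------- backward


def flatten_params(model):
    return [
        ("kernels", model.kernels),
        ("conv_bias", model.conv_bias),
        ("fc_weights", model.fc_weights),
        ("fc_bias", model.fc_bias),
    ]


def batch_loss(model, x, targets):
    scores = forward(model, x)
    return float(np.mean((scores - targets) ** 2))


@pytest.mark.parametrize("conv_sigmoid", [False, True], ids=["linear-conv", "sigmoid-conv"])
def test_gradients_match_central_finite_differences(conv_sigmoid):
    rng = np.random.default_rng(99)
    model = small_model(seed=99, conv_sigmoid=conv_sigmoid)
    x = rng.normal(size=(4, 8, 12))
    y = rng.integers(0, 2, size=4)
    targets = np.zeros((4, 2))
    targets[np.arange(4), y] = 1.0

    grads = backward(model, x, targets)
    h = 1e-5
    for name, arr in flatten_params(model):
        g = grads[name]
        for idx in np.ndindex(arr.shape):
            orig = arr[idx]
            arr[idx] = orig + h
            lp = batch_loss(model, x, targets)
            arr[idx] = orig - h
            lm = batch_loss(model, x, targets)
            arr[idx] = orig
            num = (lp - lm) / (2 * h)
            rel = abs(g[idx] - num) / max(abs(g[idx]), abs(num), 1e-4)
            assert rel <= 1e-5, f"{name}{idx}: analytic {g[idx]} vs numeric {num}"


def test_zero_gradient_at_exact_fit():
    """Scores equal to targets are a stationary point of the MSE loss."""
    model = small_model()
    model.fc_weights[:] = 0.0
    model.fc_bias[:] = 0.0
    x = np.random.default_rng(3).normal(size=(2, 8, 12))
    targets = np.full((2, 2), 0.5)  # sigmoid(0) = 0.5 everywhere
    grads = backward(model, x, targets)
    for name, _ in flatten_params(model):
        assert np.max(np.abs(grads[name])) == 0.0


def test_batch_gradient_is_mean_of_per_example_gradients():
    rng = np.random.default_rng(5)
    model = small_model(seed=5)
    x = rng.normal(size=(6, 8, 12))
    targets = np.eye(2)[rng.integers(0, 2, size=6)]
    batch = backward(model, x, targets)
    for name, _ in flatten_params(model):
        per = np.mean(
            [backward(model, x[i : i + 1], targets[i : i + 1])[name] for i in range(6)],
            axis=0,
        )
        np.testing.assert_allclose(batch[name], per, atol=1e-12)


def test_backward_shape_mismatch_raises():
    model = small_model()
    with pytest.raises(DataError):
        backward(model, np.zeros((2, 8, 12)), np.zeros((2, 3)))


# ----------------------------------------------------------------- train


def separable_spectra(n_per_class=100, seed=42):
    """Frequency-domain 1-s epochs of the default simulator, 2 classes."""
    from seizurecnn import segmentation, spectral, synthetic

    timeline = [("interictal", float(n_per_class)), ("ictal", float(n_per_class))]
    cfg = synthetic.SyntheticConfig(timeline=timeline, seed=seed, phase_randomize=True)
    rec = synthetic.generate_record(cfg)
    tl = segmentation.build_timeline(rec, preictal_len_s=1, interictal_margin_s=1)
    eps = [e for e in segmentation.extract_epochs(rec, tl) if e.label != "preictal"]
    spectra = spectral.batch_transform(eps)
    x = np.stack([s.data for s in spectra])
    y = np.array([0 if s.label == "interictal" else 1 for s in spectra])
    return x, y


class TestTrain:
    def test_separable_spectra_reach_high_training_accuracy(self):
        x, y = separable_spectra()
        cfg = CNNConfig(input_shape=x.shape[1:], n_classes=2, seed=42)
        model, trace = train(x, y, cfg)
        preds = cnn.predict_batch(model, x)
        assert np.mean(preds == y) >= 0.95
        assert trace.mse[-1] < trace.mse[0]

    def test_same_seed_gives_identical_weights(self):
        x, y = separable_spectra(n_per_class=30)
        cfg = CNNConfig(input_shape=x.shape[1:], n_classes=2, seed=7, max_epochs=5)
        m1, t1 = train(x, y, cfg)
        m2, t2 = train(x, y, cfg)
        np.testing.assert_array_equal(m1.kernels, m2.kernels)
        np.testing.assert_array_equal(m1.fc_weights, m2.fc_weights)
        assert t1.mse == t2.mse

    def test_zero_learning_rate_changes_nothing(self):
        x, y = separable_spectra(n_per_class=20)
        cfg = CNNConfig(
            input_shape=x.shape[1:], n_classes=2, seed=3, learning_rate=0.0, max_epochs=20
        )
        model, trace = train(x, y, cfg)
        fresh = init_model(cfg)
        np.testing.assert_array_equal(model.kernels, fresh.kernels)
        np.testing.assert_array_equal(model.fc_weights, fresh.fc_weights)
        # trace is constant up to batch summation order
        assert max(trace.mse) - min(trace.mse) <= 1e-12

    def test_single_class_dataset_rejected(self):
        x = np.zeros((40, 8, 12))
        y = np.zeros(40, dtype=int)
        with pytest.raises(ConfigurationError):
            train(x, y, CNNConfig(input_shape=(8, 12), n_classes=2))


class TestPredict:
    def test_argmax_and_tie_rule(self):
        # scores are monotone in fc_bias when weights are zero
        model = small_model()
        model.fc_weights[:] = 0.0
        model.fc_bias[:] = [2.0, -2.0]
        x = np.zeros((8, 12))
        assert predict(model, x) == 0
        model.fc_bias[:] = [-2.0, 2.0]
        assert predict(model, x) == 1
        model.fc_bias[:] = [1.0, 1.0]  # exact tie -> lowest class index
        assert predict(model, x) == 0

    def test_three_class_argmax(self):
        cfg = CNNConfig(input_shape=(8, 12), n_classes=3)
        model = init_model(cfg)
        model.fc_weights[:] = 0.0
        model.fc_bias[:] = [0.1, 0.2, 0.9]
        assert predict(model, np.zeros((8, 12))) == 2


def test_shape_algebra_and_checkpoint_round_trip(tmp_path):
    cfg = CNNConfig(input_shape=(6, 129), n_classes=3)
    assert cfg.conv_shape == (2, 125)
    assert cfg.pooled_shape == (1, 62)
    assert cfg.n_features == 6 * 1 * 62
    model = init_model(cfg)
    model.norm_mean = np.random.default_rng(0).normal(size=(6, 129))
    model.norm_sd = np.ones((6, 129))
    save_model(model, tmp_path / "m.h5")
    back = load_model(tmp_path / "m.h5")
    np.testing.assert_array_equal(back.kernels, model.kernels)
    np.testing.assert_array_equal(back.norm_mean, model.norm_mean)
    assert back.config == cfg
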