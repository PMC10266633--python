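import numpy as np
import pytest

from rcwgbs import nn

SMALL_SPEC = nn.ModelSpec(n_filters=8, dense_units=16)


def _chain_mean_data(n, seed=0, length=100):
    """Targets equal the mean of feature row 5 — linear, learnable.

    Chain entries are coherent within an example (a per-example level plus
    noise, like a spatially correlated methylome), so the targets have real
    variance and fitting them is distinguishable from predicting the mean.
    """
    rng = np.random.default_rng(seed)
    X = np.zeros((n, 5, length))
    base = rng.random(n)
    X[:, 4, :] = np.clip(base[:, None] + rng.normal(0, 0.05, (n, length)), 0, 1)
    X[:, :4, :] = rng.integers(0, 2, (n, 4, length))
    return X, X[:, 4, :].mean(axis=1)


class TestArchitecture:
    def test_shape_trace_matches_printed_sizes(self):
        trace = dict(nn.ModelSpec().shape_trace())
        assert trace["input"] == (5, 100, 1)
        assert trace["conv1"] == (1, 96, 128)
        assert trace["pool1"] == (1, 48, 128)
        assert trace["conv2"] == (1, 46, 128)
        assert trace["pool2"] == (1, 23, 128)
        assert trace["conv3"] == (1, 21, 128)   # 21 x 1 x 128 pre-dense map
        assert trace["dense1"] == (10, 1, 128)  # 10 x 1 x 128 representation
        assert trace["dense2"] == (1,)

    def test_forward_pass_produces_printed_intermediate_shapes(self):
        net = nn.build_model(seed=0)
        X = np.random.default_rng(0).random((3, 5, 100, 1))
        _, cache = net.forward(X, want_cache=True)
        assert cache["Z1"].shape == (3, 96, 128)
        assert cache["P1"].shape == (3, 48, 128)
        assert cache["Z2"].shape == (3, 46, 128)
        assert cache["P2"].shape == (3, 23, 128)
        assert cache["Z3"].shape == (3, 21, 128)
        assert cache["Z4"].shape == (3, 1280)

    def test_invalid_spec_reports_trace(self):
        with pytest.raises(ValueError, match="dense_units"):
            nn.ModelSpec(dense_units=1000).shape_trace()
        with pytest.raises(ValueError):
            nn.ModelSpec(input_length=6).shape_trace()

    def test_output_in_unit_interval(self):
        net = nn.build_model(SMALL_SPEC, seed=1)
        X = np.random.default_rng(1).normal(size=(1000, 5, 100))
        out = net.predict(X)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestGradients:
    def test_analytic_gradients_match_numerical(self):
        spec = nn.ModelSpec(n_filters=3, dense_units=6, input_length=20)
        net = nn.CNNRegressor(spec, seed=1, dtype=np.float64)
        rng = np.random.default_rng(2)
        # move off the ReLU kinks that zero-initialized biases sit on
        for k in net.params:
            net.params[k] = net.params[k] + rng.normal(0, 0.05, net.params[k].shape)
        X = rng.random((4, 5, 20))
        y = rng.random(4)

        def loss():
            return float(np.mean((net.forward(X) - y) ** 2))

        out, cache = net.forward(X, want_cache=True)
        grads = net.backward(cache, 2 * (out - y) / len(y))
        eps = 1e-6
        for k in net.params:
            flat = net.params[k].ravel()
            for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[k].ravel()[idx]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-9), k


class TestPredict:
    def test_batch_size_invariance(self):
        net = nn.build_model(SMALL_SPEC, seed=2)
        X = np.random.default_rng(3).random((50, 5, 100))
        one = np.array([net.predict(X[i : i + 1])[0] for i in range(50)])
        batched = net.predict(X, batch_size=32)
        assert np.max(np.abs(one - batched)) < 1e-6

    def test_permutation_equivariance(self):
        net = nn.build_model(SMALL_SPEC, seed=3)
        X = np.random.default_rng(4).random((20, 5, 100))
        perm = np.random.default_rng(5).permutation(20)
        np.testing.assert_allclose(net.predict(X[perm]), net.predict(X)[perm], atol=1e-7)

    def test_shape_mismatch_named(self):
        net = nn.build_model(seed=0)
        with pytest.raises(ValueError, match="5, 100"):
            net.predict(np.zeros((2, 4, 50)))


class TestTraining:
    def test_learns_chain_mean_function(self):
        """The target is linear in row 5; the net must fit it closely."""
        X, y = _chain_mean_data(2000, seed=6)
        net = nn.build_model(seed=6)
        trained = nn.train(net, X, y, nn.TrainingConfig(max_epochs=8, seed=6))
        assert trained.history["val_mae"].min() < 0.05

    def test_constant_target_converges_to_constant(self):
        X, _ = _chain_mean_data(400, seed=7)
        y = np.full(400, 0.5)
        net = nn.build_model(SMALL_SPEC, seed=7)
        trained = nn.train(
            net, X, y, nn.TrainingConfig(max_epochs=15, patience=15, seed=7)
        )
        pred = trained.predict(X)
        assert np.abs(pred - 0.5).mean() < 0.05
        assert pred.mean() == pytest.approx(0.5, abs=0.05)

    def test_training_deterministic_given_seed(self):
        X, y = _chain_mean_data(300, seed=8)
        runs = []
        for _ in range(2):
            net = nn.build_model(SMALL_SPEC, seed=8)
            runs.append(nn.train(net, X, y, nn.TrainingConfig(max_epochs=3, seed=8)))
        assert runs[0].history.equals(runs[1].history)
        for k in runs[0].params:
            assert np.array_equal(runs[0].params[k], runs[1].params[k])

    def test_train_loss_decreases_early(self):
        X, y = _chain_mean_data(1000, seed=9)
        net = nn.build_model(SMALL_SPEC, seed=9)
        trained = nn.train(
            net, X, y, nn.TrainingConfig(max_epochs=5, patience=10, seed=9)
        )
        mse = trained.history["train_mse"].to_numpy()
        assert mse[-1] < mse[0] * 1.05  # non-increasing with slack

    def test_chain_ablation_collapses_to_mean(self):
        """Zeroing row 5 removes the only signal; predictions go to the target mean."""
        X, y = _chain_mean_data(800, seed=10)
        net = nn.build_model(SMALL_SPEC, seed=10)
        trained = nn.train(
            net, X, y, nn.TrainingConfig(max_epochs=15, patience=15, seed=10)
        )
        ablated = X.copy()
        ablated[:, 4, :] = 0.0
        # without the chain the net cannot track the per-example targets
        r_full = np.corrcoef(trained.predict(X), y)[0, 1]
        r_ablated = np.corrcoef(trained.predict(ablated), y)[0, 1]
        assert r_full > 0.8
        assert abs(r_ablated) < 0.3

    def test_target_bounds_and_size_validation(self):
        X, y = _chain_mean_data(20, seed=11)
        net = nn.build_model(SMALL_SPEC, seed=11)
        with pytest.raises(ValueError, match="targets"):
            nn.train(net, X, y + 2.0)
        with pytest.raises(ValueError, match="matrices"):
            nn.train(net, X, y[:-1])


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        X, y = _chain_mean_data(200, seed=12)
        net = nn.build_model(SMALL_SPEC, seed=12)
        trained = nn.train(
            net, X, y, nn.TrainingConfig(max_epochs=2, seed=12),
            scheme="2mer", metadata={"coverage_median": 10},
        )
        path = tmp_path / "model.npz"
        trained.save(path)
        back = nn.TrainedModel.load(path)
        assert back.spec == trained.spec
        assert back.scheme == "2mer"
        assert back.metadata["coverage_median"] == 10
        assert back.history.equals(trained.history)
        np.testing.assert_array_equal(back.predict(X), trained.predict(X))
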