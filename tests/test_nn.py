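"""Feed-forward trainer: parameter audit, gradients, determinism."""

import numpy as np
import pytest

from pefrisk.errors import ConfigError, DataError
from pefrisk.nn import MLP, NetworkSpec, ParameterAudit, TrainConfig, count_parameters


def _toy_data(n=40, d=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    t = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(float)
    return X, t


class TestParameterAudit:
    @pytest.mark.parametrize(
        "hidden, mask, total, unfrozen, ratio",
        [
            ((32,), (False, False), 321, 321, 100.0),
            ((32,), (True, False), 321, 33, 10.3),
            ((32, 32), (True, False, False), 1377, 1089, 79.1),
        ],
    )
    def test_published_architectures_at_input_dim_8(self, hidden, mask, total, unfrozen, ratio):
        audit = count_parameters(NetworkSpec(input_dim=8, hidden=hidden), mask)
        assert audit.total == total
        assert audit.unfrozen == unfrozen
        assert audit.unfrozen_ratio == ratio

    def test_counts_are_weights_plus_biases(self):
        # 3 -> 4 -> 1: (3*4 + 4) + (4*1 + 1) = 21
        assert count_parameters(NetworkSpec(3, (4,))).total == 21

    def test_mask_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            count_parameters(NetworkSpec(5, (8,)), (True,))

    def test_ratio_rounds_half_away_from_zero(self):
        assert ParameterAudit(total=1000, unfrozen=105).unfrozen_ratio == 10.5
        assert ParameterAudit(total=10000, unfrozen=1025).unfrozen_ratio == 10.3
        assert ParameterAudit(total=10000, unfrozen=1035).unfrozen_ratio == 10.4


class TestGradients:
    @pytest.mark.parametrize("hidden", [(3,), (4, 3)])
    def test_backprop_matches_finite_differences(self, hidden):
        """Central-difference oracle on every parameter of a tiny net."""
        spec = NetworkSpec(input_dim=3, hidden=hidden)
        model = MLP.initialize(spec, seed=1)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 3))
        t = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        gW, gb = model.gradients(X, t)
        eps = 1e-6
        for l in range(len(model.weights)):
            for arr, grad in ((model.weights[l], gW[l]), (model.biases[l], gb[l])):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    up = model.loss(X, t)
                    arr[idx] = orig - eps
                    down = model.loss(X, t)
                    arr[idx] = orig
                    fd = (up - down) / (2 * eps)
                    assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_first_adam_step_follows_gradient_sign(self):
        """With fresh moment estimates, Adam's first update is ~ -lr*sign(g)."""
        spec = NetworkSpec(input_dim=2, hidden=(3,))
        model = MLP.initialize(spec, seed=3)
        X = np.array([[1.0, -0.5], [-0.3, 0.8]])
        t = np.array([1.0, 0.0])
        gW, _ = model.gradients(X, t)
        before = [w.copy() for w in model.weights]
        model.fit(X, t, TrainConfig(epochs=1, learning_rate=1e-3))
        for l, g in enumerate(gW):
            delta = model.weights[l] - before[l]
            big = np.abs(g) > 1e-10
            assert np.allclose(delta[big], -1e-3 * np.sign(g[big]), atol=1e-5)


class TestTraining:
    def test_same_seed_gives_identical_weights(self):
        X, t = _toy_data()
        runs = []
        for _ in range(2):
            m = MLP.initialize(NetworkSpec(4, (8,)), seed=5)
            m.fit(X, t, TrainConfig(epochs=30), seed=5)
            runs.append(m)
        for a, b in zip(runs[0].weights, runs[1].weights):
            assert np.array_equal(a, b)

    def test_loss_decreases_on_learnable_data(self):
        X, t = _toy_data(n=80)
        m = MLP.initialize(NetworkSpec(4, (8,)), seed=6)
        trace = m.fit(X, t, TrainConfig(epochs=100))
        assert trace[-1] <= trace[0]

    def test_minibatch_training_runs(self):
        X, t = _toy_data(n=30)
        m = MLP.initialize(NetworkSpec(4, (8,)), seed=7)
        trace = m.fit(X, t, TrainConfig(epochs=10, batch_size=8), seed=7)
        assert len(trace) == 10

    def test_zero_epochs_rejected(self):
        with pytest.raises(ConfigError):
            TrainConfig(epochs=0)

    def test_feature_dimension_checked(self):
        m = MLP.initialize(NetworkSpec(4, (8,)), seed=8)
        with pytest.raises(DataError):
            m.predict_proba(np.zeros((3, 5)))

    def test_probabilities_in_unit_interval(self):
        X, _ = _toy_data()
        m = MLP.initialize(NetworkSpec(4, (8,)), seed=9)
        p = m.predict_proba(X)
        assert np.all((p > 0) & (p < 1))
        zones = m.predict_zones(X)
        assert set(np.unique(zones)) <= {0, 1}
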