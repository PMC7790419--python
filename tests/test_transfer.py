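"""Transfer learning: freezing semantics, protocol counts, serialization."""

from datetime import date, timedelta

import numpy as np
import pytest

from pefrisk.cohort import DailyObservation, PatientSeries
from pefrisk.errors import ConfigError, DataError
from pefrisk.nn import MLP, NetworkSpec, TrainConfig
from pefrisk.transfer import (
    ARCHITECTURES,
    SourceModel,
    Standardizer,
    TLConfig,
    evaluate_patient_tl,
    load_model,
    run_cohort_tl,
    save_model,
    train_source,
    transfer_target,
)

FAST = TLConfig(source_epochs=30, target_epochs=20)


def _pool(n=120, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 5))
    y = (X[:, 0] + 0.3 * rng.normal(size=n) > 0.8).astype(int)
    y[:3] = 0  # guarantee both classes
    return X, y


def _trained_source(hidden=(4,), seed=0):
    X, y = _pool(seed=seed)
    spec = NetworkSpec(input_dim=5, hidden=hidden)
    return train_source(X, y, spec, TrainConfig(epochs=25), seed=seed, validation_folds=0)


class TestTransferTarget:
    def test_fully_frozen_model_is_bit_identical_to_source(self):
        source = _trained_source()
        X, y = _pool(n=40, seed=1)
        model = transfer_target(source, X, y, (True, True), TrainConfig(epochs=15), seed=2)
        for a, b in zip(model.weights, source.mlp.weights):
            assert np.array_equal(a, b)
        for a, b in zip(model.biases, source.mlp.biases):
            assert np.array_equal(a, b)

    def test_hidden_frozen_output_retrained(self):
        """TL1 semantics: frozen hidden layer stays bit-equal, output moves."""
        source = _trained_source()
        X, y = _pool(n=40, seed=3)
        model = transfer_target(source, X, y, (True, False), TrainConfig(epochs=15), seed=4)
        assert np.array_equal(model.weights[0], source.mlp.weights[0])
        assert np.array_equal(model.biases[0], source.mlp.biases[0])
        assert not np.array_equal(model.weights[1], source.mlp.weights[1])

    def test_nothing_frozen_updates_every_layer(self):
        source = _trained_source()
        X, y = _pool(n=40, seed=5)
        model = transfer_target(source, X, y, (False, False), TrainConfig(epochs=15), seed=6)
        for a, b in zip(model.weights, source.mlp.weights):
            assert not np.array_equal(a, b)

    def test_feature_dimension_mismatch_rejected(self):
        source = _trained_source()
        with pytest.raises(DataError):
            transfer_target(
                source, np.zeros((10, 8)), np.array([0, 1] * 5), (True, False),
                TrainConfig(epochs=5),
            )

    def test_frozen_layers_invariant_across_seeds(self):
        """Freezing must hold exactly for every training seed."""
        source = _trained_source(hidden=(4, 3))
        X, y = _pool(n=30, seed=7)
        for seed in range(25):
            model = transfer_target(
                source, X, y, (True, False, False), TrainConfig(epochs=8), seed=seed
            )
            assert np.array_equal(model.weights[0], source.mlp.weights[0])
            assert np.array_equal(model.biases[0], source.mlp.biases[0])


class TestTrainSource:
    def test_single_class_pool_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 5))
        with pytest.raises(DataError):
            train_source(X, np.zeros(20, dtype=int), NetworkSpec(5, (4,)), TrainConfig(epochs=5))

    def test_validation_folds_reported(self):
        X, y = _pool()
        src = train_source(
            X, y, NetworkSpec(5, (4,)), TrainConfig(epochs=10), seed=1, validation_folds=3
        )
        assert len(src.fold_metrics) == 3
        assert all(r.n > 0 for r in src.fold_metrics)

    def test_deterministic_given_seed(self):
        X, y = _pool()
        a = train_source(X, y, NetworkSpec(5, (4,)), TrainConfig(epochs=10), seed=2,
                         validation_folds=0)
        b = train_source(X, y, NetworkSpec(5, (4,)), TrainConfig(epochs=10), seed=2,
                         validation_folds=0)
        for wa, wb in zip(a.mlp.weights, b.mlp.weights):
            assert np.array_equal(wa, wb)


def _predictable_patient(pid="TGT", n=60, seed=0, base=500.0):
    """Red days fully determined by PM2.5: high pollution knocks PEFR to a
    level below the 20th percentile of the mix."""
    rng = np.random.default_rng(seed)
    high = rng.random(n) < 0.3
    pm25 = np.where(high, 80.0, 10.0) + rng.uniform(0, 0.5, n)
    # cluster PEFR values are exact constants so each fold's refitted cutoff
    # lands on the polluted-day level and labels follow PM2.5 exactly
    pefr = np.where(high, base - 60.0, base)
    obs = tuple(
        DailyObservation(
            date=date(2018, 1, 1) + timedelta(days=i),
            pefr=float(pefr[i]),
            pm25=float(pm25[i]),
            co2=900.0 + float(rng.uniform(0, 1)),
            temp=21.0,
            rh=40.0,
        )
        for i in range(n)
    )
    return PatientSeries(patient_id=pid, sex="female", observations=obs)


class TestEvaluatePatientTL:
    def test_nn_is_on_separable_patient_is_perfect(self):
        cohort = [_predictable_patient()]
        outcome = evaluate_patient_tl(
            cohort, "TGT", "NN_IS",
            TLConfig(source_epochs=30, target_epochs=400), seed=1,
        )
        assert outcome.average["balanced_accuracy"] == pytest.approx(1.0)
        assert len(outcome.fold_results) == 3

    def test_three_folds_per_patient_and_architecture(self):
        cohort = [_predictable_patient(f"P{i}", seed=i) for i in range(3)]
        results, counts = run_cohort_tl(cohort, config=FAST, seed=2)
        assert counts == {"NN_IS": 9, "TL1_IS": 9, "TL2_IS": 9}
        assert set(results["architecture"]) == set(ARCHITECTURES)

    def test_unknown_architecture_and_missing_patient_rejected(self):
        cohort = [_predictable_patient()]
        with pytest.raises(ConfigError):
            evaluate_patient_tl(cohort, "TGT", "TL9_IS", FAST)
        with pytest.raises(DataError):
            evaluate_patient_tl(cohort, "NOPE", "NN_IS", FAST)

    def test_tl_needs_a_source_patient(self):
        cohort = [_predictable_patient()]
        with pytest.raises(DataError):
            evaluate_patient_tl(cohort, "TGT", "TL1_IS", FAST)

    def test_compat8_encoding_flows_through(self):
        cohort = [_predictable_patient(f"P{i}", seed=i) for i in range(2)]
        cfg = TLConfig(source_epochs=10, target_epochs=10, expand_to_8=True)
        outcome = evaluate_patient_tl(cohort, "P0", "TL1_IS", cfg, seed=3)
        assert len(outcome.fold_results) == 3


class TestSerialization:
    def test_round_trip(self, tmp_path):
        source = _trained_source()
        path = tmp_path / "model.json"
        save_model(source.mlp, path, freeze_mask=(True, False), seed=0)
        back = load_model(path)
        assert back.spec == source.mlp.spec
        for a, b in zip(back.weights, source.mlp.weights):
            assert np.array_equal(a, b)


def test_standardizer_handles_constant_columns():
    X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
    z = Standardizer.fit(X)
    out = z.transform(X)
    assert np.allclose(out[:, 1], 0.0)
    assert np.isfinite(out).all()
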