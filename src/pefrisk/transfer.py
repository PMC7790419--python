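"""Frozen-layer transfer learning for personalized risk networks.

Three architectures are compared, all trained with imbalanced sampling (IS)
on their training splits:

* ``NN_IS``  — one hidden layer (32 units), trained from random
  initialization on the target patient's data only.
* ``TL1_IS`` — one hidden layer: a *source* network is first trained on the
  pooled data of every other patient; the hidden layer is then frozen and
  only the output layer is retrained on the target patient.
* ``TL2_IS`` — two hidden layers: source trained the same way; the first
  hidden layer is frozen, the second hidden layer and the output layer are
  retrained on the target patient.

All target-model layers (frozen or not) start from the source weights, so
transfer is pure fine-tuning under a freeze mask. Each target patient is
evaluated with 3-fold cross-validation (2/3 train, 1/3 test), the zoning
cutoff refitted on each training split; a 25-patient cohort therefore
yields 75 trained target models per architecture.

Feature standardization is per patient by default: every patient's
features are z-scored with their own statistics (training-split statistics
on the target side), in the source pool and the target phase alike. The
shared structure the source model can transfer lives in patient-relative
coordinates — a flow of 400 L/min is alarming for one patient and routine
for another, exactly as the zoning cutoffs are personal — and per-patient
scaling is what makes the source task and the target task the *same* task
so the transferred weights remain meaningful. The alternative
(``scaling="pooled"``: one scaler fitted on the pooled source data and
reused on the target) is retained for comparison; it leaves the
between-patient baseline offset in the inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream_seed
from .errors import ConfigError, DataError
from .features import Examples, build_examples
from .metrics import EvalResult, aggregate_folds, confusion
from .nn import MLP, NetworkSpec, TrainConfig, count_parameters, validate_mask
from .resampling import imbalanced_sample
from .zoning import DEFAULT_QUANTILE, RED, fit_cutoff

__all__ = [
    "ARCHITECTURES",
    "TLConfig",
    "Standardizer",
    "SourceModel",
    "train_source",
    "transfer_target",
    "evaluate_patient_tl",
    "run_cohort_tl",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

# architecture -> (hidden layer widths, freeze mask for the target phase)
ARCHITECTURES: dict[str, tuple[tuple[int, ...], tuple[bool, ...]]] = {
    "NN_IS": ((32,), (False, False)),
    "TL1_IS": ((32,), (True, False)),
    "TL2_IS": ((32, 32), (True, False, False)),
}


def zone_targets(y: np.ndarray) -> np.ndarray:
    """Map zone labels (0=red, 1=safe) to red-probability targets in {0,1}."""
    return (np.asarray(y) == RED).astype(float)


@dataclass(frozen=True)
class TLConfig:
    """Protocol settings for the two training phases.

    Epoch defaults (1000 source / 100 target) follow the study protocol;
    both are overridable for scaled-down runs. ``source_validation_folds=0``
    skips the diagnostic k-fold validation pass over the source pool (the
    validation metrics never feed model selection).
    """

    source_epochs: int = 1000
    target_epochs: int = 100
    learning_rate: float = 1e-3
    target_folds: int = 3
    source_validation_folds: int = 0
    quantile: float = DEFAULT_QUANTILE
    lag_exposure: bool = False
    expand_to_8: bool = False
    scaling: str = "per_patient"  # or "pooled"; see module docstring

    def __post_init__(self) -> None:
        if self.scaling not in ("per_patient", "pooled"):
            raise ConfigError(f"scaling must be per_patient or pooled, got {self.scaling!r}")

    @property
    def input_dim(self) -> int:
        return 8 if self.expand_to_8 else 5

    def source_train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.source_epochs, learning_rate=self.learning_rate)

    def target_train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.target_epochs, learning_rate=self.learning_rate)


@dataclass(frozen=True)
class Standardizer:
    """Column-wise standardization fitted once and applied everywhere."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        sd = X.std(axis=0)
        return cls(mean=X.mean(axis=0), sd=np.where(sd > 0, sd, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


@dataclass
class SourceModel:
    """Population network trained on the pooled non-target patients."""

    mlp: MLP
    scaler: Standardizer
    fold_metrics: list[EvalResult] = field(default_factory=list)


def _stratified_folds(y: np.ndarray, k: int, seed: int):
    """Index pairs (train, test) for stratified shuffled k-fold."""
    from sklearn.model_selection import KFold, StratifiedKFold

    counts = np.bincount(y, minlength=2)
    if counts.min() >= k:
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed).split(
            np.zeros(len(y)), y
        )
    return KFold(n_splits=k, shuffle=True, random_state=seed).split(np.zeros(len(y)))


def _fit_with_is(
    model: MLP, X: np.ndarray, y: np.ndarray, cfg: TrainConfig, seed: int, mask=None
) -> list[float]:
    """Imbalanced-sample the training split, then train on it."""
    rs = imbalanced_sample(X, y, substream_seed(seed, "is"))
    return model.fit(
        rs.X, zone_targets(rs.y), cfg, freeze_mask=mask, seed=substream_seed(seed, "sgd")
    )


def train_source(
    X_pool: np.ndarray,
    y_pool: np.ndarray,
    spec: NetworkSpec,
    config: TrainConfig,
    k: int = 5,
    seed: int = 0,
    validation_folds: int | None = None,
) -> SourceModel:
    """Train the population (source) network on pooled labelled examples.

    Optionally runs a diagnostic k-fold validation pass first (each
    training split imbalanced-sampled, the held-out split untouched), then
    retrains a fresh network on the full pool with IS. ``validation_folds``
    defaults to ``k``; pass 0 to skip validation.
    """
    y_pool = np.asarray(y_pool)
    if len(np.unique(y_pool)) < 2:
        raise DataError("pooled source data is single-class")
    scaler = Standardizer.fit(X_pool)
    Xs = scaler.transform(X_pool)

    n_val = k if validation_folds is None else validation_folds
    fold_metrics: list[EvalResult] = []
    if n_val >= 2:
        for i, (tr, te) in enumerate(
            _stratified_folds(y_pool, n_val, substream_seed(seed, "src-folds"))
        ):
            m = MLP.initialize(spec, substream_seed(seed, "src-init", str(i)))
            _fit_with_is(m, Xs[tr], y_pool[tr], config, substream_seed(seed, "src-fit", str(i)))
            fold_metrics.append(confusion(y_pool[te], m.predict_zones(Xs[te])))

    final = MLP.initialize(spec, substream_seed(seed, "src-init", "final"))
    _fit_with_is(final, Xs, y_pool, config, substream_seed(seed, "src-fit", "final"))
    return SourceModel(mlp=final, scaler=scaler, fold_metrics=fold_metrics)


def transfer_target(
    source: SourceModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    mask,
    config: TrainConfig,
    seed: int = 0,
) -> MLP:
    """Fine-tune the source network on one target training split.

    Every layer starts from the source weights; layers flagged in ``mask``
    stay frozen (bit-identical to source) while the rest retrain on the
    imbalanced-sampled target split.
    """
    if np.asarray(X_train).shape[1] != source.mlp.spec.input_dim:
        raise DataError(
            f"target feature dimension {np.asarray(X_train).shape[1]} != "
            f"source input_dim {source.mlp.spec.input_dim}"
        )
    mask = validate_mask(source.mlp.spec, mask)
    model = source.mlp.copy()
    Xs = source.scaler.transform(X_train)
    _fit_with_is(model, Xs, np.asarray(y_train), config, seed, mask=mask)
    return model


@dataclass
class PatientTLOutcome:
    """3-fold results for one (patient, architecture)."""

    patient_id: str
    architecture: str
    fold_results: list[EvalResult] = field(default_factory=list)
    skipped_folds: int = 0
    n_models_trained: int = 0

    @property
    def average(self) -> dict[str, float]:
        return aggregate_folds(self.fold_results)


def evaluate_patient_tl(
    cohort,
    target_patient_id: str,
    architecture: str,
    config: TLConfig = TLConfig(),
    seed: int = 0,
    source: SourceModel | None = None,
) -> PatientTLOutcome:
    """Evaluate one architecture on one target patient (3-fold CV).

    For the TL architectures a source network is trained once on the pooled
    examples of every other patient (zoned on their own full history) and
    reused across the target folds, matching the protocol in which the
    source excludes the target entirely and does not depend on the target's
    fold split. A pre-trained ``source`` may be supplied to share it across
    calls.
    """
    if architecture not in ARCHITECTURES:
        raise ConfigError(f"unknown architecture {architecture!r}")
    hidden, mask = ARCHITECTURES[architecture]
    spec = NetworkSpec(input_dim=config.input_dim, hidden=hidden)
    needs_source = architecture != "NN_IS"

    by_id = {s.patient_id: s for s in cohort}
    if target_patient_id not in by_id:
        raise DataError(f"patient {target_patient_id!r} not in cohort")
    target = by_id[target_patient_id]
    examples = build_examples(
        target, lag_exposure=config.lag_exposure, expand_to_8=config.expand_to_8
    )

    outcome = PatientTLOutcome(patient_id=target_patient_id, architecture=architecture)

    if needs_source and source is None:
        others = [s for s in cohort if s.patient_id != target_patient_id]
        if len(others) < 1:
            raise DataError("transfer learning needs at least one source patient")
        source = build_source_model(others, architecture, config, seed)
        outcome.n_models_trained += 1

    pefr = examples.pefr_target
    provisional = fit_cutoff(pefr, config.quantile).labels(pefr)
    if len(np.unique(provisional)) < 2:
        raise DataError(f"patient {target_patient_id}: single-class labels")

    fold_seed = substream_seed(seed, "tl-folds", target_patient_id, architecture)
    for i, (tr, te) in enumerate(_stratified_folds(provisional, config.target_folds, fold_seed)):
        cutoff = fit_cutoff(pefr[tr], config.quantile)
        y_tr, y_te = cutoff.labels(pefr[tr]), cutoff.labels(pefr[te])
        if len(np.unique(y_tr)) < 2:
            logger.warning(
                "skipping fold %d for patient %s / %s: single-class training split",
                i, target_patient_id, architecture,
            )
            outcome.skipped_folds += 1
            continue
        phase_seed = substream_seed(seed, "tl-fit", target_patient_id, architecture, str(i))
        if needs_source:
            if config.scaling == "per_patient":
                z = Standardizer.fit(examples.X[tr])
                X_tr_in, X_te_in = z.transform(examples.X[tr]), z.transform(examples.X[te])
            else:
                X_tr_in, X_te_in = examples.X[tr], examples.X[te]
            model = transfer_target(
                source, X_tr_in, y_tr, mask, config.target_train_config(), phase_seed
            )
            X_te = source.scaler.transform(X_te_in)
        else:
            scaler = Standardizer.fit(examples.X[tr])
            model = MLP.initialize(spec, substream_seed(phase_seed, "init"))
            _fit_with_is(
                model, scaler.transform(examples.X[tr]), y_tr,
                config.target_train_config(), phase_seed,
            )
            X_te = scaler.transform(examples.X[te])
        outcome.n_models_trained += 1
        outcome.fold_results.append(confusion(y_te, model.predict_zones(X_te)))
    return outcome


def build_source_model(
    source_series, architecture: str, config: TLConfig, seed: int
) -> SourceModel:
    """Pool the source patients' labelled examples and train the source net."""
    hidden, _ = ARCHITECTURES[architecture]
    spec = NetworkSpec(input_dim=config.input_dim, hidden=hidden)
    xs, ys = [], []
    for s in source_series:
        ex = build_examples(s, lag_exposure=config.lag_exposure, expand_to_8=config.expand_to_8)
        model = fit_cutoff(ex.pefr_target, config.quantile, patient_id=s.patient_id)
        X = ex.X
        if config.scaling == "per_patient":
            X = Standardizer.fit(X).transform(X)
        xs.append(X)
        ys.append(model.labels(ex.pefr_target))
    X_pool = np.vstack(xs)
    y_pool = np.concatenate(ys)
    return train_source(
        X_pool, y_pool, spec, config.source_train_config(),
        k=max(config.source_validation_folds, 2),
        seed=substream_seed(seed, "source", architecture),
        validation_folds=config.source_validation_folds,
    )


def run_cohort_tl(
    cohort,
    architectures=("NN_IS", "TL1_IS", "TL2_IS"),
    config: TLConfig = TLConfig(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Evaluate every (patient, architecture); returns per-fold rows and the
    count of trained *target* models per architecture."""
    rows = []
    target_model_counts = {arch: 0 for arch in architectures}
    for arch in architectures:
        for target in cohort:
            others = [s for s in cohort if s.patient_id != target.patient_id]
            src = (
                build_source_model(others, arch, config, substream_seed(seed, target.patient_id))
                if arch != "NN_IS"
                else None
            )
            outcome = evaluate_patient_tl(
                cohort, target.patient_id, arch, config, seed=seed, source=src
            )
            n_targets = len(outcome.fold_results)
            target_model_counts[arch] += n_targets
            for fold, res in enumerate(outcome.fold_results):
                rows.append(
                    {
                        "patient_id": target.patient_id,
                        "architecture": arch,
                        "fold": fold,
                        **res.as_dict(),
                        "skipped_folds": outcome.skipped_folds,
                    }
                )
    return pd.DataFrame(rows), target_model_counts


# ---- serialization ----------------------------------------------------------


def save_model(model: MLP, path, freeze_mask=None, seed: int | None = None) -> None:
    """JSON container: layer sizes, weights, freeze mask, seed metadata."""
    payload = {
        "input_dim": model.spec.input_dim,
        "hidden": list(model.spec.hidden),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "freeze_mask": list(freeze_mask) if freeze_mask is not None else None,
        "seed": seed,
        "total_parameters": count_parameters(model.spec).total,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> MLP:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    spec = NetworkSpec(input_dim=payload["input_dim"], hidden=tuple(payload["hidden"]))
    return MLP(
        spec=spec,
        weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
    )
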