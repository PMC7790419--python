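"""Nine-classifier comparison harness with per-patient cross-validation.

The schemes are the standard tabular classifiers, under their usual
abbreviations: decision trees with Gini or entropy splits (DT-G, DT-E),
random forest (RF), support-vector machine (SVM), K-nearest neighbours
(KNN), gradient boosting (GB), logistic regression (LR), Gaussian naive
Bayes (NB), and a one-hidden-layer perceptron (NN). All use scikit-learn
defaults with fixed seeds; scale-sensitive schemes (SVM, KNN, LR, NN) get a
standardizer fitted on the training split.

Evaluation is per patient: stratified k-fold (default 5) over that
patient's lag-1 examples, optionally applying imbalanced sampling to each
training split. The zoning cutoff is refitted on the training split of
every fold, so no information about held-out days leaks into the labels the
model trains on; fold assignment uses provisional whole-history labels
purely to stratify. Test splits are never resampled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._rng import substream_seed
from .errors import DataError
from .features import Examples
from .metrics import EvalResult, aggregate_folds, confusion
from .resampling import imbalanced_sample
from .zoning import DEFAULT_QUANTILE, fit_cutoff

__all__ = ["SCHEMES", "make_estimator", "FoldOutcome", "train_and_eval", "run_cohort_conventional"]

logger = logging.getLogger(__name__)

SCHEMES = ("DT-G", "DT-E", "RF", "SVM", "KNN", "GB", "LR", "NB", "NN")

_SCALED = frozenset({"SVM", "KNN", "LR", "NN"})


def make_estimator(scheme: str, seed: int = 0):
    """Instantiate one of the nine schemes with library-default settings."""
    if scheme == "DT-G":
        est = DecisionTreeClassifier(criterion="gini", random_state=seed)
    elif scheme == "DT-E":
        est = DecisionTreeClassifier(criterion="entropy", random_state=seed)
    elif scheme == "RF":
        est = RandomForestClassifier(random_state=seed)
    elif scheme == "SVM":
        est = SVC(random_state=seed)
    elif scheme == "KNN":
        est = KNeighborsClassifier()
    elif scheme == "GB":
        est = GradientBoostingClassifier(random_state=seed)
    elif scheme == "LR":
        est = LogisticRegression(max_iter=1000, random_state=seed)
    elif scheme == "NB":
        est = GaussianNB()
    elif scheme == "NN":
        est = MLPClassifier(hidden_layer_sizes=(32,), max_iter=500, random_state=seed)
    else:
        raise DataError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if scheme in _SCALED:
        return make_pipeline(StandardScaler(), est)
    return est


@dataclass
class FoldOutcome:
    """Per-fold confusion results plus their average for one (scheme, patient)."""

    scheme: str
    patient_id: str
    use_is: bool
    fold_results: list[EvalResult] = field(default_factory=list)
    skipped_folds: int = 0

    @property
    def average(self) -> dict[str, float]:
        return aggregate_folds(self.fold_results)


def _make_folds(y_provisional: np.ndarray, k: int, seed: int):
    """Stratified shuffled folds; plain K-fold when a class is too small."""
    counts = np.bincount(y_provisional, minlength=2)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return splitter.split(np.zeros(len(y_provisional)), y_provisional)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return splitter.split(np.zeros(len(y_provisional)))


def train_and_eval(
    scheme: str,
    examples: Examples,
    use_is: bool,
    k: int = 5,
    seed: int = 0,
    quantile: float = DEFAULT_QUANTILE,
) -> FoldOutcome:
    """Cross-validate one scheme on one patient's examples.

    Folds whose training split ends up single-class (after the per-fold
    cutoff refit) are skipped with a warning; the reported fold count
    reflects evaluated folds only.
    """
    if len(examples) < k:
        raise DataError(
            f"patient {examples.patient_id}: {len(examples)} examples < {k} folds"
        )
    pefr = examples.pefr_target
    provisional = fit_cutoff(pefr, quantile).labels(pefr)
    if len(np.unique(provisional)) < 2:
        raise DataError(
            f"patient {examples.patient_id}: provisional labels are single-class"
        )

    fold_seed = substream_seed(seed, "folds", examples.patient_id, scheme)
    outcome = FoldOutcome(scheme=scheme, patient_id=examples.patient_id, use_is=use_is)
    for i, (train_idx, test_idx) in enumerate(_make_folds(provisional, k, fold_seed)):
        cutoff = fit_cutoff(pefr[train_idx], quantile)
        y_train = cutoff.labels(pefr[train_idx])
        y_test = cutoff.labels(pefr[test_idx])
        if len(np.unique(y_train)) < 2:
            logger.warning(
                "skipping fold %d for patient %s / %s: single-class training split",
                i, examples.patient_id, scheme,
            )
            outcome.skipped_folds += 1
            continue
        X_train, X_test = examples.X[train_idx], examples.X[test_idx]
        if use_is:
            rs = imbalanced_sample(
                X_train, y_train, substream_seed(seed, "is", examples.patient_id, scheme, str(i))
            )
            X_train, y_train = rs.X, rs.y
        est = make_estimator(scheme, substream_seed(seed, "est", examples.patient_id, scheme, str(i)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter on tiny folds
            est.fit(X_train, y_train)
        outcome.fold_results.append(confusion(y_test, est.predict(X_test)))
    return outcome


def run_cohort_conventional(
    cohort,
    schemes=SCHEMES,
    use_is_values=(False, True),
    k: int = 5,
    seed: int = 0,
    quantile: float = DEFAULT_QUANTILE,
    lag_exposure: bool = False,
) -> pd.DataFrame:
    """Evaluate every (patient, scheme, IS-flag); one row per evaluated fold."""
    from .features import build_examples

    rows = []
    for series in cohort:
        examples = build_examples(series, lag_exposure=lag_exposure)
        for scheme in schemes:
            for use_is in use_is_values:
                outcome = train_and_eval(scheme, examples, use_is, k=k, seed=seed, quantile=quantile)
                for fold, res in enumerate(outcome.fold_results):
                    rows.append(
                        {
                            "patient_id": series.patient_id,
                            "scheme": scheme,
                            "use_is": use_is,
                            "fold": fold,
                            **res.as_dict(),
                            "skipped_folds": outcome.skipped_folds,
                        }
                    )
    return pd.DataFrame(rows)
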