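"""Imbalanced sampling (IS): combined up-sampling and over-sampling.

The transform balances a binary training set in two steps:

1. *Up-sampling*: the minority class is rebuilt as exactly ``n_major``
   random draws with replacement from the minority pool, so minority and
   majority counts match.
2. *Over-sampling*: every tuple of the balanced set (both classes) is then
   duplicated exactly once, doubling the total.

The output therefore always has ``4 * n_major`` rows split evenly between
the classes, every output row is a copy of some input row, and after the
doubling step every distinct tuple's multiplicity is even. The red zone
(class 0) is ordinarily the minority; if a training split happens to have
class 0 in the majority the roles are swapped so the minority class is
always the one up-sampled. Resampling is only ever applied to training
splits, never to held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["ResamplingResult", "imbalanced_sample"]


@dataclass(frozen=True)
class ResamplingResult:
    """Balanced training set plus an audit trail of how it was built."""

    X: np.ndarray
    y: np.ndarray
    indices: np.ndarray  # row index into the input for every output row
    n0_in: int
    n1_in: int
    n0_out: int
    n1_out: int
    seed: int

    def __len__(self) -> int:
        return len(self.y)

    def to_frame(self, feature_names=None) -> pd.DataFrame:
        """Debug dump: one row per distinct input tuple with its multiplicity."""
        names = list(feature_names) if feature_names is not None else [
            f"x{i}" for i in range(self.X.shape[1])
        ]
        idx, counts = np.unique(self.indices, return_counts=True)
        # one representative output row per distinct source index
        rep = {i: j for j, i in reversed(list(enumerate(self.indices)))}
        frame = pd.DataFrame(self.X[[rep[i] for i in idx]], columns=names)
        frame["label"] = self.y[[rep[i] for i in idx]]
        frame["source_row"] = idx
        frame["multiplicity"] = counts
        return frame


def imbalanced_sample(X, y, seed: int) -> ResamplingResult:
    """Apply the up-/over-sampling transform to a labelled training set.

    ``y`` holds labels in {0, 1}; ``X`` is the matching feature matrix.
    Raises :class:`DataError` if only one class is present (the transform is
    undefined there). Deterministic given ``seed``; seeds differ only in
    which minority tuples the up-sampling step draws.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise DataError("X must be 2-D with one row per label")
    n0_in = int(np.sum(y == 0))
    n1_in = int(np.sum(y == 1))
    if n0_in + n1_in != len(y):
        raise DataError("labels must be 0 or 1")
    if n0_in == 0 or n1_in == 0:
        raise DataError("imbalanced sampling needs both classes present")

    # class 0 is expected minority; swap roles if a split inverts that
    if n0_in <= n1_in:
        minority_idx = np.flatnonzero(y == 0)
        majority_idx = np.flatnonzero(y == 1)
    else:
        minority_idx = np.flatnonzero(y == 1)
        majority_idx = np.flatnonzero(y == 0)

    rng = np.random.default_rng(seed)
    drawn = rng.choice(minority_idx, size=len(majority_idx), replace=True)

    # doubling step: each tuple of the balanced set duplicated exactly once
    out_idx = np.concatenate([drawn, drawn, majority_idx, majority_idx])
    y_out = y[out_idx]
    return ResamplingResult(
        X=X[out_idx],
        y=y_out,
        indices=out_idx,
        n0_in=n0_in,
        n1_in=n1_in,
        n0_out=int(np.sum(y_out == 0)),
        n1_out=int(np.sum(y_out == 1)),
        seed=int(seed),
    )
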