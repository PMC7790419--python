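"""Lag-1 feature construction for the zone classifiers.

Each modelling example predicts today's PEFR zone from yesterday's PEFR and
the four indoor air-quality variables. The raw encoding has 5 features, in
this fixed order::

    (pefr_lag1, pm25, co2, temp, rh)

Exposure features are same-day by default (forecast today's zone from
yesterday's flow and today's indoor environment); ``lag_exposure=True``
takes them from the previous day instead. The first day of a series has no
lag and is dropped, so a series of n days yields n - 1 examples.

An optional expanded 8-feature encoding appends three derived terms
(squared lagged PEFR and two exposure interactions); it exists so the
network parameter audit can be run at input width 8 as well as 5, and is
otherwise equivalent information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import PatientSeries
from .errors import DataError
from .zoning import ZoningModel

__all__ = ["FEATURE_NAMES", "FEATURE_NAMES_8", "Examples", "build_examples"]

FEATURE_NAMES = ("pefr_lag1", "pm25", "co2", "temp", "rh")
FEATURE_NAMES_8 = FEATURE_NAMES + ("pefr_lag1_sq", "pm25_x_co2", "temp_x_rh")


@dataclass(frozen=True)
class Examples:
    """Feature matrix plus the target-day PEFR used for zone labelling."""

    patient_id: str
    X: np.ndarray  # (n, 5) or (n, 8)
    pefr_target: np.ndarray  # (n,) PEFR on the predicted day
    feature_names: tuple[str, ...]
    y: np.ndarray | None = None  # zone labels under some fitted cutoff

    def __len__(self) -> int:
        return len(self.pefr_target)

    def with_labels(self, model: ZoningModel) -> "Examples":
        return Examples(
            patient_id=self.patient_id,
            X=self.X,
            pefr_target=self.pefr_target,
            feature_names=self.feature_names,
            y=model.labels(self.pefr_target),
        )


def _expand8(X5: np.ndarray) -> np.ndarray:
    extra = np.column_stack(
        [X5[:, 0] ** 2, X5[:, 1] * X5[:, 2], X5[:, 3] * X5[:, 4]]
    )
    return np.hstack([X5, extra])


def build_examples(
    series: PatientSeries,
    zoning: ZoningModel | None = None,
    lag_exposure: bool = False,
    expand_to_8: bool = False,
) -> Examples:
    """Build one labelled example per day t >= 2 of a patient series."""
    n = len(series)
    if n < 2:
        raise DataError(
            f"series {series.patient_id} has {n} day(s); need >= 2 for lag features"
        )
    frame = series.to_frame()
    pefr = frame["pefr"].to_numpy(dtype=float)
    expo = frame[["pm25", "co2", "temp", "rh"]].to_numpy(dtype=float)

    pefr_lag = pefr[:-1]
    expo_used = expo[:-1] if lag_exposure else expo[1:]
    X = np.column_stack([pefr_lag, expo_used])
    names = FEATURE_NAMES
    if expand_to_8:
        X = _expand8(X)
        names = FEATURE_NAMES_8

    examples = Examples(
        patient_id=series.patient_id,
        X=X,
        pefr_target=pefr[1:],
        feature_names=names,
    )
    return examples.with_labels(zoning) if zoning is not None else examples
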