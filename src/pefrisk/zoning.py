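"""Personalized exacerbation zoning.

Each patient's "red zone" cutoff is the empirical 20th percentile of their
own historical PEFR distribution; days at or below the cutoff are red
(class 0, the positive class for risk prediction), days above it are safe
(class 1). The quantile is computed with linear interpolation between order
statistics; the method name is recorded on the fitted model so alternative
conventions remain comparable.

Labels: RED = 0, SAFE = 1 throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["RED", "SAFE", "ZoningModel", "fit_cutoff", "label_day", "zoning_report"]

RED = 0  # exacerbation ("red zone"), positive class, usually minority
SAFE = 1

DEFAULT_QUANTILE = 0.20
QUANTILE_METHOD = "linear"


@dataclass(frozen=True)
class ZoningModel:
    """A fitted personalized cutoff."""

    patient_id: str
    cutoff: float  # L/min
    quantile: float
    n_history: int
    method: str = QUANTILE_METHOD

    def labels(self, pefr: np.ndarray | Sequence[float]) -> np.ndarray:
        """Vectorized labelling: RED (0) iff pefr <= cutoff."""
        pefr = np.asarray(pefr, dtype=float)
        if np.any(pefr <= 0):
            raise DataError("pefr values must be positive")
        return np.where(pefr <= self.cutoff, RED, SAFE)


def fit_cutoff(
    history: Iterable[float],
    quantile: float = DEFAULT_QUANTILE,
    patient_id: str = "",
) -> ZoningModel:
    """Fit a patient's cutoff as the empirical quantile of their history."""
    values = np.asarray(list(history), dtype=float)
    if values.size == 0:
        raise DataError("cannot fit a zoning cutoff on an empty history")
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise DataError("history must contain finite, positive PEFR values")
    if not 0.0 < quantile < 1.0:
        raise DataError(f"quantile must be in (0, 1), got {quantile}")
    cutoff = float(np.quantile(values, quantile, method=QUANTILE_METHOD))
    return ZoningModel(
        patient_id=patient_id,
        cutoff=cutoff,
        quantile=quantile,
        n_history=values.size,
    )


def label_day(model: ZoningModel, pefr: float) -> int:
    """RED (0) iff ``pefr <= cutoff``, else SAFE (1)."""
    if not pefr > 0:
        raise DataError(f"pefr must be positive, got {pefr}")
    return RED if pefr <= model.cutoff else SAFE


def zoning_report(models: Sequence[ZoningModel]) -> pd.DataFrame:
    """Tabulate fitted cutoffs, one row per patient."""
    return pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in models],
            "quantile": [m.quantile for m in models],
            "method": [m.method for m in models],
            "cutoff": [m.cutoff for m in models],
            "n_history": [m.n_history for m in models],
        }
    )
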