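"""Synthetic asthma cohort generator.

Simulates per-patient daily time series of peak expiratory flow rate (PEFR,
L/min) together with four indoor air-quality covariates (daily-mean PM2.5,
CO2, temperature, relative humidity). The generator reproduces the
statistical structure the downstream analysis assumes:

* sex-stratified marginal distributions calibrated to published cohort
  summaries (median and interquartile range per variable and sex),
* patient-specific PEFR baselines (between-patient heterogeneity), so a
  population model and an individual model genuinely differ,
* first-order autoregressive day-to-day PEFR dependence, matching the use of
  yesterday's PEFR as a predictor,
* linear same-day exposure effects (negative for PM2.5 and CO2 by default),
* series lengths drawn uniformly on a configured integer range (default
  51-200 days).

PM2.5 and CO2 are log-normal (nonnegative, right-skewed); temperature and
humidity are normal, humidity clipped to [0, 100]. One PEFR value is emitted
per day. All draws flow from an explicit seed, and identical (config, seed)
pairs yield identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream_seed
from .errors import CohortParseError, ConfigError, DataError

__all__ = [
    "QuartileSpec",
    "SexProfile",
    "CohortConfig",
    "DailyObservation",
    "PatientSeries",
    "generate_patient",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "cohort_to_frame",
]

# standard normal upper quartile; converts an IQR to a normal/log-normal scale
_Z75 = 0.6744897501960817

COHORT_COLUMNS = ("patient_id", "sex", "date", "pefr", "pm25", "co2", "temp", "rh")
_NUMERIC_COLUMNS = ("pefr", "pm25", "co2", "temp", "rh")

# floor applied to simulated PEFR so the strictly-positive invariant holds
# even in extreme noise draws; 60 L/min is far below any plausible adult value
_PEFR_FLOOR = 60.0


@dataclass(frozen=True)
class QuartileSpec:
    """Median and quartiles of one variable, as cohort tables report them."""

    median: float
    p25: float
    p75: float

    def __post_init__(self) -> None:
        if not (self.p25 <= self.median <= self.p75):
            raise ConfigError(
                f"quartiles must satisfy p25 <= median <= p75, got {self}"
            )

    @property
    def normal_sd(self) -> float:
        """SD of the normal with this IQR."""
        return (self.p75 - self.p25) / (2.0 * _Z75)

    @property
    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the log-normal with this median and IQR."""
        if self.p25 <= 0:
            raise ConfigError("log-normal calibration needs positive quartiles")
        mu = math.log(self.median)
        sigma = math.log(self.p75 / self.p25) / (2.0 * _Z75)
        return mu, sigma

    @property
    def lognormal_sd(self) -> float:
        mu, sigma = self.lognormal_params
        return (
            math.exp(mu + sigma**2 / 2.0) * math.sqrt(math.expm1(sigma**2))
        )


@dataclass(frozen=True)
class SexProfile:
    """Sex-stratified marginal calibration for PEFR and the four exposures."""

    pefr: QuartileSpec
    pm25: QuartileSpec
    co2: QuartileSpec
    temp: QuartileSpec
    rh: QuartileSpec


# Defaults reproduce the study cohort's published sex-stratified summaries:
# women n=15: PEFR 352 (310-400) L/min, PM2.5 41.1 (28.5-54.7) ug/m3,
#             CO2 1018.5 (847.8-1268.7) ppm, temp 22.6 (21.4-23.6) C,
#             RH 40.6 (33.1-47.9) %
# men   n=10: PEFR 470 (400-600), PM2.5 31.8 (21.9-47.2),
#             CO2 926.2 (729.6-1178.4), temp 22.7 (21.6-24.6),
#             RH 38.3 (31.9-46.9)
FEMALE_DEFAULT = SexProfile(
    pefr=QuartileSpec(352.0, 310.0, 400.0),
    pm25=QuartileSpec(41.1, 28.5, 54.7),
    co2=QuartileSpec(1018.5, 847.8, 1268.7),
    temp=QuartileSpec(22.6, 21.4, 23.6),
    rh=QuartileSpec(40.6, 33.1, 47.9),
)
MALE_DEFAULT = SexProfile(
    pefr=QuartileSpec(470.0, 400.0, 600.0),
    pm25=QuartileSpec(31.8, 21.9, 47.2),
    co2=QuartileSpec(926.2, 729.6, 1178.4),
    temp=QuartileSpec(22.7, 21.6, 24.6),
    rh=QuartileSpec(38.3, 31.9, 46.9),
)


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    Exposure effects are L/min change in same-day PEFR per unit of the
    exposure, applied to the deviation of the exposure from its sex-specific
    median (so nonzero effects do not shift the PEFR median). The default
    PM2.5 and CO2 effects are negative: polluted days depress flow.
    """

    n_patients: int = 25
    frac_female: float = 0.6
    female: SexProfile = field(default_factory=lambda: FEMALE_DEFAULT)
    male: SexProfile = field(default_factory=lambda: MALE_DEFAULT)
    autocorr: float = 0.5  # lag-1 PEFR autocorrelation, in [0, 1)
    beta_pm25: float = -0.35  # L/min per ug/m3
    beta_co2: float = -0.02  # L/min per ppm
    beta_temp: float = 0.0  # L/min per degC
    beta_rh: float = 0.0  # L/min per % RH
    noise_sd: float = 18.0  # innovation SD of the PEFR process, L/min
    min_days: int = 51
    max_days: int = 200
    start_date: date = date(2017, 11, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        if not 0.0 <= self.frac_female <= 1.0:
            raise ConfigError(f"frac_female must be in [0, 1], got {self.frac_female}")
        if not 0.0 <= self.autocorr < 1.0:
            raise ConfigError(f"autocorr must be in [0, 1), got {self.autocorr}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if not 1 <= self.min_days <= self.max_days:
            raise ConfigError(
                f"need 1 <= min_days <= max_days, got {self.min_days}..{self.max_days}"
            )

    def profile(self, sex: str) -> SexProfile:
        if sex == "female":
            return self.female
        if sex == "male":
            return self.male
        raise ConfigError(f"sex must be 'female' or 'male', got {sex!r}")


@dataclass(frozen=True)
class DailyObservation:
    """One patient-day: PEFR plus the four indoor air-quality variables."""

    date: date
    pefr: float  # L/min, > 0
    pm25: float  # ug/m3, >= 0
    co2: float  # ppm, >= 0
    temp: float  # degC
    rh: float  # %, in [0, 100]

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pefr) and self.pefr > 0):
            raise DataError(f"pefr must be finite and positive, got {self.pefr}")
        if self.pm25 < 0 or self.co2 < 0:
            raise DataError("pm25 and co2 must be nonnegative")
        if not 0.0 <= self.rh <= 100.0:
            raise DataError(f"rh must be in [0, 100], got {self.rh}")


@dataclass(frozen=True)
class PatientSeries:
    """Ordered daily observations for one patient."""

    patient_id: str
    sex: str
    observations: tuple[DailyObservation, ...]

    def __post_init__(self) -> None:
        dates = [o.date for o in self.observations]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise DataError(f"dates must be strictly increasing for {self.patient_id}")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def pefr(self) -> np.ndarray:
        return np.array([o.pefr for o in self.observations], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "sex": self.sex,
                "date": [o.date.isoformat() for o in self.observations],
                "pefr": [o.pefr for o in self.observations],
                "pm25": [o.pm25 for o in self.observations],
                "co2": [o.co2 for o in self.observations],
                "temp": [o.temp for o in self.observations],
                "rh": [o.rh for o in self.observations],
            }
        )


def _exposure_effect_var(config: CohortConfig, profile: SexProfile) -> float:
    """Variance of the summed linear exposure terms for one day."""
    return (
        (config.beta_pm25 * profile.pm25.lognormal_sd) ** 2
        + (config.beta_co2 * profile.co2.lognormal_sd) ** 2
        + (config.beta_temp * profile.temp.normal_sd) ** 2
        + (config.beta_rh * profile.rh.normal_sd) ** 2
    )


def _baseline_sd(config: CohortConfig, profile: SexProfile) -> float:
    """Between-patient SD of the PEFR baseline.

    The published IQR pools between-patient and day-to-day variation; the
    between-patient share is what remains after removing the stationary
    within-patient variance of the autoregressive process.
    """
    pooled_var = profile.pefr.normal_sd ** 2
    within_var = (config.noise_sd**2 + _exposure_effect_var(config, profile)) / (
        1.0 - config.autocorr**2
    )
    floor = (0.25 * profile.pefr.normal_sd) ** 2
    return math.sqrt(max(pooled_var - within_var, floor))


def generate_patient(
    config: CohortConfig,
    sex: str,
    seed: int,
    patient_id: str = "P000",
    n_days: int | None = None,
) -> PatientSeries:
    """Simulate one patient's daily series.

    PEFR follows a first-order autoregression around a patient-specific
    baseline with additive same-day exposure effects and Gaussian noise:

        pefr_t = b + phi * (pefr_{t-1} - b)
                 + sum_v beta_v * (x_{v,t} - median_v(sex)) + eps_t

    The first day is drawn from the stationary distribution of the process.
    ``n_days`` overrides the configured uniform length draw when given.
    """
    profile = config.profile(sex)
    rng = np.random.default_rng(seed)

    n = int(n_days) if n_days is not None else int(
        rng.integers(config.min_days, config.max_days + 1)
    )
    if n < 1:
        raise ConfigError(f"n_days must be >= 1, got {n}")

    baseline = rng.normal(profile.pefr.median, _baseline_sd(config, profile))

    pm_mu, pm_sigma = profile.pm25.lognormal_params
    co_mu, co_sigma = profile.co2.lognormal_params
    pm25 = rng.lognormal(pm_mu, pm_sigma, n)
    co2 = rng.lognormal(co_mu, co_sigma, n)
    temp = rng.normal(profile.temp.median, profile.temp.normal_sd, n)
    rh = np.clip(rng.normal(profile.rh.median, profile.rh.normal_sd, n), 0.0, 100.0)

    effects = (
        config.beta_pm25 * (pm25 - profile.pm25.median)
        + config.beta_co2 * (co2 - profile.co2.median)
        + config.beta_temp * (temp - profile.temp.median)
        + config.beta_rh * (rh - profile.rh.median)
    )

    phi = config.autocorr
    stationary_sd = (
        math.sqrt((config.noise_sd**2 + float(np.var(effects))) / (1.0 - phi**2))
        if config.noise_sd > 0 or np.any(effects)
        else 0.0
    )
    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)

    pefr = np.empty(n)
    prev = baseline + (rng.normal(0.0, stationary_sd) if stationary_sd > 0 else 0.0)
    for t in range(n):
        level = baseline + phi * (prev - baseline) + effects[t] + noise[t]
        level = max(level, _PEFR_FLOOR)
        pefr[t] = level
        prev = level

    start = config.start_date
    # 4-decimal precision: below any sensor resolution, and short enough to
    # round-trip exactly through CSV text
    obs = tuple(
        DailyObservation(
            date=start + timedelta(days=t),
            pefr=round(float(pefr[t]), 4),
            pm25=round(float(pm25[t]), 4),
            co2=round(float(co2[t]), 4),
            temp=round(float(temp[t]), 4),
            rh=round(float(rh[t]), 4),
        )
        for t in range(n)
    )
    return PatientSeries(patient_id=patient_id, sex=sex, observations=obs)


def generate_cohort(config: CohortConfig) -> list[PatientSeries]:
    """Simulate the full cohort: round(frac_female * n) women, the rest men."""
    n_female = round(config.frac_female * config.n_patients)
    sexes = ["female"] * n_female + ["male"] * (config.n_patients - n_female)
    cohort = []
    for i, sex in enumerate(sexes):
        pid = f"P{i + 1:03d}"
        seed = substream_seed(config.seed, "cohort", pid)
        cohort.append(generate_patient(config, sex, seed, patient_id=pid))
    return cohort


def cohort_to_frame(cohort: Sequence[PatientSeries]) -> pd.DataFrame:
    if not cohort:
        return pd.DataFrame(columns=list(COHORT_COLUMNS))
    return pd.concat([s.to_frame() for s in cohort], ignore_index=True)


def write_cohort(cohort: Sequence[PatientSeries], path) -> None:
    """Write the cohort as CSV (one row per patient-day, ISO dates, header)."""
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort(path) -> list[PatientSeries]:
    """Read a cohort CSV back into patient series.

    Raises :class:`CohortParseError` naming the offending row and column on
    any non-numeric measurement cell, and :class:`DataError` when a parsed
    value violates a domain invariant.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortParseError(f"cohort CSV missing columns: {missing}")

    numeric: dict[str, np.ndarray] = {}
    for col in _NUMERIC_COLUMNS:
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(
                f"row {row + 2}, column '{col}': could not parse "
                f"{frame[col].iloc[row]!r} as a number"
            )
        numeric[col] = parsed.to_numpy(dtype=float)

    try:
        dates = [date.fromisoformat(d) for d in frame["date"]]
    except ValueError as exc:
        raise CohortParseError(f"column 'date': {exc}") from exc

    cohort = []
    for pid, idx in frame.groupby("patient_id", sort=False).groups.items():
        idx = list(idx)
        sexes = set(frame["sex"].iloc[idx])
        if len(sexes) != 1:
            raise CohortParseError(f"patient {pid} has inconsistent sex values {sexes}")
        obs = tuple(
            DailyObservation(
                date=dates[i],
                pefr=numeric["pefr"][i],
                pm25=numeric["pm25"][i],
                co2=numeric["co2"][i],
                temp=numeric["temp"][i],
                rh=numeric["rh"][i],
            )
            for i in idx
        )
        cohort.append(PatientSeries(patient_id=str(pid), sex=sexes.pop(), observations=obs))
    return cohort


def zero_noise_config(**overrides) -> CohortConfig:
    """Config with all stochastic PEFR structure off (degenerate process)."""
    base = CohortConfig(
        autocorr=0.0,
        beta_pm25=0.0,
        beta_co2=0.0,
        beta_temp=0.0,
        beta_rh=0.0,
        noise_sd=0.0,
    )
    return replace(base, **overrides)
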