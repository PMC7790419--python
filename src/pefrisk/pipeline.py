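"""End-to-end experiment orchestration with a reproducibility manifest.

``run_experiment`` composes the whole analysis: simulate (or load) a
cohort, fit personalized zoning cutoffs, run the nine-classifier comparison
with and without imbalanced sampling, run the transfer-learning protocol,
and aggregate everything to cohort medians/IQRs. Every stochastic step
draws from a named substream of the single root seed, and the manifest
records the full configuration, the derived seeds, software versions and
per-module conventions, so a run can be reproduced exactly from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import substream_seed
from .cohort import CohortConfig, generate_cohort, read_cohort, write_cohort
from .conventional import SCHEMES, run_cohort_conventional
from .metrics import METRIC_NAMES, summarize, summarize_ratio
from .transfer import ARCHITECTURES, TLConfig, run_cohort_tl
from .zoning import DEFAULT_QUANTILE, QUANTILE_METHOD, fit_cutoff, zoning_report

__all__ = ["ExperimentConfig", "run_experiment", "summarize_conventional", "summarize_tl"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    quantile: float = DEFAULT_QUANTILE
    schemes: tuple[str, ...] = SCHEMES
    k_conventional: int = 5
    run_conventional: bool = True
    with_is: bool = True  # False: baseline schemes only, no resampled arm
    run_tl: bool = True
    tl_architectures: tuple[str, ...] = tuple(ARCHITECTURES)
    tl: TLConfig = field(default_factory=TLConfig)
    lag_exposure: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        if "cohort" in raw:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        if "tl" in raw:
            raw["tl"] = TLConfig(**raw["tl"])
        for key in ("schemes", "tl_architectures"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _per_patient_averages(results: pd.DataFrame, group_cols: list[str]) -> pd.DataFrame:
    """Fold-averaged metrics per patient within each group."""
    rows = []
    for keys, grp in results.groupby(group_cols + ["patient_id"], sort=True):
        row = dict(zip(group_cols + ["patient_id"], keys))
        for m in METRIC_NAMES:
            vals = grp[m].to_numpy(dtype=float)
            defined = vals[~np.isnan(vals)]
            row[m] = float(np.mean(defined)) if defined.size else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _summary_block(per_patient: pd.DataFrame) -> dict:
    block = {}
    for m in METRIC_NAMES:
        s = summarize({m: per_patient[m].to_numpy()})[m]
        block[m] = dataclasses.asdict(s)
    block["n_patients"] = int(len(per_patient))
    return block


def summarize_conventional(results: pd.DataFrame) -> dict:
    """Scheme x IS-flag cohort summaries plus after/before-IS ratios."""
    per_patient = _per_patient_averages(results, ["scheme", "use_is"])
    out: dict = {}
    for scheme in sorted(per_patient["scheme"].unique()):
        out[scheme] = {}
        sub = per_patient[per_patient["scheme"] == scheme]
        for use_is in (False, True):
            key = "with_is" if use_is else "without_is"
            grp = sub[sub["use_is"] == use_is]
            if len(grp):
                out[scheme][key] = _summary_block(grp)
        both = sub[sub["use_is"]].merge(
            sub[~sub["use_is"]], on="patient_id", suffixes=("_after", "_before")
        )
        if len(both):
            out[scheme]["is_ratio"] = {
                m: dataclasses.asdict(
                    summarize_ratio(both[f"{m}_after"], both[f"{m}_before"])
                )
                for m in METRIC_NAMES
            }
    return out


def summarize_tl(results: pd.DataFrame) -> dict:
    """Architecture-level cohort summaries."""
    per_patient = _per_patient_averages(results, ["architecture"])
    return {
        arch: _summary_block(per_patient[per_patient["architecture"] == arch])
        for arch in sorted(per_patient["architecture"].unique())
    }


def run_experiment(
    config: ExperimentConfig,
    out_dir,
    cohort_csv=None,
) -> dict:
    """Run the full pipeline and write the results bundle to ``out_dir``.

    ``cohort_csv`` loads an existing cohort instead of simulating one.
    Returns the bundle as a dict (results frames plus summaries).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cohort_csv is not None:
        cohort = read_cohort(cohort_csv)
    else:
        cohort_cfg = dataclasses.replace(
            config.cohort, seed=substream_seed(config.seed, "cohort")
        )
        cohort = generate_cohort(cohort_cfg)
    write_cohort(cohort, out / "cohort.csv")

    zoning_models = [
        fit_cutoff(s.pefr, config.quantile, patient_id=s.patient_id) for s in cohort
    ]
    zoning_report(zoning_models).to_csv(out / "zoning.csv", index=False)

    bundle: dict = {"cohort": cohort}
    summary: dict = {}
    target_counts: dict[str, int] = {}

    if config.run_conventional:
        conv = run_cohort_conventional(
            cohort,
            schemes=config.schemes,
            use_is_values=(False, True) if config.with_is else (False,),
            k=config.k_conventional,
            seed=substream_seed(config.seed, "conventional"),
            quantile=config.quantile,
            lag_exposure=config.lag_exposure,
        )
        conv.to_csv(out / "conventional_results.csv", index=False)
        summary["conventional"] = summarize_conventional(conv)
        bundle["conventional"] = conv

    if config.run_tl:
        tl_cfg = dataclasses.replace(
            config.tl, quantile=config.quantile, lag_exposure=config.lag_exposure
        )
        tl, target_counts = run_cohort_tl(
            cohort,
            architectures=config.tl_architectures,
            config=tl_cfg,
            seed=substream_seed(config.seed, "transfer"),
        )
        tl.to_csv(out / "tl_results.csv", index=False)
        summary["transfer"] = summarize_tl(tl)
        bundle["tl"] = tl

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, allow_nan=True, default=float)

    manifest = {
        "package_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "root_seed": config.seed,
        "substream_seeds": {
            name: substream_seed(config.seed, name)
            for name in ("cohort", "conventional", "transfer")
        },
        "config": _config_dict(config),
        "conventions": {
            "quantile_method": QUANTILE_METHOD,
            "red_zone_rule": "pefr <= per-patient training-split quantile cutoff",
            "positive_class": "red zone (label 0)",
            "feature_order": "pefr_lag1, pm25, co2, temp, rh",
            "input_dim": config.tl.input_dim,
            "nn_optimizer": "adam lr=1e-3 full-batch, binary cross entropy",
        },
        "tl_target_models_trained": target_counts,
        "library_versions": _library_versions(),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)

    bundle["summary"] = summary
    bundle["manifest"] = manifest
    return bundle


def _config_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cohort"]["start_date"] = config.cohort.start_date.isoformat()
    return d


def _library_versions() -> dict:
    import sklearn

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
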