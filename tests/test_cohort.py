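"""Synthetic cohort generator: process structure, calibration, CSV I/O."""

import io

import numpy as np
import pytest

from pefrisk._rng import substream_seed
from pefrisk.cohort import (
    CohortConfig,
    cohort_to_frame,
    generate_cohort,
    generate_patient,
    read_cohort,
    write_cohort,
    zero_noise_config,
)
from pefrisk.errors import CohortParseError, ConfigError


class TestGeneratePatient:
    def test_degenerate_process_is_constant_at_baseline(self):
        """No noise, no exposure effects, no autocorrelation: PEFR is flat."""
        series = generate_patient(zero_noise_config(), "female", seed=3, n_days=40)
        pefr = series.pefr
        assert np.all(pefr == pefr[0])
        assert len(series) == 40

    def test_dates_strictly_increasing_and_invariants_hold(self, small_cohort):
        for series in small_cohort:
            frame = series.to_frame()
            dates = frame["date"].to_numpy()
            assert np.all(dates[1:] > dates[:-1])
            assert np.all(frame["pefr"] > 0)
            assert np.all(frame["pm25"] >= 0)
            assert np.all(frame["co2"] >= 0)
            assert frame["rh"].between(0, 100).all()

    def test_series_length_within_configured_bounds(self):
        config = CohortConfig(min_days=51, max_days=200)
        lengths = [
            len(generate_patient(config, "male", seed=s)) for s in range(30)
        ]
        assert all(51 <= n <= 200 for n in lengths)
        assert len(set(lengths)) > 1  # lengths actually vary

    def test_negative_pm25_effect_depresses_flow_on_every_seed(self):
        """Monte-Carlo sign check: strong negative PM2.5 effect makes PM2.5
        negatively correlated with both same-day and next-day PEFR."""
        config = zero_noise_config(beta_pm25=-2.0, autocorr=0.5)
        for seed in range(20):
            series = generate_patient(config, "female", seed=seed, n_days=200)
            frame = series.to_frame()
            pm25 = frame["pm25"].to_numpy()
            pefr = frame["pefr"].to_numpy()
            assert np.corrcoef(pm25, pefr)[0, 1] < 0
            assert np.corrcoef(pm25[:-1], pefr[1:])[0, 1] < 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(noise_sd=-1.0)
        with pytest.raises(ConfigError):
            CohortConfig(autocorr=1.0)
        with pytest.raises(ConfigError):
            CohortConfig(frac_female=1.5)
        with pytest.raises(ConfigError):
            CohortConfig(min_days=0)
        with pytest.raises(ConfigError):
            generate_patient(CohortConfig(), "other", seed=0)


class TestGenerateCohort:
    def test_default_cohort_matches_study_composition(self):
        cohort = generate_cohort(CohortConfig(seed=9))
        assert len(cohort) == 25
        assert sum(s.sex == "female" for s in cohort) == 15
        assert sum(s.sex == "male" for s in cohort) == 10

    def test_single_patient_cohort(self):
        cohort = generate_cohort(CohortConfig(n_patients=1, frac_female=1.0, seed=0))
        assert len(cohort) == 1
        assert cohort[0].sex == "female"

    def test_same_config_and_seed_give_byte_identical_csv(self):
        config = CohortConfig(n_patients=3, min_days=51, max_days=60, seed=11)
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_cohort(generate_cohort(config), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_sex_calibration_medians_match_published_summaries(self):
        """Sex-stratified medians of PEFR/PM2.5/CO2 within 5% of the cohort
        table (women 352 L/min, 41.1 ug/m3, 1018.5 ppm; men 470, 31.8,
        926.2) on >=10,000 simulated patient-days per sex."""
        targets = {
            "female": {"pefr": 352.0, "pm25": 41.1, "co2": 1018.5},
            "male": {"pefr": 470.0, "pm25": 31.8, "co2": 926.2},
        }
        config = CohortConfig(seed=2021)
        for sex, expected in targets.items():
            series = [
                generate_patient(
                    config, sex, substream_seed(2021, "calibration", sex, str(i))
                )
                for i in range(500)
            ]
            frame = cohort_to_frame(series)
            assert len(frame) >= 10_000
            for col, target in expected.items():
                median = float(frame[col].median())
                assert median == pytest.approx(target, rel=0.05), (sex, col)


class TestCohortCSV:
    def test_round_trip_identity(self, tmp_path):
        cohort = generate_cohort(
            CohortConfig(n_patients=2, min_days=51, max_days=55, seed=5)
        )
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert back == cohort

    def test_empty_cohort_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_cohort([], path)
        lines = path.read_text().strip().splitlines()
        assert lines == ["patient_id,sex,date,pefr,pm25,co2,temp,rh"]

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "patient_id,sex,date,pefr,pm25,co2,temp,rh\n"
            "P1,female,2018-01-01,400,30,900,22,40\n"
            "P1,female,2018-01-02,oops,30,900,22,40\n"
        )
        with pytest.raises(CohortParseError, match=r"row 3.*pefr.*oops"):
            read_cohort(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("patient_id,sex,date,pefr\nP1,female,2018-01-01,400\n")
        with pytest.raises(CohortParseError, match="missing columns"):
            read_cohort(path)
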