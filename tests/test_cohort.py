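import datetime as dt

import numpy as np
import pandas as pd
import pytest

from pdcshift.adherence import pdc_table
from pdcshift.cohort import (
    WaveAssignmentError,
    apply_inclusion,
    assign_wave,
    build_analysis_dataset,
    covariate_columns,
    impute_and_flag,
)


def twelve_patient_fixture():
    """Hand-built tables exercising every inclusion/exclusion branch.

    Expected outcome (hand-derived):
      p01 eligible, wave 1            — consecutive months before test
      p02 excluded                    — single prescription
      p03 excluded                    — months not consecutive (Jan, Mar)
      p04 eligible, wave 2            — test on the 2020-10-04 boundary
      p05 eligible, wave 3            — test on the 2021-05-30 boundary
      p06 eligible, wave 1            — test on the 2020-10-03 boundary
      p07 eligible, wave 2            — test on the 2021-05-29 boundary
      p08 excluded                    — never tested positive
      p09 excluded                    — two dispensings in the same month
      p10 excluded                    — dispensings only after the test
      p11 eligible but later dropped  — missing pre-existing conditions
      p12 eligible, wave 2            — anchored on most recent positive
    """
    def rx(pid, *dates):
        return [{"patient_id": pid, "dispense_date": d, "boxes": 2} for d in dates]

    prescriptions = pd.DataFrame(
        rx("p01", "2020-01-15", "2020-02-10", "2020-03-05")
        + rx("p02", "2020-01-15")
        + rx("p03", "2020-01-15", "2020-03-15")
        + rx("p04", "2020-08-01", "2020-09-01")
        + rx("p05", "2021-03-20", "2021-04-18")
        + rx("p06", "2020-08-02", "2020-09-02")
        + rx("p07", "2021-03-01", "2021-04-01")
        + rx("p08", "2020-01-10", "2020-02-10")
        + rx("p09", "2020-03-02", "2020-03-25")
        + rx("p10", "2020-06-10", "2020-07-10")
        + rx("p11", "2020-01-20", "2020-02-20")
        + rx("p12", "2020-06-01", "2020-07-01", "2020-10-20", "2020-11-20")
    )

    tests = pd.DataFrame(
        [
            {"patient_id": "p01", "test_date": "2020-04-01", "result": 1},
            {"patient_id": "p02", "test_date": "2020-04-01", "result": 1},
            {"patient_id": "p03", "test_date": "2020-05-01", "result": 1},
            {"patient_id": "p04", "test_date": "2020-10-04", "result": 1},
            {"patient_id": "p05", "test_date": "2021-05-30", "result": 1},
            {"patient_id": "p06", "test_date": "2020-10-03", "result": 1},
            {"patient_id": "p07", "test_date": "2021-05-29", "result": 1},
            {"patient_id": "p08", "test_date": "2020-05-01", "result": 0},
            {"patient_id": "p09", "test_date": "2020-05-01", "result": 1},
            {"patient_id": "p10", "test_date": "2020-05-01", "result": 1},
            {"patient_id": "p11", "test_date": "2020-04-15", "result": 1},
            {"patient_id": "p12", "test_date": "2020-08-01", "result": 1},
            {"patient_id": "p12", "test_date": "2020-12-15", "result": 1},
        ]
    )

    covariates = pd.DataFrame(
        {
            "patient_id": [f"p{i:02d}" for i in range(1, 13)],
            "age": np.linspace(40, 75, 12),
            "sex": [0, 1] * 6,
            "cond_hypertension": [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, np.nan, 0],
            "metformin_months": 14.0,
            "fac_education": [9.0, 8.5, np.nan, 10.0, 9.2, np.nan, 9.8, 9.1, 9.5, 9.9, 9.3, 8.8],
        }
    )
    deaths = pd.DataFrame(
        {"patient_id": [f"p{i:02d}" for i in range(1, 13)], "deceased": [0, 1] * 6}
    )
    expected_eligible = ["p01", "p04", "p05", "p06", "p07", "p11", "p12"]
    expected_waves = {"p01": 1, "p04": 2, "p05": 3, "p06": 1, "p07": 2, "p12": 2}
    return prescriptions, tests, covariates, deaths, expected_eligible, expected_waves


class TestAssignWave:
    @pytest.mark.parametrize(
        "date,wave",
        [
            ("2020-04-01", 1),
            ("2020-03-29", 1),
            ("2020-10-03", 1),
            ("2020-10-04", 2),
            ("2021-05-29", 2),
            ("2021-05-30", 3),
            ("2021-12-18", 3),
        ],
    )
    def test_printed_boundaries(self, date, wave):
        assert assign_wave(date) == wave

    def test_early_march_grace_folds_into_wave1(self):
        assert assign_wave("2020-03-15") == 1
        with pytest.raises(WaveAssignmentError):
            assign_wave("2020-03-15", early_to_wave1=False)

    def test_out_of_range_raises(self):
        with pytest.raises(WaveAssignmentError):
            assign_wave("2022-01-01")

    def test_partition_exhaustive_and_exclusive(self):
        day = dt.date(2020, 3, 29)
        prev = 0
        while day <= dt.date(2021, 12, 18):
            w = assign_wave(day)
            assert w in (1, 2, 3) and w >= prev
            prev = w
            day += dt.timedelta(days=1)


class TestApplyInclusion:
    def test_twelve_patient_fixture(self):
        rx, tests, *_ , expected, _waves = twelve_patient_fixture()
        eligible, attrition = apply_inclusion(tests, rx)
        assert list(eligible["patient_id"]) == expected
        # attrition counts never increase along the rule sequence
        counts = list(attrition.values())
        assert counts == sorted(counts, reverse=True)

    def test_anchor_is_most_recent_positive(self):
        rx, tests, *_ = twelve_patient_fixture()
        eligible, _ = apply_inclusion(tests, rx)
        anchor = eligible.set_index("patient_id")["anchor_test_date"]
        assert anchor["p12"] == pd.Timestamp("2020-12-15")

    def test_empty_result_allowed(self):
        tests = pd.DataFrame(
            [{"patient_id": "x", "test_date": "2020-05-01", "result": 0}]
        )
        rx = pd.DataFrame(
            [{"patient_id": "x", "dispense_date": "2020-01-01", "boxes": 1}]
        )
        eligible, attrition = apply_inclusion(tests, rx)
        assert eligible.empty and attrition["positive_test"] == 0


class TestImputeAndFlag:
    def test_median_imputation_with_indicator(self):
        df = pd.DataFrame({"x": [1.0, 2.0, np.nan, 4.0]})
        out = impute_and_flag(df)
        assert out["x"].tolist() == [1.0, 2.0, 2.0, 4.0]
        assert out["x_missing"].tolist() == [0, 0, 1, 0]

    def test_fully_observed_column_untouched(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [np.nan, 3.0]})
        out = impute_and_flag(df)
        assert "x_missing" not in out.columns
        assert "y_missing" in out.columns

    def test_one_indicator_per_incomplete_variable(self):
        df = pd.DataFrame({"a": [np.nan, 1.0], "b": [2.0, np.nan], "c": [1.0, 1.0]})
        out = impute_and_flag(df)
        flags = [c for c in out.columns if c.endswith("_missing")]
        assert sorted(flags) == ["a_missing", "b_missing"]

    def test_idempotent(self):
        df = pd.DataFrame({"x": [1.0, np.nan, 3.0]})
        once = impute_and_flag(df)
        twice = impute_and_flag(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_entirely_missing_column_errors(self):
        with pytest.raises(ValueError, match="entirely missing"):
            impute_and_flag(pd.DataFrame({"x": [np.nan, np.nan]}))


class TestBuildAnalysisDataset:
    def _build(self):
        rx, tests, covariates, deaths, _, waves = twelve_patient_fixture()
        eligible, attrition = apply_inclusion(tests, rx)
        anchors = eligible.set_index("patient_id")["anchor_test_date"]
        ends = (pd.to_datetime(anchors) - pd.Timedelta(days=1)).to_dict()
        pdc = pdc_table(rx, ends)
        data = build_analysis_dataset(
            eligible, pdc, covariates, tests, deaths, attrition=attrition
        )
        return data, attrition, waves

    def test_schema_and_waves(self):
        data, _, waves = self._build()
        assert list(data["patient_id"]) == sorted(waves)  # p11 dropped
        assert dict(zip(data["patient_id"], data["wave"])) == waves
        assert data["A"].between(0, 1).all()
        assert set(data["Y"]) <= {0, 1}
        assert set(data["neg_ctrl"]) <= {0, 1}

    def test_missing_preexisting_dropped_and_counted(self):
        data, attrition, _ = self._build()
        assert "p11" not in set(data["patient_id"])
        assert attrition["complete_preexisting"] == len(data)

    def test_facility_missingness_imputed_with_flags(self):
        data, _, _ = self._build()
        assert data["fac_education"].notna().all()
        assert "fac_education_missing" in data.columns

    def test_duplicate_patient_errors(self):
        rx, tests, covariates, deaths, *_ = twelve_patient_fixture()
        eligible, _ = apply_inclusion(tests, rx)
        dup = pd.concat([eligible, eligible.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            build_analysis_dataset(dup, pd.DataFrame(), covariates, tests, deaths)

    def test_covariate_columns_excludes_identifiers_and_outcomes(self):
        data, _, _ = self._build()
        cols = covariate_columns(data)
        assert {"patient_id", "A", "Y", "wave", "neg_ctrl"}.isdisjoint(cols)
        assert "age" in cols and "fac_education_missing" in cols
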