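import datetime as dt

import numpy as np
import pandas as pd
import pytest

from pdcshift.adherence import pdc_table
from pdcshift.synthetic import (
    ConfigurationError,
    GenerationError,
    ScmParams,
    generate_cohort,
    generate_prescriptions,
    generate_tests,
    inject_missingness,
    outcome_probability,
    split_tables,
    true_shift_effect,
    FACILITY_VARS,
)
from .conftest import brute_force_days_covered
from pdcshift.adherence import ObservationWindow, PrescriptionRecord


class TestScmParams:
    def test_serialization_round_trip_is_lossless(self):
        p = ScmParams(n=123, seed=9)
        q = ScmParams.from_dict(p.to_dict())
        assert p == q

    @pytest.mark.parametrize(
        "bad",
        [
            {"n": 0},
            {"wave_weights": (0.5, 0.5, 0.5)},
            {"adh_concentration": -1.0},
            {"miss_rates": {"fac_education": 1.5}},
            {"miss_rates": {"age": 0.1}},
            {"y_coefs": {"no_such_var": 1.0}},
        ],
    )
    def test_invalid_configuration_names_the_field(self, bad):
        with pytest.raises(ConfigurationError):
            ScmParams(**bad)


class TestGenerateCohort:
    def test_marginal_moments_match_targets(self):
        p = ScmParams(n=50000, seed=7)
        c = generate_cohort(p)
        assert c["A"].mean() == pytest.approx(p.target_pdc_mean, abs=0.02)
        assert c["A"].std() == pytest.approx(p.target_pdc_sd, abs=0.02)
        for wave, target in zip((1, 2, 3), p.target_mortality_by_wave):
            got = c.loc[c["wave"] == wave, "Y"].mean()
            assert got == pytest.approx(target, abs=0.02)

    def test_same_seed_byte_identical(self):
        p = ScmParams(n=2000, seed=42)
        c1, c2 = generate_cohort(p), generate_cohort(p)
        assert c1.to_csv(index=False) == c2.to_csv(index=False)

    def test_intercept_only_outcome_model_hits_half(self):
        p = ScmParams(
            n=30000, seed=3, y_coef_a=0.0, y_coefs={}, y_wave_intercepts=(0.0, 0.0, 0.0)
        )
        c = generate_cohort(p)
        assert c["Y"].mean() == pytest.approx(0.5, abs=0.01)

    def test_schema_invariants(self, small_cohort):
        c = small_cohort
        assert c["patient_id"].is_unique
        assert c["A"].between(0, 1).all()
        assert set(c["Y"]) <= {0, 1}
        assert set(c["wave"]) <= {1, 2, 3}
        # vaccination only appears after wave 1
        assert c.loc[c["wave"] == 1, "vaccine_doses"].eq(0).all()

    def test_test_dates_fall_in_assigned_wave(self, small_cohort):
        from pdcshift.cohort import assign_wave

        waves = small_cohort["test_date"].map(assign_wave)
        assert (waves == small_cohort["wave"]).all()


class TestGeneratePrescriptions:
    def test_full_adherence_gapless_window(self):
        cohort = pd.DataFrame(
            {
                "patient_id": ["x"],
                "metformin_months": [10.0],
                "test_date": [dt.date(2020, 12, 1)],
                "A": [1.0],
            }
        )
        p = ScmParams(n=1, seed=0)
        rx = generate_prescriptions(cohort, p)
        records = [
            PrescriptionRecord("x", pd.Timestamp(r.dispense_date).date(), int(r.boxes),
                               int(r.tablets_per_box), float(r.tablets_per_day))
            for r in rx.itertuples()
        ]
        end = dt.date(2020, 11, 30)
        start = end - dt.timedelta(days=299)
        window = ObservationWindow(start, end)
        assert brute_force_days_covered(records, window) == 300

    def test_half_adherence_covers_150_of_300_days(self):
        cohort = pd.DataFrame(
            {
                "patient_id": ["x"],
                "metformin_months": [10.0],
                "test_date": [dt.date(2020, 12, 1)],
                "A": [0.5],
            }
        )
        rx = generate_prescriptions(cohort, ScmParams(n=1, seed=0))
        records = [
            PrescriptionRecord("x", pd.Timestamp(r.dispense_date).date(), int(r.boxes),
                               int(r.tablets_per_box), float(r.tablets_per_day))
            for r in rx.itertuples()
        ]
        end = dt.date(2020, 11, 30)
        window = ObservationWindow(end - dt.timedelta(days=299), end)
        assert abs(brute_force_days_covered(records, window) - 150) <= 3

    def test_round_trip_recovers_adherence_within_tolerance(self):
        p = ScmParams(n=100, seed=31, miss_rates={})
        cohort = generate_cohort(p)
        rx = generate_prescriptions(cohort, p)
        ends = {
            r.patient_id: pd.Timestamp(r.test_date) - pd.Timedelta(days=1)
            for r in cohort.itertuples()
        }
        table = pdc_table(rx, ends)
        merged = cohort.merge(table[["patient_id", "pdc"]], on="patient_id")
        assert len(merged) == len(cohort)
        assert np.max(np.abs(merged["pdc"] - merged["A"])) <= 0.01

    def test_at_least_two_consecutive_dispense_months(self):
        p = ScmParams(n=50, seed=12, miss_rates={})
        cohort = generate_cohort(p)
        rx = generate_prescriptions(cohort, p)
        months = pd.to_datetime(rx["dispense_date"])
        rx = rx.assign(month=months.dt.year * 12 + months.dt.month)
        for _, grp in rx.groupby("patient_id"):
            m = np.sort(grp["month"].unique())
            assert len(m) >= 2 and np.any(np.diff(m) == 1)

    def test_unreachable_target_raises_listing_patient(self):
        cohort = pd.DataFrame(
            {
                "patient_id": ["low"],
                "metformin_months": [10.0],
                "test_date": [dt.date(2020, 12, 1)],
                "A": [0.02],
            }
        )
        with pytest.raises(GenerationError, match="low"):
            generate_prescriptions(cohort, ScmParams(n=1, seed=0))


class TestInjectMissingness:
    def test_zero_rates_leave_cohort_unchanged(self, small_cohort):
        p = ScmParams(n=10, seed=1, miss_rates={v: 0.0 for v in FACILITY_VARS})
        out = inject_missingness(small_cohort, p)
        pd.testing.assert_frame_equal(out, small_cohort)

    def test_realized_fraction_within_binomial_bounds(self):
        p = ScmParams(n=10000, seed=5, miss_rates={"fac_education": 0.10})
        cohort = generate_cohort(p.replace(miss_rates={}))
        out = inject_missingness(cohort, p)
        n_missing = out["fac_education"].isna().sum()
        assert 900 <= n_missing <= 1100

    def test_default_rates_realized_in_band(self):
        p = ScmParams(n=6000, seed=6)
        out = inject_missingness(generate_cohort(p.replace(miss_rates={})), p)
        for var, rate in p.miss_rates.items():
            frac = out[var].isna().mean()
            assert 0.01 <= frac <= 0.15, (var, frac)

    def test_individual_level_variables_untouched(self, small_cohort):
        p = ScmParams(n=10, seed=2)
        out = inject_missingness(small_cohort, p)
        for col in ("age", "sex", "metformin_months", "A", "Y"):
            assert out[col].notna().all()


class TestTrueShiftEffect:
    def test_zero_shift_gives_exact_null(self):
        psi, se = true_shift_effect(ScmParams(n=10, seed=0), 0.0, n_mc=5000, seed=1)
        assert psi == 0.0 and se == 0.0

    def test_no_adherence_effect_gives_null(self):
        p = ScmParams(n=10, seed=0, y_coef_a=0.0)
        psi, se = true_shift_effect(p, 0.1, n_mc=100_000, seed=2)
        assert abs(psi) <= 2 * max(se, 1e-12)

    def test_monotone_in_delta_for_protective_exposure(self):
        p = ScmParams(n=10, seed=0)
        psis = [
            true_shift_effect(p, d, n_mc=200_000, seed=3)[0]
            for d in (0.0, 0.05, 0.1, 0.2)
        ]
        assert psis == sorted(psis)
        assert psis[-1] > 0

    def test_positive_effect_under_default_confounding(self):
        psi, se = true_shift_effect(ScmParams(n=10, seed=0), 0.1, n_mc=200_000, seed=4)
        assert psi > 10 * se  # clearly positive


def test_split_tables_align_with_cohort(small_cohort):
    covariates, deaths = split_tables(small_cohort)
    assert len(covariates) == len(deaths) == len(small_cohort)
    assert (deaths["deceased"] == small_cohort["Y"]).all()


def test_generate_tests_anchors_most_recent_positive(small_cohort):
    p = ScmParams(n=10, seed=3)
    tests = generate_tests(small_cohort, p)
    pos = tests[tests["result"] == 1]
    assert len(pos) == len(small_cohort)
    merged = pos.merge(small_cohort[["patient_id", "test_date"]], on="patient_id")
    assert (pd.to_datetime(merged["test_date_x"]) == pd.to_datetime(merged["test_date_y"])).all()
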