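"""Synthetic cohort generator with a known-counterfactual truth oracle.

The generator emulates an insurance-claims cohort of chronic metformin
users who tested positive for SARS-CoV-2: 14 confounders (individual-level
age, sex, four pre-existing-condition indicators, months on metformin,
vaccine doses; facility-level population, insurance-affiliation proportion,
disabled proportion, average education, illiteracy rate, occupants per
room), a continuous adherence exposure A (PDC on [0, 1]), a binary
mortality outcome Y, a three-wave calendar structure, and a negative-
control outcome driven by confounders only.

The data-generating process is a structural causal model with explicit
exogenous errors:

* W  ~ the covariate distributions below (waves drawn with fixed weights,
  vaccination probability depending on wave);
* A | W ~ Beta(mu(W) * phi, (1 - mu(W)) * phi) with logit mu(W) linear in
  standardized covariates — marginal mean ~0.81, sd ~0.13;
* Y | A, W ~ Bernoulli(expit(c_wave + beta_A * A + beta_W' z(W)));
* negative control | W ~ Bernoulli(expit(c_nc + gamma' z(W))), no A term,
  so its true shift effect is exactly zero.

Because the outcome probability is an explicit function, the true effect of
any shift policy can be computed by Monte-Carlo counterfactual simulation
(:func:`true_shift_effect`), which downstream estimators are tested
against.  All covariate standardizations are affine in the raw columns
(facility population enters no structural equation), so a main-terms
logistic model on the raw analysis columns is an exactly correct outcome
model — the "correctly specified parametric nuisance" condition used in the
recovery and coverage simulations.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import WAVE_BOUNDS

__all__ = [
    "ScmParams",
    "generate_cohort",
    "generate_prescriptions",
    "generate_tests",
    "split_tables",
    "inject_missingness",
    "true_shift_effect",
    "outcome_probability",
]

FACILITY_VARS = [
    "fac_population",
    "fac_imss_prop",
    "fac_disabled_prop",
    "fac_education",
    "fac_illiteracy",
    "fac_occupants_per_room",
]

CONDITION_VARS = ["cond_hypertension", "cond_obesity", "cond_ckd", "cond_cardio"]

COVARIATES = (
    ["age", "sex"]
    + CONDITION_VARS
    + ["metformin_months", "vaccine_doses"]
    + FACILITY_VARS
)

# Affine standardizations z = (x - center) / scale applied inside the
# structural equations (facility population is standardized on the log
# scale but carries zero structural weight by default).
_Z_CENTER = {
    "age": 58.0,
    "sex": 0.5,
    "cond_hypertension": 0.45,
    "cond_obesity": 0.35,
    "cond_ckd": 0.08,
    "cond_cardio": 0.12,
    "metformin_months": 14.0,
    "vaccine_doses": 0.0,
    "fac_population": np.log(30000.0),
    "fac_imss_prop": 0.667,
    "fac_disabled_prop": 0.0625,
    "fac_education": 9.5,
    "fac_illiteracy": 0.074,
    "fac_occupants_per_room": 1.1,
}
_Z_SCALE = {
    "age": 12.0,
    "sex": 1.0,
    "cond_hypertension": 1.0,
    "cond_obesity": 1.0,
    "cond_ckd": 1.0,
    "cond_cardio": 1.0,
    "metformin_months": 8.0,
    "vaccine_doses": 1.0,
    "fac_population": 0.6,
    "fac_imss_prop": 0.13,
    "fac_disabled_prop": 0.04,
    "fac_education": 1.5,
    "fac_illiteracy": 0.05,
    "fac_occupants_per_room": 0.3,
}

# Intercepts calibrated once (Monte Carlo, n = 2,000,000) so the default
# marginal moments match the emulation targets: PDC mean 0.81 / sd 0.13,
# per-wave mortality 31.8% / 35.9% / 35.8%.  See docs/methods.md.
_DEFAULT_ADH_INTERCEPT = 1.4381
_DEFAULT_ADH_CONCENTRATION = 9.234
_DEFAULT_Y_WAVE_INTERCEPTS = (0.1428, 0.3731, 0.4640)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class ConfigurationError(ValueError):
    """Invalid structural-model configuration; names the offending field."""


class GenerationError(RuntimeError):
    """A target quantity is unreachable with the configured granularity."""


@dataclass
class ScmParams:
    """Full parameterization of the synthetic structural causal model."""

    n: int = 10000
    seed: int = 0
    wave_weights: tuple = (0.355, 0.465, 0.180)
    p_vacc_by_wave: tuple = (0.0, 0.08, 0.35)

    adh_intercept: float = _DEFAULT_ADH_INTERCEPT
    adh_concentration: float = _DEFAULT_ADH_CONCENTRATION
    adh_coefs: dict = field(
        default_factory=lambda: {
            "age": 0.18,
            "cond_hypertension": 0.08,
            "cond_obesity": -0.05,
            "metformin_months": 0.15,
            "fac_education": 0.12,
            "fac_occupants_per_room": -0.12,
        }
    )

    y_wave_intercepts: tuple = _DEFAULT_Y_WAVE_INTERCEPTS
    y_coef_a: float = -1.2
    y_coefs: dict = field(
        default_factory=lambda: {
            "age": 0.55,
            "sex": -0.15,
            "cond_hypertension": 0.25,
            "cond_obesity": 0.30,
            "cond_ckd": 0.45,
            "cond_cardio": 0.35,
            "metformin_months": -0.05,
            "vaccine_doses": -0.25,
            "fac_education": -0.15,
            "fac_occupants_per_room": 0.20,
            "fac_illiteracy": 0.10,
        }
    )

    nc_intercept: float = 0.2067
    nc_coefs: dict = field(
        default_factory=lambda: {
            "age": 0.20,
            "sex": 0.05,
            "fac_education": -0.15,
            "fac_occupants_per_room": 0.25,
        }
    )

    miss_rates: dict = field(
        default_factory=lambda: {
            "fac_population": 0.03,
            "fac_imss_prop": 0.05,
            "fac_disabled_prop": 0.12,
            "fac_education": 0.06,
            "fac_illiteracy": 0.09,
            "fac_occupants_per_room": 0.04,
        }
    )

    # Emulation targets (documentation; checked by the test suite).
    target_pdc_mean: float = 0.81
    target_pdc_sd: float = 0.13
    target_mortality_by_wave: tuple = (0.318, 0.359, 0.358)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        if len(self.wave_weights) != 3 or any(w < 0 for w in self.wave_weights):
            raise ConfigurationError(f"wave_weights invalid: {self.wave_weights}")
        if abs(sum(self.wave_weights) - 1.0) > 1e-8:
            raise ConfigurationError(
                f"wave_weights must sum to 1, got {sum(self.wave_weights)}"
            )
        for name, p in zip(("wave1", "wave2", "wave3"), self.p_vacc_by_wave):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"p_vacc_by_wave[{name}] = {p} outside [0, 1]")
        if not self.adh_concentration > 0:
            raise ConfigurationError(
                f"adh_concentration must be > 0, got {self.adh_concentration}"
            )
        for field_name, coefs in (
            ("adh_coefs", self.adh_coefs),
            ("y_coefs", self.y_coefs),
            ("nc_coefs", self.nc_coefs),
        ):
            unknown = set(coefs) - set(COVARIATES)
            if unknown:
                raise ConfigurationError(
                    f"{field_name} references unknown covariates {sorted(unknown)}"
                )
        for var, rate in self.miss_rates.items():
            if var not in FACILITY_VARS:
                raise ConfigurationError(
                    f"miss_rates key {var!r} is not a facility variable"
                )
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"miss_rates[{var}] = {rate} outside [0, 1]")

    # -- lossless serialization -------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScmParams":
        kwargs = dict(d)
        for k in ("wave_weights", "p_vacc_by_wave", "y_wave_intercepts",
                  "target_mortality_by_wave"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    def replace(self, **changes) -> "ScmParams":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# Structural equations
# ---------------------------------------------------------------------------


def _zscore(df: pd.DataFrame, var: str) -> np.ndarray:
    x = df[var].to_numpy(dtype=float)
    if var == "fac_population":
        x = np.log(np.maximum(x, 1.0))
    return (x - _Z_CENTER[var]) / _Z_SCALE[var]


def _linear_predictor(df: pd.DataFrame, intercept, coefs: dict) -> np.ndarray:
    eta = np.broadcast_to(np.asarray(intercept, dtype=float), len(df)).copy()
    for var, b in coefs.items():
        if b != 0.0:
            eta += b * _zscore(df, var)
    return eta


def adherence_mean(params: ScmParams, df: pd.DataFrame) -> np.ndarray:
    """Conditional mean mu(W) of the scaled-Beta adherence model."""
    return _expit(_linear_predictor(df, params.adh_intercept, params.adh_coefs))


def outcome_probability(params: ScmParams, a, df: pd.DataFrame) -> np.ndarray:
    """Structural P(Y = 1 | A = a, W): the oracle outcome regression."""
    wave = df["wave"].to_numpy(dtype=int)
    intercepts = np.asarray(params.y_wave_intercepts)[wave - 1]
    eta = _linear_predictor(df, intercepts, params.y_coefs)
    return _expit(eta + params.y_coef_a * np.asarray(a, dtype=float))


def negative_control_probability(params: ScmParams, df: pd.DataFrame) -> np.ndarray:
    return _expit(_linear_predictor(df, params.nc_intercept, params.nc_coefs))


def _draw_covariates(params: ScmParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    wave = rng.choice([1, 2, 3], size=n, p=np.asarray(params.wave_weights))
    df = pd.DataFrame(
        {
            "age": np.clip(rng.normal(58, 12, n), 18, 95),
            "sex": rng.binomial(1, 0.48, n),
            "cond_hypertension": rng.binomial(1, 0.45, n),
            "cond_obesity": rng.binomial(1, 0.35, n),
            "cond_ckd": rng.binomial(1, 0.08, n),
            "cond_cardio": rng.binomial(1, 0.12, n),
            "metformin_months": np.clip(rng.lognormal(np.log(14.0), 0.55, n), 2, 48),
            "fac_population": np.exp(rng.normal(np.log(30000.0), 0.6, n)),
            "fac_imss_prop": rng.beta(8, 4, n),
            "fac_disabled_prop": rng.beta(2, 30, n),
            "fac_education": np.clip(rng.normal(9.5, 1.5, n), 3, 16),
            "fac_illiteracy": rng.beta(2, 25, n),
            "fac_occupants_per_room": np.clip(rng.normal(1.1, 0.3, n), 0.4, 2.5),
            "wave": wave,
        }
    )
    p_vacc = np.asarray(params.p_vacc_by_wave)[wave - 1]
    vaccinated = rng.binomial(1, p_vacc)
    df["vaccine_doses"] = vaccinated * (1 + rng.binomial(1, 0.5, n))
    df["vaccinated"] = (df["vaccine_doses"] >= 1).astype(int)
    return df


def _draw_adherence(params: ScmParams, df: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    mu = np.clip(adherence_mean(params, df), 1e-4, 1 - 1e-4)
    phi = params.adh_concentration
    return rng.beta(mu * phi, (1 - mu) * phi)


def _draw_test_dates(
    df: pd.DataFrame, rng: np.random.Generator
) -> pd.Series:
    # Tests span March 2020 – October 2021; waves cover the printed ranges.
    test_end_cap = _dt.date(2021, 10, 31)
    dates = np.empty(len(df), dtype=object)
    for wave, (lo, hi) in WAVE_BOUNDS.items():
        hi = min(hi, test_end_cap)
        mask = (df["wave"] == wave).to_numpy()
        span = (hi - lo).days + 1
        offs = rng.integers(0, span, size=int(mask.sum()))
        dates[mask] = [lo + _dt.timedelta(days=int(o)) for o in offs]
    return pd.Series(dates, index=df.index, name="test_date")


def generate_cohort(params: ScmParams) -> pd.DataFrame:
    """Draw a full synthetic cohort from the structural causal model.

    Returns an analysis-ready table: one row per patient with the 14
    confounders, wave indicator columns (``wave2``, ``wave3``), the test
    date, adherence ``A``, mortality ``Y``, the negative-control outcome
    ``neg_ctrl`` and the ``vaccinated`` subgroup indicator.  Reproducible:
    the same params (including seed) give byte-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    df = _draw_covariates(params, params.n, rng)
    df.insert(0, "patient_id", [f"P{i:07d}" for i in range(params.n)])
    df["test_date"] = _draw_test_dates(df, rng)
    df["A"] = _draw_adherence(params, df, rng)
    df["Y"] = rng.binomial(1, outcome_probability(params, df["A"].to_numpy(), df))
    df["neg_ctrl"] = rng.binomial(1, negative_control_probability(params, df))
    df["wave2"] = (df["wave"] == 2).astype(int)
    df["wave3"] = (df["wave"] == 3).astype(int)
    return df


# ---------------------------------------------------------------------------
# Raw-table synthesis (exercises the adherence and cohort modules)
# ---------------------------------------------------------------------------

TABLETS_PER_BOX = 30
TABLETS_PER_DAY = 2.0
DAYS_PER_BOX = int(TABLETS_PER_BOX / TABLETS_PER_DAY)  # 15 covered days per box


def _window_length(months: float) -> int:
    return int(np.clip(round(months * 30), 90, 600))


def generate_prescriptions(
    cohort: pd.DataFrame, params: ScmParams, on_unreachable: str = "error"
) -> pd.DataFrame:
    """Emit refill records whose PDC reproduces each patient's A (±0.01).

    The schedule is a monthly refill skeleton: two 30-tablet boxes per
    month (a full month's supply at two tablets/day) for as long as the
    bulk supply lasts, plus one trailing box timed so that exactly the
    remainder of the target covered days falls inside the window.  The
    observation window ends the day before the positive test and spans
    ~30 days per month on metformin (clipped to [90, 600] days).

    A target adherence below two boxes' coverage is structurally
    incompatible with the two-consecutive-month dispensing pattern.  With
    ``on_unreachable='error'`` (default) such patients raise a
    GenerationError listing them; with ``'floor'`` they are clamped to the
    minimum dispensable supply (two monthly boxes) with a logged warning.

    Raises
    ------
    GenerationError
        If a patient's target adherence is too low to be reachable with at
        least two consecutive months of dispensing (fewer than two boxes).
    """
    if on_unreachable not in ("error", "floor"):
        raise ValueError(f"on_unreachable must be 'error' or 'floor', got {on_unreachable!r}")
    rows = []
    failures = []
    floored = []
    for rec in cohort.itertuples():
        L = _window_length(rec.metformin_months)
        end = pd.Timestamp(rec.test_date) - pd.Timedelta(days=1)
        start = end - pd.Timedelta(days=L - 1)
        target_days = int(round(float(rec.A) * L))
        k, r = divmod(target_days, DAYS_PER_BOX)
        if k < 2:
            if on_unreachable == "error":
                failures.append(rec.patient_id)
                continue
            k, r = 2, 0  # minimum dispensable supply
            floored.append(rec.patient_id)
        # Bulk: two boxes per month keeps the stock exactly matched to
        # consumption; small supplies are spread over two months so every
        # patient satisfies the consecutive-month dispensing pattern.
        n_months = max(int(np.ceil(k / 2)), 2)
        boxes_left = k
        for j in range(n_months):
            b = min(2, boxes_left - (n_months - j - 1))
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "dispense_date": (start + pd.Timedelta(days=30 * j)).date(),
                    "boxes": b,
                    "tablets_per_box": TABLETS_PER_BOX,
                    "tablets_per_day": TABLETS_PER_DAY,
                }
            )
            boxes_left -= b
        if r > 0:
            # Trailing box truncated by the window end: covers exactly r days.
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "dispense_date": (start + pd.Timedelta(days=L - r)).date(),
                    "boxes": 1,
                    "tablets_per_box": TABLETS_PER_BOX,
                    "tablets_per_day": TABLETS_PER_DAY,
                }
            )
    if floored:
        import logging

        logging.getLogger(__name__).warning(
            "clamped %d patient(s) with unreachably low target adherence to "
            "the minimum two-box supply", len(floored)
        )
    if failures:
        raise GenerationError(
            "target adherence unreachable with the monthly box regimen for "
            f"patients {failures[:10]}{'...' if len(failures) > 10 else ''}"
        )
    return pd.DataFrame(rows)


def generate_tests(
    cohort: pd.DataFrame, params: ScmParams, p_prior_negative: float = 0.15
) -> pd.DataFrame:
    """Test records: each patient's positive test, plus occasional earlier
    negative tests (exercising most-recent-positive anchoring)."""
    rng = np.random.default_rng((params.seed + 1) % (2**31 - 1))
    rows = []
    for rec in cohort.itertuples():
        if rng.random() < p_prior_negative:
            back = int(rng.integers(30, 200))
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "test_date": (pd.Timestamp(rec.test_date) - pd.Timedelta(days=back)).date(),
                    "result": 0,
                }
            )
        rows.append(
            {
                "patient_id": rec.patient_id,
                "test_date": pd.Timestamp(rec.test_date).date(),
                "result": 1,
            }
        )
    return pd.DataFrame(rows)


def split_tables(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Covariate and death tables for the cohort-assembly round-trip."""
    cov_cols = ["patient_id"] + COVARIATES + ["vaccinated", "neg_ctrl", "wave2", "wave3"]
    covariates = cohort[cov_cols].copy()
    deaths = cohort[["patient_id", "Y"]].rename(columns={"Y": "deceased"})
    return covariates, deaths


def inject_missingness(cohort: pd.DataFrame, params: ScmParams) -> pd.DataFrame:
    """Blank facility-level entries at the configured per-variable rates.

    Individual-level variables are never touched.  A fresh copy is
    returned; the draw is reproducible from ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng((params.seed + 2) % (2**31 - 1))
    out = cohort.copy()
    for var, rate in params.miss_rates.items():
        if rate == 0.0 or var not in out.columns:
            continue
        mask = rng.random(len(out)) < rate
        out.loc[mask, var] = np.nan
    return out


# ---------------------------------------------------------------------------
# Counterfactual truth oracle
# ---------------------------------------------------------------------------


def true_shift_effect(
    params: ScmParams,
    delta: float,
    n_mc: int = 1_000_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """True shift effect psi(delta) = E[Y] - E[Y_d] by Monte-Carlo simulation.

    Draws (W, A) from the structural model, applies the shift rule
    d(a, w; delta) with the natural support bounds [0, 1], and evaluates
    the structural outcome probability at both the observed and the
    shifted adherence.  Returns the mean difference and its Monte-Carlo
    standard error.  psi(0) = 0 with SE 0, exactly.
    """
    if not 0.0 <= delta < 1.0:
        raise ConfigurationError(f"delta must lie in [0, 1), got {delta}")
    if n_mc < 1:
        raise ConfigurationError(f"n_mc must be >= 1, got {n_mc}")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    df = _draw_covariates(params, int(n_mc), rng)
    a = _draw_adherence(params, df, rng)
    a_shift = np.where(a <= 1.0 - delta, a + delta, a)
    diff = outcome_probability(params, a, df) - outcome_probability(params, a_shift, df)
    psi = float(np.mean(diff))
    se = float(np.std(diff, ddof=1) / np.sqrt(n_mc)) if n_mc > 1 else 0.0
    return psi, se
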