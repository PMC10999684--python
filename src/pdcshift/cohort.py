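"""Cohort construction: inclusion rules, epidemic-wave labels, imputation.

The analysis unit is one patient with a positive SARS-CoV-2 test and a
chronic metformin prescription history.  Inclusion requires at least one
positive PCR/rapid test and dispensings in at least two consecutive
calendar months before the (most recent) positive test; patients with a
single prescription are excluded.  Facility-level covariates may carry
missing values, which are median-imputed with per-variable missingness
indicator columns appended.
"""

from __future__ import annotations

import datetime as _dt
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WAVE_BOUNDS",
    "apply_inclusion",
    "assign_wave",
    "impute_and_flag",
    "build_analysis_dataset",
]

#: Inclusive date ranges of the three epidemic waves.
WAVE_BOUNDS: dict[int, tuple[_dt.date, _dt.date]] = {
    1: (_dt.date(2020, 3, 29), _dt.date(2020, 10, 3)),
    2: (_dt.date(2020, 10, 4), _dt.date(2021, 5, 29)),
    3: (_dt.date(2021, 5, 30), _dt.date(2021, 12, 18)),
}

#: Tests from early March 2020 predate the first wave's formal start; by
#: default they are folded into wave 1 so the wave partition is exhaustive.
EARLY_GRACE_START = _dt.date(2020, 3, 1)


class WaveAssignmentError(ValueError):
    """Raised when a test date falls outside every wave window."""


def assign_wave(test_date, *, early_to_wave1: bool = True) -> int:
    """Map a positive-test date to an epidemic wave label in {1, 2, 3}.

    Dates in [2020-03-01, 2020-03-28] precede the printed wave-1 start;
    with ``early_to_wave1`` (default) they are assigned to wave 1 with a
    logged notice, otherwise they raise.
    """
    d = pd.Timestamp(test_date).date()
    for wave, (lo, hi) in WAVE_BOUNDS.items():
        if lo <= d <= hi:
            return wave
    if early_to_wave1 and EARLY_GRACE_START <= d < WAVE_BOUNDS[1][0]:
        logger.info("test date %s precedes wave 1 start; assigned to wave 1", d)
        return 1
    raise WaveAssignmentError(f"test date {d} falls outside all wave windows")


def _month_index(dates: pd.Series) -> pd.Series:
    ts = pd.to_datetime(dates)
    return ts.dt.year * 12 + ts.dt.month


def apply_inclusion(
    tests: pd.DataFrame,
    prescriptions: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Select eligible patients and record attrition at each step.

    Parameters
    ----------
    tests
        Columns ``patient_id``, ``test_date``, ``result`` (1 = positive).
    prescriptions
        Columns ``patient_id``, ``dispense_date`` (other columns ignored).

    Returns
    -------
    (eligible, attrition)
        ``eligible``: one row per eligible patient with columns
        ``patient_id`` and ``anchor_test_date`` (the most recent positive
        test, which anchors the adherence window and the wave label).
        ``attrition``: ordered step -> patient-count mapping.
    """
    tests = tests.copy()
    tests["test_date"] = pd.to_datetime(tests["test_date"])
    rx = prescriptions.copy()
    rx["dispense_date"] = pd.to_datetime(rx["dispense_date"])

    attrition: dict[str, int] = {}
    attrition["tested"] = int(tests["patient_id"].nunique())

    pos = tests[tests["result"].astype(int) == 1]
    anchor = pos.groupby("patient_id")["test_date"].max().rename("anchor_test_date")
    attrition["positive_test"] = int(anchor.size)

    rx = rx[rx["patient_id"].isin(anchor.index)]
    n_rx = rx.groupby("patient_id").size()
    multi = n_rx[n_rx >= 2].index
    attrition["ge2_prescriptions"] = int(len(multi))

    # Consecutive calendar months of dispensing strictly before the anchor test.
    eligible_ids = []
    anchor_multi = anchor.loc[anchor.index.isin(multi)]
    rx_multi = rx[rx["patient_id"].isin(multi)].merge(
        anchor_multi.reset_index(), on="patient_id"
    )
    rx_before = rx_multi[rx_multi["dispense_date"] < rx_multi["anchor_test_date"]]
    months = rx_before.assign(month=_month_index(rx_before["dispense_date"]))
    for pid, grp in months.groupby("patient_id", sort=True):
        m = np.sort(grp["month"].unique())
        if len(m) >= 2 and np.any(np.diff(m) == 1):
            eligible_ids.append(pid)
    attrition["consecutive_months_before_test"] = len(eligible_ids)

    if not eligible_ids:
        logger.warning("inclusion rules produced an empty cohort")
    eligible = pd.DataFrame(
        {
            "patient_id": eligible_ids,
            "anchor_test_date": anchor.loc[eligible_ids].to_numpy(),
        }
    )
    eligible = eligible.sort_values("patient_id", ignore_index=True)
    return eligible, attrition


def impute_and_flag(covariates: pd.DataFrame) -> pd.DataFrame:
    """Median-impute missing numeric entries, flagging each imputed variable.

    Every numeric column with at least one missing value gets its missing
    entries replaced by the column's observed median and a companion binary
    indicator column ``<name>_missing`` appended; fully observed columns are
    left untouched.  The operation is idempotent.
    """
    out = covariates.copy()
    num_cols = [
        c
        for c in out.columns
        if pd.api.types.is_numeric_dtype(out[c]) and not c.endswith("_missing")
    ]
    for c in num_cols:
        mask = out[c].isna()
        if not mask.any():
            continue
        if mask.all():
            raise ValueError(f"covariate {c!r} is entirely missing; median undefined")
        med = out.loc[~mask, c].median()
        out[c] = out[c].fillna(med)
        flag = f"{c}_missing"
        if flag not in out.columns:
            out[flag] = mask.astype(int)
    return out


def build_analysis_dataset(
    eligible: pd.DataFrame,
    pdc: pd.DataFrame,
    covariates: pd.DataFrame,
    tests: pd.DataFrame,
    deaths: pd.DataFrame | Mapping,
    *,
    preexisting_cols: Iterable[str] | None = None,
    attrition: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Assemble the analysis table: one row per patient, (W, A, Y, wave, ...).

    Parameters
    ----------
    eligible
        Output of :func:`apply_inclusion`.
    pdc
        Output of :func:`pdcshift.adherence.pdc_table` (column ``pdc``).
    covariates
        One row per patient: confounders W plus a ``vaccinated`` indicator;
        may contain missing facility-level values (imputed here) and, for
        synthetic cohorts, a ``neg_ctrl`` column.
    tests
        Test records; used for the negative-control outcome when
        ``covariates`` has no ``neg_ctrl`` column (most recent result).
    deaths
        DataFrame with ``patient_id``/``deceased`` or a mapping id -> 0/1.
    preexisting_cols
        Individual-level pre-existing-condition columns; patients with a
        missing value in any of them are dropped (not imputed).  Defaults
        to every column whose name starts with ``cond_``.

    Returns
    -------
    DataFrame ordered by patient_id with columns: patient_id, the covariate
    columns (imputed, with missingness flags), A, Y, wave, neg_ctrl,
    vaccinated.
    """
    if eligible["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in eligible set")
    if covariates["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in covariates")

    df = eligible.merge(pdc[["patient_id", "pdc"]], on="patient_id", how="inner")
    df = df.merge(covariates, on="patient_id", how="inner")

    if preexisting_cols is None:
        preexisting_cols = [c for c in df.columns if c.startswith("cond_")]
    pre_cols = [c for c in preexisting_cols if c in df.columns]
    if pre_cols:
        bad = df[pre_cols].isna().any(axis=1)
        if bad.any():
            logger.info(
                "dropping %d patient(s) with missing pre-existing-condition data",
                int(bad.sum()),
            )
        df = df[~bad]
    if attrition is not None:
        attrition["complete_preexisting"] = int(len(df))

    if isinstance(deaths, pd.DataFrame):
        death_map = deaths.set_index("patient_id")["deceased"]
    else:
        death_map = pd.Series(dict(deaths))
    df["Y"] = df["patient_id"].map(death_map).fillna(0).astype(int)

    df["wave"] = df["anchor_test_date"].map(assign_wave)

    if "neg_ctrl" not in df.columns:
        t = tests.copy()
        t["test_date"] = pd.to_datetime(t["test_date"])
        last = t.sort_values("test_date").groupby("patient_id")["result"].last()
        df["neg_ctrl"] = df["patient_id"].map(last).fillna(0).astype(int)

    if "vaccinated" not in df.columns:
        df["vaccinated"] = 0

    df = df.rename(columns={"pdc": "A"})
    if not df["A"].between(0, 1).all():
        raise ValueError("adherence A outside [0, 1] in analysis dataset")

    w_cols = [
        c
        for c in df.columns
        if c
        not in {"patient_id", "anchor_test_date", "A", "Y", "wave", "neg_ctrl", "vaccinated"}
    ]
    df = impute_and_flag(df)
    flag_cols = [c for c in df.columns if c.endswith("_missing")]
    ordered = (
        ["patient_id", "anchor_test_date"]
        + [c for c in w_cols if not c.endswith("_missing")]
        + flag_cols
        + ["A", "Y", "wave", "neg_ctrl", "vaccinated"]
    )
    df = df[ordered].sort_values("patient_id").reset_index(drop=True)
    return df


def covariate_columns(data: pd.DataFrame) -> list[str]:
    """Names of the confounder columns W in an analysis table."""
    skip = {
        "patient_id",
        "anchor_test_date",
        "test_date",
        "A",
        "Y",
        "wave",
        "neg_ctrl",
        "vaccinated",
    }
    return [c for c in data.columns if c not in skip]
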