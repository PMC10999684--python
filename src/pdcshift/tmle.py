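"""Targeted minimum loss-based estimation of the shift effect.

The estimand is psi = E[Y] - E[Y_d]: the reduction in mortality risk under
a delta-shift of adherence.  Estimation proceeds in two steps:

1. an initial substitution estimator plugs the fitted outcome regression
   Qbar_n, evaluated at shifted exposures, into the empirical distribution
   of W;
2. Qbar_n is fluctuated along a weighted intercept-only logistic submodel
   logit Qbar_eps = logit Qbar_n + eps, with the density ratio
   r(a, w) = g_d(a | w) / g(a | w) as weights, so the updated Qbar_n*
   solves the efficient-influence-function (EIF) score equation.

The estimator is asymptotically linear with influence function

    D_i = (y_i - ybar) - [ r(a_i, w_i) (y_i - Qbar*(a_i, w_i))
                           + Qbar*(d(a_i, w_i), w_i) - theta* ],

whose sample variance yields the Wald 95% confidence interval.  Being a
substitution estimator, theta* = mean of Qbar*(d(a_i, w_i), w_i) always
stays in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import nuisance as _nuis
from .cohort import covariate_columns
from .policy import (
    FeasibilityReport,
    ShiftPolicy,
    density_ratio,
    ratio_diagnostic,
    shift_rule,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ShiftEstimate",
    "initial_estimate",
    "fluctuate",
    "estimate_shift_effect",
    "run_analysis",
    "substitution_curve",
    "render_report",
]

MAX_TARGETING_ITER = 10


@dataclass
class ShiftEstimate:
    """Point estimate, targeting diagnostics, and Wald inference."""

    delta: float
    psi: float
    theta_star: float
    y_bar: float
    epsilon: float
    se: float
    ci_low: float
    ci_high: float
    mean_eif: float
    n: int
    stratum: str = "overall"
    outcome: str = "Y"
    feasibility: FeasibilityReport | None = None
    n_iter: int = 1
    converged: bool = True
    score_residual: float = 0.0
    eif: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "stratum",
                "outcome",
                "delta",
                "n",
                "psi",
                "se",
                "ci_low",
                "ci_high",
                "theta_star",
                "y_bar",
                "epsilon",
                "mean_eif",
                "n_iter",
                "converged",
            )
        }
        if self.feasibility is not None:
            d["max_ratio"] = self.feasibility.max_ratio
            d["feasible"] = self.feasibility.feasible
        return d


def initial_estimate(
    data: pd.DataFrame,
    qbar,
    policy: ShiftPolicy,
    outcome_col: str = "Y",
    w_cols: list[str] | None = None,
) -> float:
    """Plug-in value of E[Y] - E[Qbar_n(d(A, W), W)] before targeting."""
    if w_cols is None:
        w_cols = covariate_columns(data)
    w = data[w_cols]
    a_shift = shift_rule(data["A"].to_numpy(), w, policy)
    y_bar = float(data[outcome_col].mean())
    return y_bar - float(np.mean(qbar(a_shift, w)))


def _solve_epsilon(y: np.ndarray, offset: np.ndarray, weights: np.ndarray) -> float:
    """MLE of the intercept fluctuation: solves sum w (y - expit(off + eps)) = 0."""
    if np.all(weights == 0):
        raise ValueError("all clever-covariate weights are zero")

    def score(eps: float) -> float:
        return float(np.sum(weights * (y - expit(offset + eps))))

    lo, hi = -20.0, 20.0
    s_lo, s_hi = score(lo), score(hi)
    # score is decreasing in eps; degenerate one-sided cases pin the boundary
    if s_lo <= 0:
        return lo if s_lo < 0 else 0.0 if score(0.0) == 0 else lo
    if s_hi >= 0:
        return hi
    return float(brentq(score, lo, hi, xtol=1e-14))


class _FluctuatedQ:
    """Qbar_n* = expit(logit Qbar_n + eps); evaluable at any (a, w)."""

    def __init__(self, qbar, eps: float):
        self.qbar = qbar
        self.eps = float(eps)

    def __call__(self, a, w) -> np.ndarray:
        p = np.clip(self.qbar(a, w), _nuis.PRED_CLIP, 1 - _nuis.PRED_CLIP)
        return expit(logit(p) + self.eps)


def fluctuate(
    data: pd.DataFrame,
    qbar,
    g,
    policy: ShiftPolicy,
    outcome_col: str = "Y",
    w_cols: list[str] | None = None,
) -> tuple[float, "_FluctuatedQ"]:
    """Fit the weighted intercept submodel; return (epsilon, Qbar_n*)."""
    if w_cols is None:
        w_cols = covariate_columns(data)
    w = data[w_cols]
    a = data["A"].to_numpy(dtype=float)
    y = data[outcome_col].to_numpy(dtype=float)
    r = density_ratio(g, a, w, policy)
    off = logit(np.clip(qbar(a, w), _nuis.PRED_CLIP, 1 - _nuis.PRED_CLIP))
    eps = _solve_epsilon(y, off, r)
    return eps, _FluctuatedQ(qbar, eps)


def estimate_shift_effect(
    data: pd.DataFrame,
    qbar,
    g,
    policy: ShiftPolicy,
    outcome_col: str = "Y",
    w_cols: list[str] | None = None,
    stratum: str = "overall",
    precomputed: dict | None = None,
) -> ShiftEstimate:
    """Full TMLE of psi = E[Y] - E[Y_d] with EIF-based Wald inference.

    ``precomputed`` may carry row-level nuisance evaluations
    (``q_obs``, ``q_shift`` on the logit scale and ``ratio``), as produced
    by cross-fitting; otherwise they are computed from ``qbar``/``g``.
    """
    if w_cols is None:
        w_cols = covariate_columns(data)
    w = data[w_cols]
    a = data["A"].to_numpy(dtype=float)
    y = data[outcome_col].to_numpy(dtype=float)
    n = len(y)
    y_bar = float(np.mean(y))

    a_shift = shift_rule(a, w, policy)
    if precomputed is not None:
        r = np.asarray(precomputed["ratio"], dtype=float)
        logit_q_obs = np.asarray(precomputed["logit_q_obs"], dtype=float)
        logit_q_shift = np.asarray(precomputed["logit_q_shift"], dtype=float)
        feas = precomputed.get("feasibility")
    else:
        r = density_ratio(g, a, w, policy)
        logit_q_obs = logit(np.clip(qbar(a, w), _nuis.PRED_CLIP, 1 - _nuis.PRED_CLIP))
        logit_q_shift = logit(np.clip(qbar(a_shift, w), _nuis.PRED_CLIP, 1 - _nuis.PRED_CLIP))
        feas = ratio_diagnostic(g, data.assign(A=a), policy, w_cols=w_cols)
    if feas is not None and not feas.feasible:
        logger.warning(
            "shift delta=%.3g flagged infeasible (max ratio %.2f >= bound %.2f); "
            "estimate returned with warning",
            policy.delta,
            feas.max_ratio,
            feas.ratio_bound,
        )

    eps_total = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, MAX_TARGETING_ITER + 1):
        eps = _solve_epsilon(y, logit_q_obs, r)
        eps_total += eps
        logit_q_obs = logit_q_obs + eps
        logit_q_shift = logit_q_shift + eps

        q_star_obs = expit(logit_q_obs)
        q_star_shift = expit(logit_q_shift)
        theta_star = float(np.mean(q_star_shift))
        eif = (y - y_bar) - (r * (y - q_star_obs) + q_star_shift - theta_star)
        se = float(np.std(eif, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        resid = float(np.mean(r * (y - q_star_obs)))
        tol = max(se / (np.sqrt(n) * np.log(max(n, 3))), 1e-12)
        if abs(resid) < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "targeting did not converge after %d iterations (residual %.3g)",
            MAX_TARGETING_ITER,
            resid,
        )

    psi = y_bar - theta_star
    half = 1.959963984540054 * se
    return ShiftEstimate(
        delta=policy.delta,
        psi=psi,
        theta_star=theta_star,
        y_bar=y_bar,
        epsilon=eps_total,
        se=se,
        ci_low=psi - half,
        ci_high=psi + half,
        mean_eif=float(np.mean(eif)),
        n=n,
        stratum=stratum,
        outcome=outcome_col,
        feasibility=feas,
        n_iter=n_iter,
        converged=converged,
        score_residual=resid,
        eif=eif,
    )


# ---------------------------------------------------------------------------
# Nuisance fitting + estimation wrappers
# ---------------------------------------------------------------------------


def fit_and_estimate(
    data: pd.DataFrame,
    policy: ShiftPolicy,
    q_library: Sequence = _nuis.DEFAULT_Q_LIBRARY,
    g_library: Sequence = _nuis.DEFAULT_G_LIBRARY,
    folds: int = 10,
    bins: int = 20,
    seed: int = 0,
    outcome_col: str = "Y",
    w_cols: list[str] | None = None,
    g_method: str = "hazard",
    cross_fit: int = 0,
    stratum: str = "overall",
) -> ShiftEstimate:
    """Fit nuisances on ``data`` and run the TMLE in one call.

    With ``cross_fit`` = K > 1, nuisances are fit K times on fold
    complements and evaluated out-of-fold before a single global
    fluctuation (cross-fitted TMLE).
    """
    if w_cols is None:
        w_cols = covariate_columns(data)
    w_cols = [c for c in w_cols if data[c].nunique() > 1]  # drop constants in strata

    if cross_fit and cross_fit > 1:
        pre = _cross_fit_nuisances(
            data, policy, q_library, g_library, folds, bins, seed,
            outcome_col, w_cols, g_method, cross_fit,
        )
        return estimate_shift_effect(
            data, None, None, policy, outcome_col, w_cols,
            stratum=stratum, precomputed=pre,
        )

    qbar = _nuis.fit_outcome_regression(
        data, q_library, V=folds, seed=seed, outcome_col=outcome_col, w_cols=w_cols
    )
    g = _nuis.fit_conditional_density(
        data, bins=bins, library=g_library, V=folds, seed=seed,
        w_cols=w_cols, method=g_method,
    )
    return estimate_shift_effect(
        data, qbar, g, policy, outcome_col, w_cols, stratum=stratum
    )


def _cross_fit_nuisances(
    data, policy, q_library, g_library, folds, bins, seed,
    outcome_col, w_cols, g_method, K,
) -> dict:
    from sklearn.model_selection import KFold

    n = len(data)
    kf = KFold(n_splits=K, shuffle=True, random_state=_nuis.derive_seed(seed, "crossfit"))
    logit_q_obs = np.empty(n)
    logit_q_shift = np.empty(n)
    ratio = np.empty(n)
    a_all = data["A"].to_numpy(dtype=float)
    for k, (tr, te) in enumerate(kf.split(data)):
        d_tr = data.iloc[tr]
        d_te = data.iloc[te]
        qbar = _nuis.fit_outcome_regression(
            d_tr, q_library, V=folds, seed=_nuis.derive_seed(seed, f"cf{k}"),
            outcome_col=outcome_col, w_cols=w_cols,
        )
        g = _nuis.fit_conditional_density(
            d_tr, bins=bins, library=g_library, V=folds,
            seed=_nuis.derive_seed(seed, f"cf{k}"), w_cols=w_cols, method=g_method,
        )
        w_te = d_te[w_cols]
        a_te = a_all[te]
        a_sh = shift_rule(a_te, w_te, policy)
        logit_q_obs[te] = logit(np.clip(qbar(a_te, w_te), _nuis.PRED_CLIP, 1 - _nuis.PRED_CLIP))
        logit_q_shift[te] = logit(np.clip(qbar(a_sh, w_te), _nuis.PRED_CLIP, 1 - _nuis.PRED_CLIP))
        ratio[te] = density_ratio(g, a_te, w_te, policy)
    max_r = float(np.max(ratio))
    feas = FeasibilityReport(
        delta=policy.delta,
        ratio_bound=policy.ratio_bound,
        max_ratio=max_r,
        q99_ratio=float(np.quantile(ratio, 0.99)),
        frac_exceeding=float(np.mean(ratio >= policy.ratio_bound)),
        feasible=bool(max_r < policy.ratio_bound),
        n=n,
    )
    return {
        "logit_q_obs": logit_q_obs,
        "logit_q_shift": logit_q_shift,
        "ratio": ratio,
        "feasibility": feas,
    }


def run_analysis(
    data: pd.DataFrame,
    deltas: Sequence[float] = (0.05, 0.10),
    q_library: Sequence = _nuis.DEFAULT_Q_LIBRARY,
    g_library: Sequence = _nuis.DEFAULT_G_LIBRARY,
    folds: int = 10,
    bins: int = 20,
    seed: int = 0,
    g_method: str = "hazard",
    cross_fit: int = 0,
    ratio_bound: float = 10.0,
    stratify_wave: bool = True,
    subgroup_vaccinated: bool = True,
    negative_control: str | None = "neg_ctrl",
    min_stratum_n: int = 200,
) -> tuple[pd.DataFrame, dict]:
    """Overall, per-wave, vaccination-subgroup and negative-control TMLEs.

    Nuisances are refit within each stratum.  Returns a tidy results table
    (one row per delta x stratum x outcome with psi, SE, 95% CI and
    feasibility) and a diagnostics dict keyed by the same labels.
    """
    strata: list[tuple[str, pd.DataFrame, str]] = [("overall", data, "Y")]
    if stratify_wave and "wave" in data.columns:
        for wv in sorted(data["wave"].unique()):
            strata.append((f"wave{wv}", data[data["wave"] == wv], "Y"))
    if subgroup_vaccinated and "vaccinated" in data.columns:
        strata.append(("unvaccinated", data[data["vaccinated"] == 0], "Y"))
        strata.append(("vaccinated", data[data["vaccinated"] == 1], "Y"))
    if negative_control is not None and negative_control in data.columns:
        strata.append(("negative_control", data, negative_control))

    rows = []
    diagnostics: dict[str, dict] = {}
    for delta in deltas:
        policy = ShiftPolicy(delta=delta, ratio_bound=ratio_bound)
        for label, sub, outcome in strata:
            if len(sub) < min_stratum_n:
                logger.warning(
                    "stratum %s skipped: n=%d below floor %d", label, len(sub), min_stratum_n
                )
                continue
            est = fit_and_estimate(
                sub.reset_index(drop=True),
                policy,
                q_library=q_library,
                g_library=g_library,
                folds=folds,
                bins=bins,
                seed=_nuis.derive_seed(seed, f"{label}:{outcome}:{delta}"),
                outcome_col=outcome,
                g_method=g_method,
                cross_fit=cross_fit,
                stratum=label,
            )
            rows.append(est.to_dict())
            diagnostics[f"{label}:{outcome}:delta={delta}"] = {
                "epsilon": est.epsilon,
                "mean_eif": est.mean_eif,
                "n_iter": est.n_iter,
                "converged": est.converged,
                "feasibility": est.feasibility.to_dict() if est.feasibility else None,
            }
    return pd.DataFrame(rows), diagnostics


# ---------------------------------------------------------------------------
# Substitution-estimate curves and adherence histograms
# ---------------------------------------------------------------------------


def substitution_curve(
    data: pd.DataFrame,
    qbar,
    policy: ShiftPolicy,
    w_cols: list[str] | None = None,
    stratum_col: str = "wave",
    spline_df: int = 8,
    hist_bins: int = 25,
) -> dict:
    """Per-subject predicted risk change under the shift, with smooth curves.

    For every subject, Delta_i = Qbar(d(a_i, w_i), w_i) - Qbar(a_i, w_i);
    subjects whose adherence is not shifted have Delta_i = 0 exactly.  Per
    stratum, a penalized B-spline smooth of Delta_i against baseline a_i is
    returned, plus before/after adherence histograms.
    """
    if w_cols is None:
        w_cols = covariate_columns(data)
    w = data[w_cols]
    a = data["A"].to_numpy(dtype=float)
    a_shift = shift_rule(a, w, policy)
    q_obs = np.asarray(qbar(a, w), dtype=float)
    q_shift = np.asarray(qbar(a_shift, w), dtype=float)
    delta_i = np.where(a_shift == a, 0.0, q_shift - q_obs)

    points = pd.DataFrame(
        {
            "patient_id": data.get("patient_id", pd.RangeIndex(len(data))),
            "stratum": data[stratum_col] if stratum_col in data.columns else "all",
            "A": a,
            "A_shifted": a_shift,
            "risk_change": delta_i,
        }
    )

    curves = []
    histograms = []
    edges = np.linspace(0.0, 1.0, hist_bins + 1)
    for label, grp in points.groupby("stratum"):
        grid = np.linspace(grp["A"].min(), grp["A"].max(), 101)
        curves.append(
            pd.DataFrame(
                {
                    "stratum": label,
                    "A": grid,
                    "smoothed_risk_change": _pspline_smooth(
                        grp["A"].to_numpy(), grp["risk_change"].to_numpy(), grid, spline_df
                    ),
                }
            )
        )
        before, _ = np.histogram(grp["A"], bins=edges)
        after, _ = np.histogram(grp["A_shifted"], bins=edges)
        histograms.append(
            pd.DataFrame(
                {
                    "stratum": label,
                    "bin_left": edges[:-1],
                    "bin_right": edges[1:],
                    "count_before": before,
                    "count_after": after,
                }
            )
        )
    return {
        "points": points,
        "curves": pd.concat(curves, ignore_index=True),
        "histograms": pd.concat(histograms, ignore_index=True),
    }


def _pspline_smooth(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, df: int, lam: float = 1.0
) -> np.ndarray:
    """Penalized B-spline (P-spline) smooth with a second-difference penalty."""
    from scipy.interpolate import BSpline

    n_basis = max(df, 4)
    degree = 3
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-12:
        return np.full(len(grid), float(np.mean(y)))
    inner = np.linspace(lo, hi, n_basis - degree + 1)
    knots = np.concatenate([[lo] * degree, inner, [hi] * degree])
    xc = np.clip(x, lo, hi)
    B = BSpline.design_matrix(xc, knots, degree).toarray()
    D = np.diff(np.eye(B.shape[1]), n=2, axis=0)
    coef = np.linalg.solve(B.T @ B + lam * (D.T @ D), B.T @ y)
    Bg = BSpline.design_matrix(np.clip(grid, lo, hi), knots, degree).toarray()
    return Bg @ coef


def render_report(results: pd.DataFrame) -> str:
    """Plain-text forest-style summary of a results table."""
    lines = ["shift-intervention TMLE estimates (psi = reduction in outcome risk)", ""]
    header = f"{'stratum':<18}{'outcome':<10}{'delta':>6}{'n':>8}{'psi %':>9}{'95% CI %':>20}{'feasible':>10}"
    lines.append(header)
    lines.append("-" * len(header))
    for r in results.itertuples():
        ci = f"[{100 * r.ci_low:+.2f}, {100 * r.ci_high:+.2f}]"
        feas = getattr(r, "feasible", True)
        lines.append(
            f"{r.stratum:<18}{r.outcome:<10}{r.delta:>6.2f}{r.n:>8d}"
            f"{100 * r.psi:>+9.2f}{ci:>20}{str(bool(feas)):>10}"
        )
    return "\n".join(lines)
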