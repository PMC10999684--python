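"""Shift-intervention policy: d(a, w; delta), its pushforward density, and
the positivity diagnostic.

The intervention adds ``delta`` to each subject's observed adherence unless
the shifted value would leave the conditional support [l(w), u(w)]:

    d(a, w; delta) = a + delta   if a <= u(w) - delta
                     a           otherwise.

Under this rule the post-intervention conditional density of the exposure is

    g_d(a | w) = g(a - delta | w) * 1{l(w) + delta <= a <= u(w)}
               + g(a | w)         * 1{a > u(w) - delta},

and the density ratio r(a, w) = g_d(a | w) / g(a | w) is both the TMLE's
clever covariate and the positivity diagnostic: the shift is considered
feasible only while r stays below a configured bound (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "ShiftPolicy",
    "FeasibilityReport",
    "shift_rule",
    "shifted_density",
    "density_ratio",
    "ratio_diagnostic",
    "check_normalization",
]

BoundFn = Callable[[pd.DataFrame], np.ndarray]


def _const_bound(value: float) -> BoundFn:
    def fn(w: pd.DataFrame) -> np.ndarray:
        return np.full(len(w), value, dtype=float)

    fn.__name__ = f"const_{value}"
    return fn


@dataclass
class ShiftPolicy:
    """Additive shift intervention with conditional support bounds.

    Parameters
    ----------
    delta
        Shift magnitude on the adherence scale, in [0, 1).
    lower_bound, upper_bound
        Functions of the covariate table returning per-row support
        endpoints; defaults are the natural PDC bounds l(w) = 0, u(w) = 1.
    ratio_bound
        Positivity threshold for the density ratio (default 10).
    """

    delta: float
    lower_bound: BoundFn = field(default_factory=lambda: _const_bound(0.0))
    upper_bound: BoundFn = field(default_factory=lambda: _const_bound(1.0))
    ratio_bound: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta < 1.0:
            raise ValueError(f"delta must lie in [0, 1), got {self.delta}")
        if not self.ratio_bound > 0:
            raise ValueError(f"ratio_bound must be positive, got {self.ratio_bound}")

    def bounds(self, w: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.lower_bound(w), dtype=float)
        hi = np.asarray(self.upper_bound(w), dtype=float)
        if np.any(lo < 0) or np.any(hi > 1) or np.any(lo >= hi):
            raise ValueError("support bounds must satisfy 0 <= l(w) < u(w) <= 1")
        if np.any(self.delta >= hi - lo):
            raise ValueError("delta must be smaller than u(w) - l(w) for every row")
        return lo, hi


def shift_rule(a, w: pd.DataFrame, policy: ShiftPolicy) -> np.ndarray:
    """Apply d(a, w; delta) row-wise: shift unless it would exceed u(w)."""
    a = np.asarray(a, dtype=float)
    lo, hi = policy.bounds(w)
    bad = (a < lo - 1e-12) | (a > hi + 1e-12)
    if np.any(bad):
        idx = np.flatnonzero(bad)[:5]
        raise ValueError(
            f"exposure outside support [l(w), u(w)] at rows {idx.tolist()}"
        )
    shifted = np.where(a <= hi - policy.delta, a + policy.delta, a)
    return np.clip(shifted, lo, hi)


def shifted_density(g, a, w: pd.DataFrame, policy: ShiftPolicy) -> np.ndarray:
    """Post-intervention density g_d(a | w) of the shifted exposure.

    ``g`` is a conditional density evaluator: ``g(a_values, w_table)``
    returning per-row densities (rows of ``a`` and ``w`` aligned).
    """
    a = np.asarray(a, dtype=float)
    lo, hi = policy.bounds(w)
    d = policy.delta
    pulled = np.clip(a - d, 0.0, 1.0)
    g_pulled = np.asarray(g(pulled, w), dtype=float)
    g_same = np.asarray(g(a, w), dtype=float)
    term1 = np.where((a >= lo + d) & (a <= hi), g_pulled, 0.0)
    term2 = np.where(a > hi - d, g_same, 0.0)
    return term1 + term2


def density_ratio(g, a, w: pd.DataFrame, policy: ShiftPolicy) -> np.ndarray:
    """Clever covariate r(a, w) = g_d(a | w) / g(a | w)."""
    a = np.asarray(a, dtype=float)
    g_obs = np.asarray(g(a, w), dtype=float)
    if np.any(g_obs <= 0):
        idx = np.flatnonzero(g_obs <= 0)[:5]
        raise ValueError(
            f"observed-exposure density is zero at rows {idx.tolist()}; "
            "positivity violated"
        )
    return shifted_density(g, a, w, policy) / g_obs


def check_normalization(
    g, w: pd.DataFrame, n_grid: int = 2001, tol: float = 1e-3
) -> np.ndarray:
    """Quadrature check that g(. | w) integrates to 1 on [0, 1] per row."""
    grid = np.linspace(0.0, 1.0, n_grid)
    masses = np.empty(len(w))
    for i in range(len(w)):
        # repeat the single covariate row across the grid
        wi = pd.DataFrame(
            np.repeat(w.iloc[[i]].to_numpy(), n_grid, axis=0), columns=w.columns
        )
        masses[i] = np.trapezoid(np.asarray(g(grid, wi), dtype=float), grid)
    if np.any(np.abs(masses - 1.0) > tol):
        raise ValueError(
            f"conditional density not normalized: masses {masses[np.abs(masses-1)>tol][:5]}"
        )
    return masses


@dataclass
class FeasibilityReport:
    """Summary of the density-ratio positivity diagnostic over a cohort."""

    delta: float
    ratio_bound: float
    max_ratio: float
    q99_ratio: float
    frac_exceeding: float
    feasible: bool
    n: int

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "ratio_bound": self.ratio_bound,
            "max_ratio": self.max_ratio,
            "q99_ratio": self.q99_ratio,
            "frac_exceeding": self.frac_exceeding,
            "feasible": self.feasible,
            "n": self.n,
        }


def ratio_diagnostic(
    g, data: pd.DataFrame, policy: ShiftPolicy, w_cols: list[str] | None = None
) -> FeasibilityReport:
    """Evaluate r(a_i, w_i) over a cohort and judge feasibility of the shift.

    Feasibility is flagged on the maximum ratio (conservative); the 0.99
    quantile and the fraction of rows at or above the bound are reported
    alongside.
    """
    if w_cols is None:
        from .cohort import covariate_columns

        w_cols = covariate_columns(data)
    w = data[w_cols]
    r = density_ratio(g, data["A"].to_numpy(), w, policy)
    max_r = float(np.max(r))
    return FeasibilityReport(
        delta=policy.delta,
        ratio_bound=policy.ratio_bound,
        max_ratio=max_r,
        q99_ratio=float(np.quantile(r, 0.99)),
        frac_exceeding=float(np.mean(r >= policy.ratio_bound)),
        feasible=bool(max_r < policy.ratio_bound),
        n=int(len(r)),
    )
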