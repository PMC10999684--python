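"""Nuisance estimation: outcome regression and conditional exposure density.

Two nuisance functions drive the shift-intervention TMLE:

* the outcome regression ``Qbar(a, w) = E[Y | A = a, W = w]``, fitted by a
  cross-validated convex ensemble (super learner) of binary-outcome
  learners; and
* the conditional density ``g(a | w)`` of the exposure given confounders,
  fitted either by a binned pooled-hazard classifier (the default,
  nonparametric) or by parametric beta regression.

All stochastic learners receive seeds derived deterministically from a
top-level seed plus a stage name, so repeated fits are bit-reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, digamma, expit, logit
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "LearnerSpec",
    "SuperLearner",
    "OutcomeRegression",
    "HazardConditionalDensity",
    "BetaConditionalDensity",
    "NuisanceFit",
    "fit_outcome_regression",
    "fit_conditional_density",
    "predict_Q",
    "derive_seed",
]

PRED_CLIP = 1e-6

DEFAULT_Q_LIBRARY = ("mean", "logistic", "gbt", "rf")
DEFAULT_G_LIBRARY = ("logistic", "gbt")


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class LearnerSpec:
    """A named candidate learner for a super-learner library."""

    name: str
    family: str = "binary-outcome"  # or "bin-hazard"
    params: tuple = ()

    def make(self, seed: int):
        params = dict(self.params)
        if self.name == "mean":
            return _MeanLearner()
        if self.name == "logistic":
            # effectively unpenalized MLE; standardization only aids lbfgs
            defaults = dict(C=1e8, solver="lbfgs", max_iter=5000)
            defaults.update(params)
            return Pipeline(
                [("scale", StandardScaler()), ("lr", LogisticRegression(**defaults))]
            )
        if self.name == "gbt":
            defaults = dict(max_depth=3, n_estimators=100, random_state=seed)
            defaults.update(params)
            return GradientBoostingClassifier(**defaults)
        if self.name == "rf":
            defaults = dict(
                n_estimators=200, min_samples_leaf=20, random_state=seed, n_jobs=1
            )
            defaults.update(params)
            return RandomForestClassifier(**defaults)
        raise ValueError(f"unknown learner {self.name!r}")


def _as_specs(library: Sequence) -> list[LearnerSpec]:
    specs = []
    for item in library:
        specs.append(item if isinstance(item, LearnerSpec) else LearnerSpec(str(item)))
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate learner names in library: {names}")
    return specs


class _MeanLearner:
    """Intercept-only classifier: predicts the marginal outcome rate."""

    def fit(self, X, y):
        self.p_ = float(np.mean(y))
        return self

    def predict_p1(self, X):
        return np.full(len(X), self.p_)


def _pos_proba(est, X) -> np.ndarray:
    if hasattr(est, "predict_p1"):
        return est.predict_p1(X)
    proba = est.predict_proba(X)
    classes = list(est.classes_)
    if 1 in classes:
        return proba[:, classes.index(1)]
    return np.zeros(len(X))


def _log_loss(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, PRED_CLIP, 1 - PRED_CLIP)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class SuperLearner:
    """Convex cross-validated ensemble of binary-outcome learners.

    Ensemble weights are non-negative, sum to one, and minimise the V-fold
    cross-validated binomial log-loss of the combined prediction; member
    learners are then refit on the full data.  Learners whose fit raises are
    dropped with a warning (weights renormalise over the survivors).
    """

    def __init__(self, library: Sequence = DEFAULT_Q_LIBRARY, V: int = 10, seed: int = 0):
        self.specs = _as_specs(library)
        self.V = int(V)
        self.seed = int(seed)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SuperLearner":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        if n < 2 * self.V:
            raise ValueError(f"need at least {2 * self.V} rows for {self.V}-fold CV")

        if len(self.specs) == 1:
            # Single-learner library: no ensembling needed.
            spec = self.specs[0]
            est = spec.make(derive_seed(self.seed, f"full:{spec.name}"))
            est.fit(X, y)
            self.members_ = [(spec, est)]
            self.weights_ = np.array([1.0])
            self.cv_risks_ = {spec.name: float("nan")}
            self.ensemble_cv_risk_ = float("nan")
            return self

        kf = KFold(n_splits=self.V, shuffle=True, random_state=derive_seed(self.seed, "cv"))
        folds = list(kf.split(X))

        cv_preds: dict[str, np.ndarray] = {}
        alive: list[LearnerSpec] = []
        for spec in self.specs:
            preds = np.empty(n)
            try:
                for k, (tr, te) in enumerate(folds):
                    est = spec.make(derive_seed(self.seed, f"cv{k}:{spec.name}"))
                    est.fit(X[tr], y[tr])
                    preds[te] = _pos_proba(est, X[te])
            except Exception as exc:  # noqa: BLE001 - any learner failure drops it
                logger.warning("learner %s failed in CV (%s); dropped", spec.name, exc)
                continue
            cv_preds[spec.name] = np.clip(preds, PRED_CLIP, 1 - PRED_CLIP)
            alive.append(spec)
        if not alive:
            raise RuntimeError("all learners failed to fit")

        P = np.column_stack([cv_preds[s.name] for s in alive])
        self.cv_risks_ = {s.name: _log_loss(y, P[:, j]) for j, s in enumerate(alive)}
        w = self._solve_weights(P, y)
        self.ensemble_cv_risk_ = _log_loss(y, P @ w)

        members = []
        kept_w = []
        for j, spec in enumerate(alive):
            try:
                est = spec.make(derive_seed(self.seed, f"full:{spec.name}"))
                est.fit(X, y)
            except Exception as exc:  # noqa: BLE001
                logger.warning("learner %s failed on full data (%s); dropped", spec.name, exc)
                continue
            members.append((spec, est))
            kept_w.append(w[j])
        if not members:
            raise RuntimeError("all learners failed to fit on the full data")
        kept_w = np.asarray(kept_w)
        if kept_w.sum() <= 0:
            kept_w = np.ones(len(members))
        self.weights_ = kept_w / kept_w.sum()
        self.members_ = members
        return self

    @staticmethod
    def _solve_weights(P: np.ndarray, y: np.ndarray) -> np.ndarray:
        m = P.shape[1]
        if m == 1:
            return np.array([1.0])

        def objective(w):
            return _log_loss(y, P @ w)

        res = minimize(
            objective,
            x0=np.full(m, 1.0 / m),
            method="SLSQP",
            bounds=[(0.0, 1.0)] * m,
            constraints=[{"type": "eq", "fun": lambda w: np.sum(w) - 1.0}],
            options={"maxiter": 200, "ftol": 1e-10},
        )
        if res.success and np.all(res.x >= -1e-9):
            w = np.clip(res.x, 0.0, 1.0)
            return w / w.sum()
        # Fallback: discrete super learner (best single member).
        logger.warning("weight optimisation failed; falling back to discrete selector")
        risks = [_log_loss(y, P[:, j]) for j in range(m)]
        w = np.zeros(m)
        w[int(np.argmin(risks))] = 1.0
        return w

    def predict_p1(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        for w, (_, est) in zip(self.weights_, self.members_):
            if w > 0:
                out += w * np.clip(_pos_proba(est, X), PRED_CLIP, 1 - PRED_CLIP)
        return out


# ---------------------------------------------------------------------------
# Outcome regression Qbar(a, w)
# ---------------------------------------------------------------------------


class OutcomeRegression:
    """Fitted outcome regression ``Qbar_n``: (a, w) -> P(Y = 1 | a, w)."""

    def __init__(self, sl: SuperLearner, w_cols: list[str]):
        self.sl = sl
        self.w_cols = list(w_cols)

    def predict(self, a, w: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.w_cols if c not in w.columns]
        if missing:
            raise KeyError(
                f"covariate schema mismatch: missing columns {missing} "
                f"(trained on {self.w_cols})"
            )
        a = np.asarray(a, dtype=float)
        X = np.column_stack([a, w[self.w_cols].to_numpy(dtype=float)])
        return np.clip(self.sl.predict_p1(X), PRED_CLIP, 1 - PRED_CLIP)

    __call__ = predict


def fit_outcome_regression(
    data: pd.DataFrame,
    library: Sequence = DEFAULT_Q_LIBRARY,
    V: int = 10,
    seed: int = 0,
    outcome_col: str = "Y",
    w_cols: list[str] | None = None,
) -> OutcomeRegression:
    """Fit ``Qbar_n(a, w)`` by super learner with (A, W) as covariates."""
    if w_cols is None:
        from .cohort import covariate_columns

        w_cols = covariate_columns(data)
    y = data[outcome_col].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome_col!r} must be binary")
    if data[w_cols].isna().any().any() or data["A"].isna().any():
        raise ValueError("missing values in A or W; impute before fitting")
    X = np.column_stack([data["A"].to_numpy(dtype=float), data[w_cols].to_numpy(dtype=float)])
    sl = SuperLearner(library, V=V, seed=derive_seed(seed, "qbar")).fit(X, y)
    fit = OutcomeRegression(sl, w_cols)
    fit.fitted_values_ = fit.predict(data["A"].to_numpy(), data[w_cols])
    return fit


def predict_Q(qbar: OutcomeRegression, a, w: pd.DataFrame) -> np.ndarray:
    """Evaluate a fitted outcome regression, clipped to [1e-6, 1 - 1e-6]."""
    return qbar.predict(a, w)


# ---------------------------------------------------------------------------
# Conditional exposure density g(a | w)
# ---------------------------------------------------------------------------


class HazardConditionalDensity:
    """Binned pooled-hazard estimator of g(a | w) on [0, 1].

    [0, 1] is partitioned at empirical quantiles of A (equal-mass bins,
    duplicated edges merged).  A binary "hazard" classifier is fit on the
    pooled expansion (one row per subject per bin up to and including the
    subject's bin) with W and one-hot bin indicators as features (so the
    hazard is saturated in the bin dimension); bin probabilities are the
    discrete-hazard products, renormalised per row, and the density is bin
    probability over bin width.
    """

    def __init__(self, edges: np.ndarray, sl: SuperLearner, w_cols: list[str]):
        self.edges = np.asarray(edges, dtype=float)
        self.widths = np.diff(self.edges)
        self.mids = 0.5 * (self.edges[:-1] + self.edges[1:])
        self.sl = sl
        self.w_cols = list(w_cols)

    @property
    def n_bins(self) -> int:
        return len(self.widths)

    def _bin_of(self, a: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.edges, a, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)

    def bin_probs(self, w: pd.DataFrame) -> np.ndarray:
        """(n, B) matrix of conditional bin-membership probabilities."""
        missing = [c for c in self.w_cols if c not in w.columns]
        if missing:
            raise KeyError(f"covariate schema mismatch: missing columns {missing}")
        W = w[self.w_cols].to_numpy(dtype=float)
        n, B = len(W), self.n_bins
        Wrep = np.repeat(W, B, axis=0)
        onehot = np.tile(np.eye(B), (n, 1))
        X = np.column_stack([onehot, Wrep])
        h = self.sl.predict_p1(X).reshape(n, B)
        h = np.clip(h, PRED_CLIP, 1 - PRED_CLIP)
        surv = np.cumprod(1 - h, axis=1)
        probs = h.copy()
        probs[:, 1:] *= surv[:, :-1]
        probs /= probs.sum(axis=1, keepdims=True)
        return probs

    def pdf(self, a, w: pd.DataFrame) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        probs = self.bin_probs(w)
        idx = self._bin_of(a)
        dens = probs[np.arange(len(a)), idx] / self.widths[idx]
        dens[(a < 0) | (a > 1)] = 0.0
        return dens

    __call__ = pdf


class BetaConditionalDensity:
    """Parametric beta-regression density for an exposure on (0, 1).

    A | W = w ~ Beta(mu(w) * phi, (1 - mu(w)) * phi) with
    logit mu(w) = beta0 + w' beta and a common concentration phi, fitted by
    maximum likelihood (covariates are standardized internally, which is an
    affine reparameterization and leaves the model unchanged).
    """

    def __init__(
        self,
        beta: np.ndarray,
        log_phi: float,
        w_cols: list[str],
        center: np.ndarray,
        scale: np.ndarray,
    ):
        self.beta = np.asarray(beta, dtype=float)
        self.log_phi = float(log_phi)
        self.w_cols = list(w_cols)
        self.center = np.asarray(center, dtype=float)
        self.scale = np.asarray(scale, dtype=float)

    @staticmethod
    def fit(
        a: np.ndarray, w: pd.DataFrame, w_cols: list[str] | None = None
    ) -> "BetaConditionalDensity":
        if w_cols is None:
            w_cols = list(w.columns)
        a = np.clip(np.asarray(a, dtype=float), 1e-4, 1 - 1e-4)
        Wraw = w[w_cols].to_numpy(dtype=float)
        center = Wraw.mean(axis=0) if Wraw.size else np.zeros(0)
        scale = Wraw.std(axis=0) if Wraw.size else np.zeros(0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        X = np.column_stack([np.ones(len(a)), (Wraw - center) / scale])
        la, l1a = np.log(a), np.log1p(-a)

        mbar, vbar = float(np.mean(a)), float(np.var(a))
        phi0 = max(mbar * (1 - mbar) / max(vbar, 1e-6) - 1, 1.0)
        x0 = np.zeros(X.shape[1] + 1)
        x0[0] = logit(mbar)
        x0[-1] = np.log(phi0)

        def nll_grad(theta):
            beta, lphi = theta[:-1], theta[-1]
            phi = np.exp(lphi)
            mu = expit(np.clip(X @ beta, -30, 30))
            mu = np.clip(mu, 1e-6, 1 - 1e-6)
            p, q = mu * phi, (1 - mu) * phi
            ll = (p - 1) * la + (q - 1) * l1a - betaln(p, q)
            dmu = phi * (la - l1a - digamma(p) + digamma(q))
            gbeta = -(dmu * mu * (1 - mu)) @ X
            dphi = mu * la + (1 - mu) * l1a - mu * digamma(p) - (1 - mu) * digamma(q) + digamma(phi)
            glphi = -np.sum(dphi) * phi
            return -np.sum(ll), np.append(gbeta, glphi)

        res = minimize(
            nll_grad, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if not res.success:
            logger.warning("beta-regression MLE did not fully converge: %s", res.message)
        return BetaConditionalDensity(res.x[:-1], res.x[-1], w_cols, center, scale)

    def _mu_phi(self, w: pd.DataFrame) -> tuple[np.ndarray, float]:
        missing = [c for c in self.w_cols if c not in w.columns]
        if missing:
            raise KeyError(f"covariate schema mismatch: missing columns {missing}")
        Wraw = w[self.w_cols].to_numpy(dtype=float)
        Z = (Wraw - self.center) / self.scale if Wraw.size else Wraw
        X = np.column_stack([np.ones(len(w)), Z])
        mu = expit(np.clip(X @ self.beta, -30, 30))
        return np.clip(mu, 1e-6, 1 - 1e-6), float(np.exp(self.log_phi))

    def pdf(self, a, w: pd.DataFrame) -> np.ndarray:
        from scipy.stats import beta as beta_dist

        a = np.clip(np.asarray(a, dtype=float), 1e-6, 1 - 1e-6)
        mu, phi = self._mu_phi(w)
        return beta_dist.pdf(a, mu * phi, (1 - mu) * phi)

    __call__ = pdf


def fit_conditional_density(
    data: pd.DataFrame,
    bins: int = 20,
    library: Sequence = DEFAULT_G_LIBRARY,
    V: int = 10,
    seed: int = 0,
    w_cols: list[str] | None = None,
    method: str = "hazard",
):
    """Fit g_n(a | w), the conditional density of adherence given W.

    ``method='hazard'`` (default) uses the binned pooled-hazard classifier;
    ``method='beta'`` fits parametric beta regression (the ``bins``,
    ``library`` and ``V`` arguments are then ignored).
    """
    if w_cols is None:
        from .cohort import covariate_columns

        w_cols = covariate_columns(data)
    a = data["A"].to_numpy(dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("exposure A outside [0, 1]")

    if method == "beta":
        return BetaConditionalDensity.fit(a, data[w_cols], w_cols)
    if method != "hazard":
        raise ValueError(f"unknown density method {method!r}")

    if bins < 2:
        raise ValueError("need at least 2 bins")
    if np.std(a) < 1e-12:
        raise ValueError(
            "exposure is degenerate (single value); conditional density "
            "undefined — positivity hazard"
        )
    edges = np.quantile(a, np.linspace(0, 1, bins + 1))
    edges[0], edges[-1] = 0.0, 1.0
    uniq = np.unique(edges)
    if len(uniq) < len(edges):
        logger.warning(
            "merged %d empty/tied density bins", len(edges) - len(uniq)
        )
    edges = uniq
    if len(edges) < 3:
        raise ValueError("exposure too discrete for binned density estimation")

    B = len(edges) - 1
    mids = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.searchsorted(edges, a, side="right") - 1, 0, B - 1)

    # Pooled expansion: one row per subject per bin up to the subject's bin.
    W = data[w_cols].to_numpy(dtype=float)
    counts = idx + 1
    subj = np.repeat(np.arange(len(a)), counts)
    binj = np.concatenate([np.arange(c) for c in counts])
    Xp = np.column_stack([np.eye(B)[binj], W[subj]])
    yp = (binj == idx[subj]).astype(float)

    sl = SuperLearner(library, V=V, seed=derive_seed(seed, "gdens")).fit(Xp, yp)
    return HazardConditionalDensity(edges, sl, w_cols)


@dataclass
class NuisanceFit:
    """Bundle of fitted nuisances with their configuration."""

    qbar: OutcomeRegression
    g: object
    V: int = 10
    seed: int = 0
    meta: dict = field(default_factory=dict)
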