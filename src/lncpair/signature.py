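"""Survival-pair selection and the pair-based risk score.

The selection funnel follows the construction used for published pair
signatures: per-pair univariate Cox (keep Wald p < 0.05), LASSO-penalized Cox
over the survivors with the penalty chosen by k-fold cross-validated
partial-likelihood deviance, then one joint unpenalized multivariate Cox over
the LASSO-selected pairs. The signature's risk score for a patient is

    riskscore = sum_i indicator_i * beta_i

where indicator_i is the 0/1 pair value and beta_i the multivariate Cox
coefficient. Because the indicators are rank-based, the score inherits
invariance to monotone transformations of the expression values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from scipy import stats
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .pairs import PairMatrix

logger = logging.getLogger(__name__)

#: two-sided 95% normal quantile, fixed so confidence intervals are exactly
#: reproducible across platforms
Z95 = 1.959964

UNIVARIATE_ALPHA_DEFAULT = 0.05
LASSO_FOLDS_DEFAULT = 10


@dataclass
class CoxFitResult:
    covariate: str
    beta: float
    se: float
    converged: bool = True

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z95 * self.se))

    @property
    def wald_z(self) -> float:
        if not np.isfinite(self.se) or self.se <= 0:
            return np.nan
        return self.beta / self.se

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.wald_z)))


@dataclass
class SignatureModel:
    """Ordered (pair_name, beta) terms defining the risk score."""

    terms: list[tuple[str, float]]

    def __post_init__(self) -> None:
        names = [t[0] for t in self.terms]
        if len(names) != len(set(names)):
            raise ValueError("duplicate pairs in signature")
        if not all(np.isfinite(b) for _, b in self.terms):
            raise ValueError("non-finite coefficient in signature")

    @property
    def pair_names(self) -> list[str]:
        return [t[0] for t in self.terms]

    @property
    def betas(self) -> np.ndarray:
        return np.array([t[1] for t in self.terms])


@dataclass
class RiskProfile:
    """Per-patient risk scores; cutoff and groups are set by stratification."""

    scores: pd.Series
    cutoff: float | None = None
    group: pd.Series | None = None  # "high" | "low"


@dataclass
class LassoCoxResult:
    alphas: np.ndarray
    coef_path: np.ndarray  # (n_features, n_alphas) on the original 0/1 scale
    cv_deviance_mean: np.ndarray
    cv_deviance_se: np.ndarray
    alpha_opt: float
    selected: list[str]
    coefs: pd.Series  # nonzero coefficients at alpha_opt


# ---------------------------------------------------------------------------
# Efron log partial likelihood (used for CV deviance and fit diagnostics)
# ---------------------------------------------------------------------------


def efron_log_partial_likelihood(
    beta: np.ndarray, X: np.ndarray, times: np.ndarray, events: np.ndarray
) -> float:
    """Cox log partial likelihood with the Efron correction for tied events."""
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    order = np.argsort(times, kind="stable")
    t_s, e_s, eta_s = times[order], events[order].astype(bool), eta[order]
    w = np.exp(eta_s)
    # suffix sums give the risk-set total at each distinct time
    n = len(t_s)
    ll = 0.0
    i = 0
    # cumulative sum from the end: risk set for time t = all j with t_j >= t
    suffix = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        tied = np.flatnonzero(e_s[i:j]) + i
        d = len(tied)
        if d > 0:
            s_risk = suffix[i]
            s_tied = float(w[tied].sum())
            ll += float(eta_s[tied].sum())
            for ell in range(d):
                ll -= np.log(s_risk - (ell / d) * s_tied)
        i = j
    return float(ll)


# ---------------------------------------------------------------------------
# Unpenalized Cox
# ---------------------------------------------------------------------------


def fit_cox(
    X: pd.DataFrame, times: np.ndarray, events: np.ndarray
) -> list[CoxFitResult]:
    """Unpenalized Cox PH fit (Efron ties, Newton-Raphson) for 1+ covariates.

    On a monotone partial likelihood (perfect separation) the fit is retried
    with a small ridge stabiliser and flagged ``converged=False``.
    """
    events = np.asarray(events, dtype=int)
    times = np.asarray(times, dtype=float)
    if events.sum() == 0:
        raise ValueError("no events in cohort; Cox model undefined")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariates: {constant}")
    df = X.copy()
    df["_time"] = times
    df["_event"] = events

    def _do_fit(penalizer: float) -> CoxPHFitter:
        cph = CoxPHFitter(penalizer=penalizer)
        cph.fit(
            df,
            duration_col="_time",
            event_col="_event",
            fit_options={"precision": 1e-9, "max_steps": 100},
        )
        return cph

    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph = _do_fit(penalizer=0.0)
        except ConvergenceError:
            logger.warning("Cox fit failed to converge (monotone likelihood?); "
                           "refitting with ridge stabiliser, betas are capped")
            cph = _do_fit(penalizer=0.1)
            converged = False
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        converged = False

    return [
        CoxFitResult(
            covariate=c,
            beta=float(cph.params_[c]),
            se=float(cph.standard_errors_[c]),
            converged=converged,
        )
        for c in X.columns
    ]


def cox_results_to_frame(results: list[CoxFitResult]) -> pd.DataFrame:
    """Report table: covariate, coef, HR, HR.95L, HR.95H, p_value."""
    return pd.DataFrame(
        [(r.covariate, r.beta, r.hr, r.ci_low, r.ci_high, r.p, r.converged) for r in results],
        columns=["covariate", "coef", "HR", "HR.95L", "HR.95H", "p_value", "converged"],
    )


def univariate_screen(
    pm: PairMatrix,
    times: np.ndarray,
    events: np.ndarray,
    alpha: float = UNIVARIATE_ALPHA_DEFAULT,
) -> tuple[list[str], list[CoxFitResult]]:
    """Per-pair univariate Cox; keep pairs with Wald p < alpha, sorted by p."""
    results: list[CoxFitResult] = []
    for name, row in zip(pm.pair_names, pm.indicator):
        if row.min() == row.max():
            logger.warning("pair %s constant across cohort, skipped in screen", name)
            continue
        res = fit_cox(pd.DataFrame({name: row}, index=pm.samples), times, events)[0]
        results.append(res)
    surviving = sorted((r for r in results if r.p < alpha), key=lambda r: r.p)
    names = [r.covariate for r in surviving]
    logger.info("univariate screen: %d / %d pairs with p < %g", len(names), pm.n_pairs, alpha)
    return names, results


# ---------------------------------------------------------------------------
# LASSO-Cox
# ---------------------------------------------------------------------------


def fit_lasso_cox(
    X: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    n_folds: int = LASSO_FOLDS_DEFAULT,
    seed: int = 0,
    lambda_rule: str = "min",
    n_alphas: int = 100,
    alpha_min_ratio: float = 0.01,
    alphas: list[float] | None = None,
) -> LassoCoxResult:
    """L1-penalized Cox over a log-spaced penalty path with k-fold CV.

    The path is fit by cyclic coordinate descent (glmnet-style, with internal
    feature standardisation; coefficients are reported on the original 0/1
    scale). The penalty is chosen at the minimum mean cross-validated
    partial-likelihood deviance (``lambda_rule="min"``) or by the 1-SE rule.
    """
    if X.shape[1] < 2:
        raise ValueError("LASSO-Cox needs >= 2 candidate pairs")
    events = np.asarray(events, dtype=int)
    times = np.asarray(times, dtype=float)
    if events.sum() < n_folds:
        raise ValueError(f"need >= {n_folds} events for {n_folds}-fold CV")
    y = Surv.from_arrays(event=events.astype(bool), time=times)
    Xv = X.to_numpy(dtype=float)

    if alphas is not None:
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas), normalize=True)
    else:
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio, normalize=True
        )
    path.fit(Xv, y)
    alphas = np.asarray(path.alphas_)
    coef_path = np.asarray(path.coef_)
    if not np.any(coef_path != 0):
        raise ValueError("no informative pairs: all LASSO coefficients zero on the whole path")

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.full((n_folds, len(alphas)), np.nan)
    for k, (tr, te) in enumerate(kf.split(Xv)):
        if events[te].sum() == 0:
            continue
        fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, normalize=True)
        fold.fit(Xv[tr], y[tr])
        fold_alphas = {a: j for j, a in enumerate(fold.alphas_)}
        for j, a in enumerate(alphas):
            jj = fold_alphas.get(a)
            if jj is None:
                continue
            beta = fold.coef_[:, jj]
            dev[k, j] = -2.0 * efron_log_partial_likelihood(beta, Xv[te], times[te], events[te])
    # restrict the penalty choice to alphas every usable fold actually fit
    # (coordinate descent may stop a fold's path early)
    n_fit = np.sum(~np.isnan(dev), axis=0)
    covered = n_fit == n_fit.max()
    mean_dev = np.full(len(alphas), np.nan)
    se_dev = np.full(len(alphas), np.nan)
    for j in np.flatnonzero(covered):
        vals = dev[~np.isnan(dev[:, j]), j]
        mean_dev[j] = vals.mean()
        if len(vals) > 1:
            se_dev[j] = vals.std(ddof=1) / np.sqrt(len(vals))
    j_min = int(np.nanargmin(mean_dev))
    if lambda_rule == "min":
        j_opt = j_min
    elif lambda_rule == "1se":
        bound = mean_dev[j_min] + se_dev[j_min]
        within = np.flatnonzero(mean_dev <= bound)
        j_opt = int(within[0])  # alphas are decreasing; first = largest penalty
    else:
        raise ValueError(f"unknown lambda rule {lambda_rule!r}")

    coefs = coef_path[:, j_opt]
    if not np.any(coefs != 0):
        nz = np.flatnonzero((coef_path != 0).any(axis=0))
        j_opt = int(nz[0])
        coefs = coef_path[:, j_opt]
        logger.warning("empty model at CV-optimal penalty; moved to largest penalty "
                       "with a nonzero coefficient (alpha=%g)", alphas[j_opt])
    nonzero = np.flatnonzero(coefs != 0)
    selected = [X.columns[i] for i in nonzero]
    logger.info("LASSO-Cox: %d / %d pairs selected at alpha=%g (%s rule)",
                len(selected), X.shape[1], alphas[j_opt], lambda_rule)
    return LassoCoxResult(
        alphas=alphas,
        coef_path=coef_path,
        cv_deviance_mean=mean_dev,
        cv_deviance_se=se_dev,
        alpha_opt=float(alphas[j_opt]),
        selected=selected,
        coefs=pd.Series(coefs[nonzero], index=selected),
    )


# ---------------------------------------------------------------------------
# Final signature
# ---------------------------------------------------------------------------


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Greedy ordered drop of columns linearly dependent on earlier ones."""
    kept: list[str] = []
    M = np.empty((X.shape[0], 0))
    for c in X.columns:
        cand = np.column_stack([M, X[c].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > M.shape[1]:
            kept.append(c)
            M = cand
        else:
            logger.warning("dropping collinear pair %s from multivariate fit", c)
    return X[kept]


def build_signature(
    selected: list[str], pm: PairMatrix, times: np.ndarray, events: np.ndarray
) -> tuple[SignatureModel, list[CoxFitResult]]:
    """Joint multivariate Cox over the selected pairs -> signature terms."""
    if not selected:
        raise ValueError("no pairs selected for the signature")
    sub = pm.select_named(selected)
    X = sub.to_frame().T  # samples x pairs
    X = _drop_collinear(X)
    results = fit_cox(X, times, events)
    model = SignatureModel(terms=[(r.covariate, r.beta) for r in results])
    return model, results


def compute_risk_scores(pm: PairMatrix, model: SignatureModel) -> RiskProfile:
    """Per-sample dot product of pair indicators and signature coefficients."""
    sub = pm.select_named(model.pair_names)  # raises naming any missing pair
    scores = pd.Series(model.betas @ sub.indicator, index=pm.samples, name="risk_score")
    return RiskProfile(scores=scores)
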