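"""Prognostic-model evaluation: time-dependent ROC, cutoff, stratification,
Kaplan-Meier comparison and clinical association tests.

The ROC at horizon t follows the cumulative/dynamic estimator of Heagerty,
Lumley & Pepe (2000) with Kaplan-Meier weighting: cases are subjects with an
event by t, controls are subjects surviving past t, and subjects censored
before t contribute through the KM estimate of the marker-conditional
survival. For a marker cutpoint c,

    sens(c, t) = [1 - S(t | M > c)] * P(M > c) / [1 - S(t)]
    spec(c, t) = S(t | M <= c) * P(M <= c) / S(t)

with all survival curves estimated by the product-limit method. The cutoff
maximising the Youden index (sensitivity + specificity - 1) on the 1-year
curve splits patients into high- and low-risk groups (high iff score >
cutoff), which are then compared by log-rank, and the risk score's
independence from clinicopathological covariates is tested with univariate
and multivariate Cox models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .signature import CoxFitResult, RiskProfile, fit_cox

logger = logging.getLogger(__name__)

#: evaluation horizons in days (1, 3, 5 years)
HORIZONS_DAYS = (365, 1095, 1825)

#: ordinal codings for clinical covariates in Cox models; labels not listed
#: (unknown, Tx, Nx, Mx, ...) are treated as missing and dropped per fit
STAGE_CODES = {"I": 1, "II": 2, "III": 3, "IV": 4}
T_CODES = {"T1": 1, "T2": 2, "T3": 3, "T4": 4}
N_CODES = {"N0": 0, "N1": 1, "N2": 2, "N3": 3}
M_CODES = {"M0": 0, "M1": 1}
SEX_CODES = {"male": 1, "female": 0}


@dataclass
class TimeDependentROC:
    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    degenerate: bool = False
    marker_median: float = np.nan


@dataclass
class KMCurve:
    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


@dataclass
class AssociationResult:
    test: str
    statistic: float
    p: float
    group_sizes: dict[str, int]
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


def kaplan_meier(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Product-limit survival estimate with at-risk counts."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty cohort")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(dtype=float)
    return KMCurve(timeline=timeline, survival=survival, at_risk=at_risk)


def _km_survival_at(times: np.ndarray, events: np.ndarray, t: float) -> float:
    # direct product-limit at a single time point (fast path for the ROC loop)
    if len(times) == 0:
        return 1.0
    order = np.argsort(times, kind="stable")
    ts, es = times[order], events[order]
    s = 1.0
    n_at_risk = len(ts)
    i = 0
    while i < len(ts) and ts[i] <= t:
        j = i
        d = 0
        while j < len(ts) and ts[j] == ts[i]:
            d += es[j]
            j += 1
        if d:
            s *= 1.0 - d / n_at_risk
        n_at_risk -= j - i
        i = j
    return s


def log_rank_test(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> AssociationResult:
    """Two-group log-rank chi-square test (1 df)."""
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {len(labels)}")
    mask = groups == labels[0]
    if mask.all() or (~mask).all():
        raise ValueError("one group is empty")
    res = logrank_test(times[mask], times[~mask], events[mask], events[~mask])
    return AssociationResult(
        test="log_rank",
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        group_sizes={str(labels[0]): int(mask.sum()), str(labels[1]): int((~mask).sum())},
    )


# ---------------------------------------------------------------------------
# Time-dependent ROC
# ---------------------------------------------------------------------------


def time_dependent_roc(
    scores: pd.Series | np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    horizon: float,
) -> TimeDependentROC:
    """Cumulative/dynamic ROC at ``horizon`` with KM weighting; AUC by trapezoid."""
    m = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not ((times <= horizon) & (events == 1)).any():
        raise ValueError(f"no events by horizon {horizon}")
    s_all = _km_survival_at(times, events, horizon)
    if s_all >= 1.0 or s_all <= 0.0:
        raise ValueError(f"degenerate overall survival {s_all} at horizon {horizon}")

    uniq = np.unique(m)
    if len(uniq) == 1:
        logger.warning("all marker values equal; degenerate ROC, AUC = 0.5 by convention")
        return TimeDependentROC(
            horizon=horizon,
            thresholds=uniq,
            sensitivity=np.array([1.0]),
            specificity=np.array([0.0]),
            auc=0.5,
            degenerate=True,
            marker_median=float(np.median(m)),
        )

    n = len(m)
    order = np.argsort(m, kind="stable")
    sens = np.empty(len(uniq))
    spec = np.empty(len(uniq))
    for k, c in enumerate(uniq):
        above = m > c
        n_above = int(above.sum())
        p_above = n_above / n
        if n_above:
            s_above = _km_survival_at(times[above], events[above], horizon)
            sens[k] = (1.0 - s_above) * p_above / (1.0 - s_all)
        else:
            sens[k] = 0.0
        below = ~above
        s_below = _km_survival_at(times[below], events[below], horizon)
        spec[k] = s_below * (1.0 - p_above) / s_all
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)

    # curve anchored at (0,0) and (1,1); thresholds descend left to right
    fpr = np.concatenate([[0.0], 1.0 - spec[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    # round away float noise so equal-coordinate points sort into a staircase
    fpr, tpr = np.round(fpr, 12), np.round(tpr, 12)
    srt = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[srt], fpr[srt]))
    return TimeDependentROC(
        horizon=horizon,
        thresholds=uniq,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        marker_median=float(np.median(m)),
    )


def youden_cutoff(roc: TimeDependentROC) -> tuple[float, float]:
    """Threshold maximising sensitivity + specificity - 1 (ties -> smallest)."""
    if roc.degenerate:
        logger.warning("degenerate ROC; using marker median as cutoff")
        return roc.marker_median, 0.0
    j = roc.sensitivity + roc.specificity - 1.0
    best = float(np.max(j))
    k = int(np.flatnonzero(j == best)[0])  # thresholds ascend; first = smallest
    return float(roc.thresholds[k]), best


def stratify(profile: RiskProfile, cutoff: float) -> RiskProfile:
    """High-risk iff risk score > cutoff (score equal to cutoff -> low)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    group = pd.Series(
        np.where(profile.scores > cutoff, "high", "low"), index=profile.scores.index, name="group"
    )
    n_high = int((group == "high").sum())
    n_low = len(group) - n_high
    logger.info("stratification at cutoff %.4f: %d high-risk, %d low-risk", cutoff, n_high, n_low)
    if n_high == 0 or n_low == 0:
        logger.warning("all samples fell into one risk group")
    return RiskProfile(scores=profile.scores, cutoff=cutoff, group=group)


# ---------------------------------------------------------------------------
# Independence analysis and clinical associations
# ---------------------------------------------------------------------------


def code_clinical_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    """Ordinal numeric coding of clinical covariates (unknowns -> NaN)."""
    return pd.DataFrame(
        {
            "age": pd.to_numeric(clinical["age"], errors="coerce"),
            "sex": clinical["sex"].map(SEX_CODES),
            "stage": clinical["stage"].map(STAGE_CODES),
            "t": clinical["t"].map(T_CODES),
            "n": clinical["n"].map(N_CODES),
            "m": clinical["m"].map(M_CODES),
        },
        index=clinical.index,
    )


def independence_analysis(
    profile: RiskProfile, clinical: pd.DataFrame
) -> tuple[list[CoxFitResult], list[CoxFitResult]]:
    """Univariate Cox per covariate plus one joint multivariate Cox.

    Tests whether the risk score remains prognostic once age, sex, stage and
    TNM categories are accounted for. Unknown categories are dropped per fit;
    covariates that are constant after dropping are skipped with a warning.
    """
    coded = code_clinical_covariates(clinical)
    coded["risk_score"] = profile.scores.reindex(coded.index)
    times = clinical["os_time_days"].to_numpy(dtype=float)
    events = clinical["event"].to_numpy(dtype=int)

    uni: list[CoxFitResult] = []
    usable: list[str] = []
    for c in coded.columns:
        ok = coded[c].notna().to_numpy()
        sub = coded.loc[ok, [c]]
        if sub[c].nunique() <= 1 or events[ok].sum() == 0:
            logger.warning("covariate %s degenerate, dropped from independence analysis", c)
            continue
        uni.append(fit_cox(sub, times[ok], events[ok])[0])
        usable.append(c)

    complete = coded[usable].notna().all(axis=1).to_numpy()
    multi = fit_cox(coded.loc[complete, usable], times[complete], events[complete])
    return uni, multi


def chi_square_association(
    groups: pd.Series, covariate: pd.Series, drop_labels: tuple[str, ...] = ("unknown",)
) -> AssociationResult:
    """Pearson chi-square (no continuity correction) of risk group vs category."""
    df = pd.DataFrame({"group": groups, "cov": covariate}).dropna()
    df = df[~df["cov"].astype(str).isin(drop_labels)]
    table = pd.crosstab(df["group"], df["cov"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(f"degenerate contingency table of shape {table.shape}")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if (expected < 5).any():
        logger.warning("chi-square: %d expected cell counts < 5", int((expected < 5).sum()))
    return AssociationResult(
        test="chi_square",
        statistic=float(chi2),
        p=float(p),
        group_sizes={str(k): int(v) for k, v in table.sum(axis=1).items()},
        extra={"dof": int(dof)},
    )


def wilcoxon_rank_sum(values: np.ndarray, groups: np.ndarray) -> AssociationResult:
    """Mann-Whitney U; exact enumeration when both groups have <= 8 values
    and there are no ties, tie-corrected normal approximation otherwise."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"rank-sum test requires exactly 2 groups, got {len(labels)}")
    x = values[groups == labels[0]]
    y = values[groups == labels[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group in rank-sum test")
    if np.all(values == values[0]):
        return AssociationResult(
            test="wilcoxon_rank_sum",
            statistic=len(x) * len(y) / 2.0,
            p=1.0,
            group_sizes={str(labels[0]): len(x), str(labels[1]): len(y)},
        )
    exact = len(x) <= 8 and len(y) <= 8 and len(np.unique(values)) == len(values)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact" if exact else "asymptotic")
    return AssociationResult(
        test="wilcoxon_rank_sum",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        group_sizes={str(labels[0]): len(x), str(labels[1]): len(y)},
        extra={"median_" + str(labels[0]): float(np.median(x)), "median_" + str(labels[1]): float(np.median(y))},
    )
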