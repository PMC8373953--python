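"""Immune-related lncRNA screening and differential expression.

Two filters feed the pair signature. First, a lncRNA is called immune-related
when its log2(x+1) expression has Pearson |r| > 0.5 with at least one
immune-related gene at p < 0.001 (t-test on n-2 df). Second, among those,
differential expression between tumor and normal is assessed with a two-group
moderated t-statistic (empirical-Bayes variance shrinkage in the limma style)
and a gene is called DE when |log2FC| > 2 and the Benjamini-Hochberg adjusted
p is below 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneList

logger = logging.getLogger(__name__)

R_MIN_DEFAULT = 0.5
P_CORR_DEFAULT = 0.001
LFC_MIN_DEFAULT = 2.0
DE_ALPHA_DEFAULT = 0.05


@dataclass
class CorrelationHit:
    lncrna_id: str
    immune_gene_id: str
    r: float
    p: float


@dataclass
class DEResult:
    gene_id: str
    log2fc: float
    p_raw: float
    p_adj: float
    direction: str  # "up" | "down"
    is_de: bool


@dataclass
class SetOverlap:
    both: set
    a_only: set
    b_only: set

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.a_only), len(self.b_only), len(self.both)


# ---------------------------------------------------------------------------
# Pearson screen
# ---------------------------------------------------------------------------


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    # two-sided p from t = r*sqrt(n-2)/sqrt(1-r^2), Student-t with n-2 df
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def pearson_screen(
    expr: ExpressionMatrix,
    immune_genes: GeneList | set[str],
    lncrnas: set[str],
    r_min: float = R_MIN_DEFAULT,
    p_max: float = P_CORR_DEFAULT,
    samples: list[str] | None = None,
) -> tuple[set[str], list[CorrelationHit]]:
    """Select lncRNAs correlated with at least one immune gene.

    Correlations are Pearson on log2(x+1) values across ``samples`` (all
    samples by default). A lncRNA is selected iff some immune gene satisfies
    |r| > r_min and p < p_max. Constant (zero-variance) vectors are skipped
    with a warning because r is undefined for them; genes absent from the
    matrix are skipped with a warning.
    """
    logv = expr.log2p1()
    if samples is not None:
        logv = logv[samples]
    n = logv.shape[1]
    if n < 3:
        raise ValueError(f"pearson_screen needs >= 3 samples, got {n}")

    present = set(logv.index)
    imm = sorted(set(immune_genes) & present)
    lnc = sorted(set(lncrnas) & present)
    for name, wanted, got in (("immune genes", set(immune_genes), imm), ("lncRNAs", set(lncrnas), lnc)):
        absent = wanted - present
        if absent:
            logger.warning("%d %s absent from expression matrix, skipped", len(absent), name)
    if not imm or not lnc:
        return set(), []

    L = logv.loc[lnc].to_numpy(dtype=float)
    G = logv.loc[imm].to_numpy(dtype=float)
    l_ok = np.ptp(L, axis=1) > 0
    g_ok = np.ptp(G, axis=1) > 0
    if (~l_ok).any() or (~g_ok).any():
        logger.warning(
            "skipping %d constant lncRNAs and %d constant immune genes (r undefined)",
            int((~l_ok).sum()), int((~g_ok).sum()),
        )
    l_sd = L[l_ok].std(axis=1, keepdims=True, ddof=0)
    g_sd = G[g_ok].std(axis=1, keepdims=True, ddof=0)
    Lz = (L[l_ok] - L[l_ok].mean(axis=1, keepdims=True)) / l_sd
    Gz = (G[g_ok] - G[g_ok].mean(axis=1, keepdims=True)) / g_sd
    R = Lz @ Gz.T / n
    P = _corr_pvalues(R, n)

    lnc_kept = [g for g, ok in zip(lnc, l_ok) if ok]
    imm_kept = [g for g, ok in zip(imm, g_ok) if ok]
    hit_mask = (np.abs(R) > r_min) & (P < p_max)
    hits = [
        CorrelationHit(lncrna_id=lnc_kept[i], immune_gene_id=imm_kept[j], r=float(R[i, j]), p=float(P[i, j]))
        for i, j in np.argwhere(hit_mask)
    ]
    selected = {h.lncrna_id for h in hits}
    logger.info("pearson screen: %d / %d lncRNAs immune-related", len(selected), len(lnc))
    return selected, hits


def hits_to_frame(hits: list[CorrelationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.lncrna_id, h.immune_gene_id, h.r, h.p) for h in hits],
        columns=["lncrna_id", "immune_gene_id", "r", "p"],
    )


# ---------------------------------------------------------------------------
# Moderated two-group t
# ---------------------------------------------------------------------------


def _invert_trigamma(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x  # good starting value for both tails
    for _ in range(50):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y -= step
        if y <= 0:
            y = 1e-8
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimation of the scaled-inverse-chi-square prior (s0^2, d0).

    Works on log sample variances: if s^2 ~ s0^2 * chi2_d/d scaled by an
    F-like prior, then e = log(s^2) - digamma(d/2) + log(d/2) has mean
    log(s0^2) + digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if pos.sum() < 2:
        return float(np.mean(s2)), np.inf
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = len(e)
    evar = np.var(e, ddof=1) * (n / (n - 1.0)) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        # no evidence of heterogeneity beyond chi-square sampling noise
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * _invert_trigamma(float(evar))
        s0_2 = float(np.exp(np.mean(e) - special.digamma(d0 / 2.0) + np.log(d0 / 2.0)))
    return s0_2, d0


def differential_expression(
    expr: ExpressionMatrix,
    lfc_min: float = LFC_MIN_DEFAULT,
    alpha: float = DE_ALPHA_DEFAULT,
    genes: list[str] | None = None,
    method: str = "moderated",
) -> list[DEResult]:
    """Tumor-vs-normal differential expression on the log2(x+1) scale.

    log2fc is the tumor mean minus the normal mean of log2(x+1). ``moderated``
    (default) shrinks per-gene pooled variances toward an empirical-Bayes
    prior and tests against t with d0 + dg df; ``welch`` is a plain Welch
    t-test fallback. p-values are BH-adjusted across all tested genes and a
    gene is DE iff |log2fc| > lfc_min and p_adj < alpha.
    """
    tumor = expr.samples_in_group("tumor")
    normal = expr.samples_in_group("normal")
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"both groups need >= 2 samples (tumor={len(tumor)}, normal={len(normal)})"
        )
    logv = expr.log2p1()
    if genes is not None:
        logv = logv.loc[list(genes)]
    X1 = logv[tumor].to_numpy(dtype=float)
    X0 = logv[normal].to_numpy(dtype=float)
    n1, n0 = X1.shape[1], X0.shape[1]
    m1, m0 = X1.mean(axis=1), X0.mean(axis=1)
    lfc = m1 - m0
    v1 = X1.var(axis=1, ddof=1)
    v0 = X0.var(axis=1, ddof=1)

    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = v1 / n1 + v0 / n0
            tstat = lfc / np.sqrt(se2)
            df_w = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
        p = 2.0 * stats.t.sf(np.abs(tstat), df=df_w)
    elif method == "moderated":
        dg = n1 + n0 - 2
        s2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / dg
        s0_2, d0 = _fit_variance_prior(s2, dg)
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_2)
            df_total = np.inf
        else:
            s2_tilde = (d0 * s0_2 + dg * s2) / (d0 + dg)
            df_total = d0 + dg
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = lfc / np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n0))
        p = 2.0 * stats.t.sf(np.abs(tstat), df=df_total)
    else:
        raise ValueError(f"unknown DE method {method!r}")

    # degenerate genes: no variance anywhere and no mean difference -> p = 1
    degenerate = (v1 == 0) & (v0 == 0) & (lfc == 0)
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)

    p_adj = benjamini_hochberg(list(p))
    results = [
        DEResult(
            gene_id=g,
            log2fc=float(lfc[i]),
            p_raw=float(p[i]),
            p_adj=float(p_adj[i]),
            direction="up" if lfc[i] >= 0 else "down",
            is_de=bool(abs(lfc[i]) > lfc_min and p_adj[i] < alpha),
        )
        for i, g in enumerate(logv.index)
    ]
    n_de = sum(r.is_de for r in results)
    logger.info("differential expression: %d / %d genes DE (|log2FC|>%g, adj p<%g)",
                n_de, len(results), lfc_min, alpha)
    return results


def de_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.log2fc, r.p_raw, r.p_adj, r.direction, r.is_de) for r in results],
        columns=["gene_id", "log2fc", "p_raw", "p_adj", "direction", "is_de"],
    )


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """BH step-up adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def intersect_sets(a: set, b: set) -> SetOverlap:
    both = a & b
    return SetOverlap(both=both, a_only=a - both, b_only=b - both)
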