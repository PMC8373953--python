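"""Associations between the risk model and externally computed score tables.

Immune-infiltration scores (one column per cell type x quantification
method), immunophenoscores and per-drug IC50 values are consumed as sample x
column tables produced by external tools; this module only tests their
association with the fitted risk profile (Spearman correlation against the
continuous score, Wilcoxon rank-sum between the high/low groups).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import AssociationResult, wilcoxon_rank_sum
from .io import ExpressionMatrix
from .screen import benjamini_hochberg
from .signature import RiskProfile

logger = logging.getLogger(__name__)

INFILTRATION_METHODS = (
    "TIMER", "xCell", "quanTIseq", "MCP-counter", "EPIC", "CIBERSORT-ABS", "CIBERSORT", "synthetic",
)


def read_score_table(path) -> pd.DataFrame:
    """TSV with sample IDs in the first column and numeric score columns.

    Infiltration tables name columns ``celltype.method``; IPS / drug tables
    use plain score or drug names.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate sample IDs in score table")
    if df.columns.has_duplicates:
        raise ValueError("duplicate columns in score table")
    return df.apply(pd.to_numeric)


def write_score_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def _split_column(col: str) -> tuple[str, str]:
    if "." in col:
        cell, method = col.rsplit(".", 1)
        if method in INFILTRATION_METHODS:
            return cell, method
    return col, "synthetic"


def spearman_risk_vs_infiltration(
    profile: RiskProfile, infiltration: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman rho of risk score vs every infiltration column.

    Returns a table (cell_type, method, rho, p, p_bh, direction, significant);
    constant columns are skipped with a warning. Raw p decides the
    significance flag; a BH column is provided alongside.
    """
    common = profile.scores.index.intersection(infiltration.index)
    if len(common) < 3:
        raise ValueError("need >= 3 overlapping samples")
    risk = profile.scores.loc[common].to_numpy()
    rows = []
    for col in infiltration.columns:
        v = infiltration.loc[common, col].to_numpy(dtype=float)
        if np.all(v == v[0]):
            logger.warning("infiltration column %s constant, skipped", col)
            continue
        rho, p = stats.spearmanr(risk, v)
        cell, method = _split_column(col)
        rows.append((cell, method, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["cell_type", "method", "rho", "p"])
    if len(out):
        out["p_bh"] = benjamini_hochberg(list(out["p"]))
        out["direction"] = np.where(out["rho"] >= 0, "positive", "negative")
        out["significant"] = out["p"] < alpha
    return out


def compare_gene_by_group(
    expr: ExpressionMatrix, gene: str, profile: RiskProfile
) -> AssociationResult:
    """Wilcoxon rank-sum of a gene's log2(x+1) expression between risk groups."""
    if profile.group is None:
        raise ValueError("profile has no risk groups; stratify first")
    if gene not in expr.values.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    common = profile.group.index.intersection(expr.values.columns)
    vals = np.log2(expr.values.loc[gene, common].to_numpy(dtype=float) + 1.0)
    groups = profile.group.loc[common].to_numpy()
    res = wilcoxon_rank_sum(vals, groups)
    res.extra["gene"] = gene
    return res


def compare_scores_by_group(scores: pd.DataFrame, profile: RiskProfile) -> pd.DataFrame:
    """Per-column Wilcoxon between risk groups with medians and direction.

    Direction is ``lower_in_high_risk`` when the high-risk median is below the
    low-risk median (for IC50 columns that reads as higher drug sensitivity
    in the high-risk group).
    """
    if profile.group is None:
        raise ValueError("profile has no risk groups; stratify first")
    common = profile.group.index.intersection(scores.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between scores and risk profile")
    groups = profile.group.loc[common].to_numpy()
    rows = []
    for col in scores.columns:
        vals = scores.loc[common, col].to_numpy(dtype=float)
        res = wilcoxon_rank_sum(vals, groups)
        med_high = float(np.median(vals[groups == "high"]))
        med_low = float(np.median(vals[groups == "low"]))
        direction = "lower_in_high_risk" if med_high < med_low else (
            "higher_in_high_risk" if med_high > med_low else "equal")
        rows.append((col, res.statistic, res.p, med_high, med_low, direction))
    return pd.DataFrame(
        rows, columns=["column", "U", "p", "median_high", "median_low", "direction"]
    )
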