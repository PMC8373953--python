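"""Synthetic tumor/normal cohorts with planted signal and known ground truth.

The generator emulates the statistical structure the pair-signature pipeline
assumes in an FPKM-like expression cohort:

* log-normal expression (Gaussian on the log2 scale, exponentiated), so pair
  indicators are essentially tie-free;
* a block of lncRNAs that are linear-plus-noise functions of immune genes,
  calibrated so the population Pearson correlation equals ``rho_target``;
* a subset of those lncRNAs with a planted tumor-vs-normal shift of
  ``de_lfc`` on the log2 scale (sign alternating);
* signal pairs of DE lncRNAs whose 0/1 indicators enter an exponential
  proportional-hazards model with coefficients ``beta_true``; member genes of
  a pair share their baseline mean so the indicator sits near 50% occupancy;
* independent exponential censoring calibrated to the target censoring
  fraction under the null linear predictor;
* immune-infiltration columns rank-correlated with the true risk (negative
  for a CD8-T-cell-like column, positive for an M0-macrophage-like column)
  and IPS/IC50 score columns shifted along the true risk.

Everything derives deterministically from one master seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ClinicalRecord,
    ExpressionMatrix,
    GeneCatalog,
    GeneList,
    write_clinical_table,
    write_expression_matrix,
    write_gene_catalog,
    write_gene_list,
    write_group_map,
)
from .immune import write_score_table

logger = logging.getLogger(__name__)


@dataclass
class CohortConfig:
    n_tumor: int = 400
    n_normal: int = 50
    n_lncrna: int = 200
    n_immune_gene: int = 30
    n_noise_gene: int = 100
    n_corr_lncrna: int = 60
    n_de_lncrna: int = 40
    n_signal_pairs: int = 8
    rho_target: float = 0.8
    de_lfc: float = 2.5
    beta_low: float = 0.4
    beta_high: float = 0.65
    baseline_hazard: float = 0.001  # events per day
    censor_rate: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_lncrna", "n_immune_gene", "n_noise_gene",
                     "n_corr_lncrna", "n_de_lncrna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_signal_pairs < 0:
            raise ValueError("n_signal_pairs must be >= 0")
        if not 0.0 < self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in (0, 1)")
        if not 0.5 < self.rho_target < 1.0:
            raise ValueError("rho_target must lie in (0.5, 1)")
        if self.n_de_lncrna > self.n_corr_lncrna:
            raise ValueError("n_de_lncrna cannot exceed n_corr_lncrna")
        if self.n_corr_lncrna > self.n_lncrna:
            raise ValueError("n_corr_lncrna cannot exceed n_lncrna")
        if self.n_signal_pairs > math.comb(self.n_de_lncrna, 2):
            raise ValueError("n_signal_pairs exceeds the number of available DE pairs")
        if 2 * self.n_signal_pairs > self.n_de_lncrna:
            raise ValueError(
                "signal pairs are built from disjoint DE lncRNAs: "
                "need n_de_lncrna >= 2 * n_signal_pairs"
            )


@dataclass
class GroundTruth:
    corr_lncrnas: set[str]
    de_lncrnas: dict[str, float]  # gene -> planted signed log2FC
    signal_pairs: list[tuple[str, str, float]]  # (gene_a, gene_b, beta_true)
    true_risk: dict[str, float]


@dataclass
class Cohort:
    expression: ExpressionMatrix
    catalog: GeneCatalog
    clinical: list[ClinicalRecord]
    infiltration: pd.DataFrame
    scores: pd.DataFrame
    immune_genes: GeneList
    truth: GroundTruth
    config: CohortConfig


def censoring_calibration(baseline_hazard: float, censor_rate: float) -> float:
    """Exponential censoring rate giving P(censor before event) = censor_rate.

    For independent exponentials with event rate lambda and censoring rate c,
    P(C < T) = c / (c + lambda), so c = lambda * q / (1 - q).
    """
    if not 0.0 < censor_rate < 1.0:
        raise ValueError("censor_rate must lie in (0, 1)")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    return baseline_hazard * censor_rate / (1.0 - censor_rate)


#: within-sample log2 noise of a correlated lncRNA around its immune-gene trend
_LNC_NOISE_SD = 0.5
#: per-sample log2 spread of an immune gene
_IMMUNE_SD = 1.0
#: clinical category frequencies emulating a TCGA-LUAD-like stage mix
_STAGE_P = {"I": 0.5367, "II": 0.2347, "III": 0.1612, "IV": 0.0510, "unknown": 0.0164}
_T_P = {"T1": 0.3327, "T2": 0.5367, "T3": 0.0878, "T4": 0.0367, "Tx": 0.0061}
_N_P = {"N0": 0.6469, "N1": 0.1878, "N2": 0.1388, "N3": 0.0041, "Nx": 0.0224}
_M_P = {"M0": 0.6612, "M1": 0.0490, "Mx": 0.2898}


def _draw(rng: np.random.Generator, table: dict[str, float], size: int) -> np.ndarray:
    labels = list(table)
    p = np.array([table[k] for k in labels])
    return rng.choice(labels, size=size, p=p / p.sum())


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate one cohort (expression, catalog, clinical, score tables, truth)."""
    ss = np.random.SeedSequence(config.seed)
    r_expr, r_surv, r_clin, r_infil = (np.random.default_rng(s) for s in ss.spawn(4))

    n_s = config.n_tumor + config.n_normal
    tumor_ids = [f"TUMOR{i:04d}" for i in range(config.n_tumor)]
    normal_ids = [f"NORMAL{i:04d}" for i in range(config.n_normal)]
    samples = tumor_ids + normal_ids
    is_tumor = np.array([1] * config.n_tumor + [0] * config.n_normal, dtype=float)

    lnc_ids = [f"LNC{i:04d}" for i in range(config.n_lncrna)]
    imm_ids = [f"IRG{i:03d}" for i in range(config.n_immune_gene)]
    pcg_ids = [f"PCG{i:03d}" for i in range(config.n_noise_gene)]

    # --- immune genes: independent log-normal drivers -----------------------
    imm_mu = r_expr.uniform(3.0, 8.0, size=config.n_immune_gene)
    Z_imm = imm_mu[:, None] + r_expr.normal(0.0, _IMMUNE_SD, size=(config.n_immune_gene, n_s))

    # --- planted assignments -------------------------------------------------
    corr_lnc = lnc_ids[: config.n_corr_lncrna]
    de_lnc = corr_lnc[: config.n_de_lncrna]
    de_sign = {g: (1.0 if i % 2 == 0 else -1.0) for i, g in enumerate(de_lnc)}
    de_lfc = {g: de_sign[g] * config.de_lfc for g in de_lnc}

    # disjoint signal pairs among the first DE lncRNAs; member genes share
    # their baseline mean and planted shift so the pair indicator stays near
    # the middle of the occupancy band
    betas = np.linspace(config.beta_low, config.beta_high, max(config.n_signal_pairs, 1))
    signal_pairs: list[tuple[str, str, float]] = []
    pair_mu: dict[str, float] = {}
    for k in range(config.n_signal_pairs):
        a, b = de_lnc[2 * k], de_lnc[2 * k + 1]
        beta = float(betas[k] * (1.0 if k % 2 == 0 else -1.0))
        signal_pairs.append((a, b, beta))
        mu = float(r_expr.uniform(3.0, 8.0))
        pair_mu[a] = pair_mu[b] = mu
        de_lfc[b] = de_lfc[a]  # same shift keeps the tumor indicator balanced

    # variance of the planted group shift seen across the pooled cohort
    p_tum = config.n_tumor / n_s
    v_shift_de = p_tum * (1.0 - p_tum) * config.de_lfc**2
    rho2 = config.rho_target**2

    Z = np.empty((config.n_lncrna, n_s))
    for i, g in enumerate(lnc_ids):
        mu = pair_mu.get(g, float(r_expr.uniform(3.0, 8.0)))
        noise = r_expr.normal(0.0, _LNC_NOISE_SD, size=n_s)
        if g in set(corr_lnc):
            partner = i % config.n_immune_gene
            v_extra = _LNC_NOISE_SD**2 + (v_shift_de if g in de_lfc else 0.0)
            slope = math.sqrt(rho2 / (1.0 - rho2) * v_extra) / _IMMUNE_SD
            sign = 1.0 if i % 2 == 0 else -1.0
            trend = sign * slope * (Z_imm[partner] - imm_mu[partner])
        else:
            trend = r_expr.normal(0.0, 1.0, size=n_s)  # idiosyncratic spread
        shift = de_lfc.get(g, 0.0) * is_tumor
        Z[i] = mu + trend + shift + noise

    Z_pcg = r_expr.uniform(3.0, 8.0, size=config.n_noise_gene)[:, None] + r_expr.normal(
        0.0, 1.0, size=(config.n_noise_gene, n_s)
    )
    # x = 2^z - 1 so that log2(x + 1) recovers z exactly and planted log2FC /
    # correlations hold on the scale the screens use; the clip at zero only
    # touches the far-left tail (z < 0)
    values = np.maximum(np.power(2.0, np.vstack([Z, Z_imm, Z_pcg])) - 1.0, 0.0)
    gene_ids = lnc_ids + imm_ids + pcg_ids
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=samples),
        sample_group={s: ("tumor" if s in set(tumor_ids) else "normal") for s in samples},
    )

    catalog = GeneCatalog(
        records={
            **{g: (g, "lncRNA") for g in lnc_ids},
            **{g: (g, "protein_coding") for g in imm_ids + pcg_ids},
        }
    )
    immune_genes = GeneList(symbols=frozenset(imm_ids))

    # --- survival from the planted pair indicators ---------------------------
    tumor_vals = expr.values[tumor_ids]
    risk = np.zeros(config.n_tumor)
    for a, b, beta in signal_pairs:
        indicator = (tumor_vals.loc[a].to_numpy() > tumor_vals.loc[b].to_numpy()).astype(float)
        risk += beta * indicator
    true_risk = dict(zip(tumor_ids, risk))
    eta = risk - risk.mean() if config.n_signal_pairs else risk

    lam = config.baseline_hazard
    event_t = r_surv.exponential(1.0, size=config.n_tumor) / (lam * np.exp(eta))
    c_rate = censoring_calibration(lam, config.censor_rate)
    censor_t = r_surv.exponential(1.0 / c_rate, size=config.n_tumor)
    os_time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)

    clinical = [
        ClinicalRecord(
            patient_id=tumor_ids[i],
            os_time_days=float(np.round(os_time[i], 1)),
            event=int(event[i]),
            age=float(np.round(r_clin.normal(65.0, 10.0))),
            sex="male" if r_clin.random() < 0.465 else "female",
            stage=str(_draw(r_clin, _STAGE_P, 1)[0]),
            t_cat=str(_draw(r_clin, _T_P, 1)[0]),
            n_cat=str(_draw(r_clin, _N_P, 1)[0]),
            m_cat=str(_draw(r_clin, _M_P, 1)[0]),
        )
        for i in range(config.n_tumor)
    ]

    # --- infiltration and score tables tied to the true risk -----------------
    risk_std = (risk - risk.mean()) / (risk.std() if risk.std() > 0 else 1.0)
    noise = lambda: r_infil.normal(0.0, 1.0, size=config.n_tumor)  # noqa: E731
    infiltration = pd.DataFrame(
        {
            "CD8_T_cell.synthetic": -risk_std + noise(),
            "Monocyte.synthetic": -0.5 * risk_std + noise(),
            "M0_macrophage.synthetic": risk_std + noise(),
            "B_cell.synthetic": noise(),
            "NK_cell.synthetic": noise(),
            "Neutrophil.synthetic": noise(),
        },
        index=tumor_ids,
    )
    scores = pd.DataFrame(
        {
            "IPS_CTLA4_blocker": -0.5 * risk_std + noise(),
            "IC50_sensitive_drug": -0.8 * risk_std + noise(),
            "IC50_resistant_drug": 0.8 * risk_std + noise(),
            "IC50_null_drug": noise(),
        },
        index=tumor_ids,
    )

    truth = GroundTruth(
        corr_lncrnas=set(corr_lnc),
        de_lncrnas=de_lfc,
        signal_pairs=signal_pairs,
        true_risk=true_risk,
    )
    logger.info(
        "synthetic cohort: %d tumor + %d normal samples, %d genes, %d signal pairs, "
        "%.0f%% events", config.n_tumor, config.n_normal, len(gene_ids),
        config.n_signal_pairs, 100.0 * event.mean(),
    )
    return Cohort(
        expression=expr,
        catalog=catalog,
        clinical=clinical,
        infiltration=infiltration,
        scores=scores,
        immune_genes=immune_genes,
        truth=truth,
        config=config,
    )


def true_pair_indicators(cohort: Cohort) -> pd.DataFrame:
    """0/1 indicators of the planted signal pairs (tumor samples x pairs)."""
    tumor_ids = [r.patient_id for r in cohort.clinical]
    vals = cohort.expression.values[tumor_ids]
    cols = {}
    for a, b, _ in cohort.truth.signal_pairs:
        cols[f"{a}|{b}"] = (vals.loc[a].to_numpy() > vals.loc[b].to_numpy()).astype(int)
    return pd.DataFrame(cols, index=tumor_ids)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, str]:
    """Write all inputs in the file dialects the readers accept; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "catalog": outdir / "catalog.tsv",
        "clinical": outdir / "clinical.tsv",
        "immune_genes": outdir / "immune_genes.txt",
        "infiltration": outdir / "infiltration.tsv",
        "scores": outdir / "scores.tsv",
    }
    write_expression_matrix(cohort.expression, paths["expression"])
    write_group_map(cohort.expression, paths["groups"])
    write_gene_catalog(cohort.catalog, paths["catalog"])
    write_clinical_table(cohort.clinical, paths["clinical"])
    write_gene_list(cohort.immune_genes, paths["immune_genes"])
    write_score_table(cohort.infiltration, paths["infiltration"])
    write_score_table(cohort.scores, paths["scores"])
    return {k: str(v) for k, v in paths.items()}
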