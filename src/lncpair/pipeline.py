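"""End-to-end orchestration: inputs -> screen -> pairs -> signature -> evaluation.

``run_pipeline`` executes the full funnel the pair-signature method defines —
immune-correlation screen, differential expression, cyclic pairing with the
occupancy filter, univariate Cox, LASSO-Cox, multivariate Cox, risk scoring,
ROC/Youden stratification, Kaplan-Meier and log-rank comparison, independence
analysis and clinical/immune/drug associations — logging every stage's
input/output counts and writing a reproducible manifest plus TSV reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, immune, io, pairs, screen, signature, synthetic

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Flat key-value pipeline configuration.

    Exactly one input mode must be active: either ``synthetic=True`` (with the
    cohort block parameters) or paths to the real input files.
    """

    # real-input paths
    expression: str | None = None
    groups: str | None = None
    catalog: str | None = None
    clinical: str | None = None
    immune_genes: str | None = None
    infiltration: str | None = None
    scores: str | None = None
    # synthetic mode
    synthetic: bool = False
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
    baseline_hazard: float = 0.001
    censor_rate: float = 0.4
    # thresholds (defaults are the published pipeline's)
    r_min: float = 0.5
    p_corr: float = 0.001
    lfc_min: float = 2.0
    de_alpha: float = 0.05
    occupancy_low: float = 0.20
    occupancy_high: float = 0.80
    uni_alpha: float = 0.05
    lasso_folds: int = 10
    lambda_rule: str = "min"
    roc_horizons: tuple[float, ...] = evaluation.HORIZONS_DAYS
    group_alpha: float = 0.05
    min_followup_days: int = 30
    ici_genes: tuple[str, ...] = ()
    # run control
    seed: int = 0
    outdir: str = "lncpair_out"

    def __post_init__(self) -> None:
        real = self.expression is not None
        if real == self.synthetic:
            raise ValueError("config must specify exactly one of: synthetic mode, real input paths")
        if real and not all([self.groups, self.catalog, self.clinical, self.immune_genes]):
            raise ValueError("real-input mode requires expression, groups, catalog, "
                             "clinical and immune_genes paths")
        if not 0 <= self.occupancy_low < self.occupancy_high <= 1:
            raise ValueError("invalid occupancy band")
        for name in ("r_min", "p_corr", "de_alpha", "uni_alpha", "group_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("roc_horizons", "ici_genes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def cohort_config(self) -> synthetic.CohortConfig:
        return synthetic.CohortConfig(
            n_tumor=self.n_tumor,
            n_normal=self.n_normal,
            n_lncrna=self.n_lncrna,
            n_immune_gene=self.n_immune_gene,
            n_noise_gene=self.n_noise_gene,
            n_corr_lncrna=self.n_corr_lncrna,
            n_de_lncrna=self.n_de_lncrna,
            n_signal_pairs=self.n_signal_pairs,
            rho_target=self.rho_target,
            de_lfc=self.de_lfc,
            baseline_hazard=self.baseline_hazard,
            censor_rate=self.censor_rate,
            seed=self.seed,
        )


class StageError(RuntimeError):
    """A pipeline stage failed or produced an empty funnel."""


def _require(condition: bool, stage: str, message: str) -> None:
    if not condition:
        raise StageError(f"stage '{stage}': {message}")


def _load_inputs(config: PipelineConfig):
    if config.synthetic:
        cohort = synthetic.generate_cohort(config.cohort_config())
        clinical = [
            r for r in cohort.clinical
            if r.os_time_days >= config.min_followup_days
        ]
        return cohort.expression, cohort.catalog, clinical, cohort.immune_genes, \
            cohort.infiltration, cohort.scores
    expr = io.read_expression_matrix(config.expression, config.groups)
    catalog = io.parse_gene_catalog(config.catalog)
    clinical = io.read_clinical_table(config.clinical, config.min_followup_days)
    immune_genes = io.read_gene_list(config.immune_genes)
    infiltration = immune.read_score_table(config.infiltration) if config.infiltration else None
    scores = immune.read_score_table(config.scores) if config.scores else None
    return expr, catalog, clinical, immune_genes, infiltration, scores


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}, "files": {}}

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        logger.info("stage %-22s %s", stage, counts)

    def save(name: str, df: pd.DataFrame, **kwargs) -> None:
        fname = f"{name}.tsv"
        df.to_csv(outdir / fname, sep="\t", **kwargs)
        manifest["files"][name] = fname

    # ---- inputs -----------------------------------------------------------
    expr, catalog, clinical, immune_genes, infiltration, scores = _load_inputs(config)
    _require(len(clinical) > 0, "inputs", "no patients after the clinical filter")
    record(
        "inputs",
        n_genes=len(expr.gene_ids),
        n_tumor=len(expr.samples_in_group("tumor")),
        n_normal=len(expr.samples_in_group("normal")),
        n_patients=len(clinical),
    )

    # ---- immune-correlation screen ---------------------------------------
    lncrnas = catalog.genes_of_biotype("lncRNA")
    immune_ids = catalog.ids_for_symbols(immune_genes)
    irlnc, hits = screen.pearson_screen(
        expr, immune_ids, lncrnas, r_min=config.r_min, p_max=config.p_corr
    )
    _require(len(irlnc) > 0, "pearson_screen", "no immune-related lncRNAs found")
    save("correlation_hits", screen.hits_to_frame(hits), index=False)
    record("pearson_screen", n_lncrna=len(lncrnas), n_irlncrna=len(irlnc))

    # ---- differential expression ------------------------------------------
    de_results = screen.differential_expression(
        expr, lfc_min=config.lfc_min, alpha=config.de_alpha, genes=sorted(irlnc)
    )
    de_genes = [r.gene_id for r in de_results if r.is_de]
    _require(len(de_genes) >= 2, "differential_expression",
             f"need >= 2 DE lncRNAs to form pairs, got {len(de_genes)}")
    save("de_table", screen.de_to_frame(de_results), index=False)
    record("differential_expression", n_tested=len(de_results), n_de=len(de_genes))

    # ---- pair matrix on patients with clinical follow-up -------------------
    patients = [r.patient_id for r in clinical if r.patient_id in set(expr.sample_ids)]
    _require(len(patients) > 0, "pairing", "no overlap between clinical and expression samples")
    clin_df = io.clinical_to_frame(clinical).loc[patients]
    tumor_expr = io.ExpressionMatrix(
        values=expr.values[patients],
        sample_group={s: expr.sample_group[s] for s in patients},
    )
    pm_all = pairs.build_pair_matrix(tumor_expr, de_genes)
    pm = pairs.filter_pairs_by_occupancy(pm_all, config.occupancy_low, config.occupancy_high)
    _require(pm.n_pairs > 0, "occupancy_filter", "no pairs left in the occupancy band")
    record("pairing", n_pairs_total=pm_all.n_pairs, n_pairs_valid=pm.n_pairs)

    times = clin_df["os_time_days"].to_numpy(dtype=float)
    events = clin_df["event"].to_numpy(dtype=int)

    # ---- survival-pair selection ------------------------------------------
    surv_names, uni_results = signature.univariate_screen(pm, times, events, alpha=config.uni_alpha)
    _require(len(surv_names) >= 2, "univariate_screen",
             f"need >= 2 survival-related pairs for LASSO, got {len(surv_names)}")
    save("univariate_cox", signature.cox_results_to_frame(uni_results), index=False)
    record("univariate_screen", n_pairs_survival=len(surv_names))

    pm_surv = pm.select_named(surv_names)
    lasso = signature.fit_lasso_cox(
        pm_surv.to_frame().T, times, events,
        n_folds=config.lasso_folds, seed=config.seed, lambda_rule=config.lambda_rule,
    )
    record("lasso_cox", n_pairs_selected=len(lasso.selected), alpha_opt=float(lasso.alpha_opt))

    model, multi_results = signature.build_signature(lasso.selected, pm, times, events)
    sig_frame = signature.cox_results_to_frame(multi_results).rename(
        columns={"covariate": "lncRNA_pair"}
    )
    save("signature", sig_frame, index=False)
    record("signature", n_signature_terms=len(model.terms))

    profile = signature.compute_risk_scores(pm, model)

    # ---- evaluation --------------------------------------------------------
    rocs = {
        float(h): evaluation.time_dependent_roc(profile.scores.loc[patients], times, events, h)
        for h in config.roc_horizons
    }
    aucs = {str(int(h)): r.auc for h, r in rocs.items()}
    cutoff, youden = evaluation.youden_cutoff(rocs[float(config.roc_horizons[0])])
    profile = evaluation.stratify(profile, cutoff)
    save(
        "risk_profile",
        pd.DataFrame({"risk_score": profile.scores, "group": profile.group}),
        index_label="patient_id",
    )
    groups = profile.group.loc[patients].to_numpy()
    n_high = int((groups == "high").sum())
    n_low = int((groups == "low").sum())
    logrank = None
    if n_high and n_low:
        logrank = evaluation.log_rank_test(times, events, groups)
    record(
        "evaluation",
        aucs=aucs, cutoff=float(cutoff), youden_index=float(youden),
        n_high=n_high, n_low=n_low,
        logrank_p=(float(logrank.p) if logrank else None),
    )
    save(
        "roc_auc",
        pd.DataFrame(
            {"horizon_days": [h for h in rocs], "auc": [r.auc for r in rocs.values()]}
        ),
        index=False,
    )

    # stage-subgroup survival comparison ({I,II} vs {III,IV})
    subgroup_p = {}
    stage_bin = clin_df["stage"].map(
        {"I": "early", "II": "early", "III": "late", "IV": "late"}
    )
    for label in ("early", "late"):
        sel = (stage_bin == label).to_numpy()
        g = groups[sel]
        if len(np.unique(g)) == 2 and events[sel].sum() > 0:
            subgroup_p[label] = float(evaluation.log_rank_test(times[sel], events[sel], g).p)
    record("subgroup_km", **{f"logrank_p_{k}": v for k, v in subgroup_p.items()})

    # independence of the risk score from clinical covariates
    uni_ind, multi_ind = evaluation.independence_analysis(profile, clin_df)
    save("independence_univariate", signature.cox_results_to_frame(uni_ind), index=False)
    save("independence_multivariate", signature.cox_results_to_frame(multi_ind), index=False)
    risk_multi = next((r for r in multi_ind if r.covariate == "risk_score"), None)
    record("independence", risk_score_multivariate_p=(risk_multi.p if risk_multi else None))

    # clinical associations
    chi_rows, wil_rows = [], []
    clin_df = clin_df.assign(status=np.where(events == 1, "dead", "alive"))
    for cov, drop in [("sex", ()), ("stage", ("unknown",)), ("t", ("Tx",)),
                      ("n", ("Nx",)), ("m", ("Mx",)), ("status", ())]:
        try:
            res = evaluation.chi_square_association(
                profile.group.loc[patients], clin_df[cov], drop_labels=drop + ("unknown", "nan")
            )
            chi_rows.append((cov, res.statistic, res.p))
        except ValueError as exc:
            logger.warning("chi-square on %s skipped: %s", cov, exc)
    for cov, mapping in [
        ("stage", {"I": "early", "II": "early", "III": "late", "IV": "late"}),
        ("t", {"T1": "low", "T2": "low", "T3": "high", "T4": "high"}),
        ("n", {"N0": "neg", "N1": "pos", "N2": "pos", "N3": "pos"}),
        ("m", {"M0": "neg", "M1": "pos"}),
    ]:
        binned = clin_df[cov].map(mapping)
        ok = binned.notna().to_numpy()
        if ok.sum() and len(pd.unique(binned[ok])) == 2:
            res = evaluation.wilcoxon_rank_sum(
                profile.scores.loc[patients].to_numpy()[ok], binned[ok].to_numpy()
            )
            wil_rows.append((cov, res.statistic, res.p))
    save("clinical_chi_square", pd.DataFrame(chi_rows, columns=["covariate", "chi2", "p"]), index=False)
    save("clinical_wilcoxon", pd.DataFrame(wil_rows, columns=["covariate", "U", "p"]), index=False)
    record("clinical_association", n_chi_square=len(chi_rows), n_wilcoxon=len(wil_rows))

    # immune and drug associations
    if infiltration is not None:
        infil_assoc = immune.spearman_risk_vs_infiltration(profile, infiltration, alpha=config.group_alpha)
        save("infiltration_spearman", infil_assoc, index=False)
        record("immune_infiltration",
               n_columns=len(infil_assoc), n_significant=int(infil_assoc["significant"].sum()))
    for gene in config.ici_genes:
        res = immune.compare_gene_by_group(expr, gene, profile)
        manifest["stages"].setdefault("ici_genes", {})[gene] = float(res.p)
    if scores is not None:
        drug_assoc = immune.compare_scores_by_group(scores, profile)
        save("score_associations", drug_assoc, index=False)
        record("drug_scores", n_columns=len(drug_assoc),
               n_significant=int((drug_assoc["p"] < config.group_alpha).sum()))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["files"]["manifest"] = "manifest.json"
    return manifest
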