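# lncpair

Prognostic signatures built from **within-sample rank comparisons of
immune-related lncRNA pairs**, for survival analysis of bulk tumor RNA-seq
cohorts (the motivating application is TCGA-LUAD).

Most expression-based prognostic signatures depend on absolute, normalized
expression values, which makes them fragile across platforms and batches.
The pair approach sidesteps this: for two lncRNAs A and B, the feature

```
(A|B)_s = 1  if  expr(A, s) > expr(B, s)   else  0
```

depends only on the within-sample ordering, so it is invariant to any
strictly monotone normalization. The workflow is:

1. **Immune-related lncRNA screen** — keep lncRNAs with Pearson |r| > 0.5
   (p < 0.001, on log2(x+1)) against at least one immune-related gene.
2. **Differential expression** — tumor vs normal, empirical-Bayes moderated
   t; keep |log2FC| > 2 with BH-adjusted p < 0.05.
3. **Cyclic single pairing** — all C(k, 2) pairs into a 0-or-1 matrix;
   discard pairs whose ones-fraction falls outside [20%, 80%].
4. **Selection** — univariate Cox (Wald p < 0.05) → LASSO-Cox (penalty by
   10-fold cross-validated partial-likelihood deviance) → one joint
   multivariate Cox (Efron ties).
5. **Risk score** — `riskscore = Σ_i (A|B)_i · β_i` with the multivariate
   coefficients β_i; the cutoff is the maximum Youden index
   (sensitivity + specificity − 1) on the 1-year time-dependent ROC
   (Heagerty–Lumley–Pepe cumulative/dynamic estimator, KM weighting).
6. **Evaluation** — Kaplan–Meier and log-rank for high vs low risk,
   univariate/multivariate Cox independence analysis, chi-square and
   Wilcoxon clinical associations, Spearman correlation with
   immune-infiltration scores and Wilcoxon comparisons of IPS / drug-IC50
   tables.

A synthetic-cohort generator (`lncpair.synthetic`) produces tumor/normal
cohorts with planted immune correlations, differential expression, and
pair-driven proportional-hazards survival, with full ground truth — so every
stage of the pipeline is testable against known answers.

## Worked example

Run the whole pipeline on the default synthetic cohort (400 tumors, 50
normals, 8 planted signal pairs, ~40% censoring):

```python
from lncpair import PipelineConfig, run_pipeline

manifest = run_pipeline(PipelineConfig(synthetic=True, seed=1, outdir="out"))
for stage, counts in manifest["stages"].items():
    print(stage, counts)
```

which prints (abridged):

```
inputs                   {'n_genes': 330, 'n_tumor': 400, 'n_normal': 50, 'n_patients': 380}
pearson_screen           {'n_lncrna': 200, 'n_irlncrna': 60}
differential_expression  {'n_tested': 60, 'n_de': 40}
pairing                  {'n_pairs_total': 780, 'n_pairs_valid': 252}
univariate_screen        {'n_pairs_survival': 42}
lasso_cox                {'n_pairs_selected': 22, ...}
signature                {'n_signature_terms': 22}
evaluation               {'aucs': {'365': 0.706, '1095': 0.808, '1825': 0.855},
                          'cutoff': -0.147, 'n_high': 102, 'n_low': 278,
                          'logrank_p': 1.4e-18}
```

Reading the funnel: all 60 planted immune-correlated lncRNAs are recovered,
40 pass the differential-expression filter, their 780 pairs shrink to 252
informative ones, and the selected signature separates survival with 1-, 3-
and 5-year AUCs of 0.71/0.81/0.86 and a log-rank p ≈ 1e−18 between the
Youden-split risk groups. `out/` contains the signature table (pair,
coefficient, HR, 95% CI, p), the per-patient risk profile, and all
evaluation/association TSVs plus `manifest.json`.

The same analysis is scriptable from the shell:

```bash
lncpair simulate --seed 1 --outdir cohort/     # write synthetic inputs
lncpair run --config pipeline.yaml             # full run from a YAML config
lncpair report --manifest out/manifest.json    # reprint the stage funnel
```

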