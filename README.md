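# prognomics

Integration of clinical covariates with multi-omics data for cancer
prognosis, built as a tested, reusable pipeline and exercised end to
end on synthetic cohorts with known ground truth.

## The problem

AJCC T/N/M stage and age are the workhorse covariates of colon-cancer
prognosis, but molecular layers — gene expression (FPKM), DNA
methylation (beta values), miRNA expression (RPM) — carry additional
structure. The obstacle to simply adding them to a survival model is
dimensionality: thousands of features against a few hundred patients.
This package implements a dimension-reduction-by-clustering strategy:

1. **Per-layer preparation** — drop features with more than 5% NA/zero
   entries, keep the union of the top 25% by coefficient of variation
   and a prior-knowledge list, and (for methylation) average CpG probes
   to gene level with chrX/Y excluded.
2. **Prognosis-driven clustering** — hierarchically cluster patients
   per layer over a grid of 7 distance metrics × 8 linkage criteria ×
   cluster counts 2–11 (every cluster must hold ≥ 10 patients), and
   keep the combination whose dummy-coded cluster label yields the best
   bias-corrected Harrell's C in a Cox model (optionally alongside the
   clinical covariates of the target model).
3. **Cluster-of-clusters (C-o-C)** — one-hot the per-layer labels into
   a binary patients × clusters matrix and run the same search again to
   obtain one integrated omics covariate.
4. **Multi-covariate Cox PH model** —

   h(t | z) = h₀(t) · exp( Σ βₙzₙ + Σ βₘzₘ )

   with zₙ the dummy-coded clinical factors (T/N/M stage, quartile age
   bins) and zₘ the cluster-label factors; fit by Newton iterations on
   the Efron partial likelihood.
5. **Discrimination comparison** — per model: apparent and
   bootstrap-optimism-corrected Harrell's C (500 replicates by
   default), 2/3/5-year Uno's IPCW C under repeated event-stratified
   5-fold cross-validation, the Grambsch–Therneau PH-assumption test,
   and likelihood-ratio / score / Wald tests; models are compared with
   paired Wilcoxon signed-rank tests and nested-model LRTs, all under
   one master seed so every model consumes identical resample indices.

The canonical comparison covers 12 covariate combinations
(C, G, M, m, CG, CM, Cm, CGM, CGm, CMm, CGMm, CA — C clinical,
G/M/m the three omics layers, A the C-o-C label) plus a
leave-one-covariate-out ablation of the full model.

Because no public cohort ships with this package, `prognomics.simcohort`
generates synthetic cohorts with planted latent prognostic subtypes
expressed in all three layers, realistic measurement scales, TNM/age
covariates, and right-censored survival from a known Cox model — so
every stage of the pipeline can be tested against ground truth.

## Worked example

```python
from prognomics.workflows import run_integration_study

study = run_integration_study(seed=1)   # n=400, three informative layers
for code in ("C", "CG", "CGM", "CGMm"):
    ev = study.evaluations[code]
    print(code, round(ev.bootstrap.corrected_mean, 4),
          {int(t): round(r.mean, 4) for t, r in ev.cv.items()})
```

prints (seed 1):

```
C 0.6687 {730: 0.6619, 1095: 0.6569, 1825: 0.6458}
CG 0.6936 {730: 0.6864, 1095: 0.6824, 1825: 0.6746}
CGM 0.6968 {730: 0.6887, 1095: 0.6887, 1825: 0.6805}
CGMm 0.7025 {730: 0.6916, 1095: 0.6911, 1825: 0.6848}
```

The first column is the bias-corrected Harrell's C (mean over 200
bootstrap replicates), the dict the mean cross-validated Uno's C at the
2/3/5-year horizons (730/1095/1825 days). Adding omics cluster
covariates to the clinical model raises discrimination monotonically;
the full model beats the clinical-only model by ≈ 0.03 at every
horizon, with paired Wilcoxon p ≈ 4e-18 over the 100 shared
cross-validation iterations (`study.comparison` holds the table).

The command-line interface wraps the same pipeline for file-based runs:

```bash
prognomics simulate --config config.yaml --outdir cohort/
prognomics run      --config config.yaml --outdir results/
prognomics metrics  --risk risk.tsv --survival clinical.tsv --variant uno --tau 1095
```

`run` writes per-model evaluation JSONs, the candidate tables and
winning labels of every clustering search, a model-comparison table and
a run manifest; re-running with the same master seed reproduces every
output byte for byte.

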