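# Methods

This note documents the statistical machinery, the synthetic-data
generator, and the numerical and design choices behind `prognomics`.

## Survival model and fitting

The core model is the Cox proportional-hazards model
h(t | z) = h₀(t)·exp(βᵀz) over a dummy-coded design holding the
clinical factors (T stage with reference T1, N stage with reference
N0, M stage with reference M0, age in four quartile-based left-closed
bins with the youngest bin as reference) and one factor per selected
cluster-label set (cluster 1 as reference). Fitting maximises the
Efron-tie partial likelihood by Newton iterations with step-halving;
convergence is declared when the log-likelihood changes by less than
1e-9 (at most 50 iterations). Efron rather than Breslow tie handling
because follow-up is recorded at day resolution, where tied event
times are routine, and Efron is the de-facto default of the R survival
ecosystem. Standard errors come from the inverse observed information;
hazard-ratio CIs use exp(β ± 1.96·se). Non-convergence, singular
information, constant columns and monotone-likelihood divergence
(|β| > 50) are reported through a `converged=False` flag rather than
an exception, because the clustering grid search must treat a failing
candidate as infeasible and move on. The fit retains the score vector
statistic at β = 0 (score test), the null and full log-likelihoods
(likelihood-ratio test) and the information matrix (Wald test); with
untied times the score test coincides exactly with the two-group
log-rank statistic, which the test suite asserts against a brute-force
implementation.

Age bins are recomputed from the data as empirical quartiles
(left-closed, right-open; the oldest bin closed). User-supplied
cutpoints override them.

## Discrimination metrics

**Harrell's C** is computed over usable pairs (i with an event at tᵢ,
j observed beyond tᵢ), crediting 1 for a concordant risk ordering and
0.5 for tied risks; pairs of tied event times are unusable. The
implementation is exact — the suite checks it against an exhaustive
double-loop oracle on a thousand small instances including ties and
censoring.

**Uno's C** is the IPCW-weighted, horizon-truncated variant: pairs with
tᵢ < tⱼ and tᵢ < τ are weighted by Ĝ(tᵢ⁻)⁻², where Ĝ is the
Kaplan–Meier estimate of the censoring survivor function (left limit,
i.e. the product over censoring times strictly before tᵢ). Default
horizons are 2/3/5 years = 730/1095/1825 days. If Ĝ reaches zero
before a contributing event time the horizon exceeds the censoring
support and the function raises. Under zero censoring and τ beyond the
last time, Uno's C reduces to Harrell's C exactly (asserted to 1e-12).

**Optimism correction.** Apparent C is optimistic because the model is
scored on its own training data. Per bootstrap replicate b: resample
patients with replacement, refit, and form
corrected_b = apparent − (c_boot − c_orig), where c_boot scores the
replicate's model on its own resample and c_orig scores it on the
original cohort. The mean of the B per-replicate corrected values (the
reported bias-corrected C) equals the classical
apparent-minus-mean-optimism estimate; the full distribution is kept
for paired model comparisons. Replicates whose refit fails (e.g. a
rare stage level absent from the resample) are redrawn and counted;
more than 20% failures aborts. B defaults to 500 for final model
evaluation and 100 for grid-search screening.

**Cross-validated Uno's C.** Each iteration draws an event-stratified
5-fold partition, fits on four folds, pools the out-of-fold linear
predictors and computes one Uno's C per horizon with Ĝ estimated on
the full sample (so the pooled predictors share one weight function; a
`per_fold_G` switch estimates Ĝ per training fold instead and averages
fold-level values). Iterations with a failing fold fit are redrawn and
logged. Default 500 iterations; the bundled studies use 100.

**PH assumption.** The Grambsch–Therneau test on Efron Schoenfeld
residuals against the KM-transformed time scale g(t) = 1 − Ŝ(t), in
the classical approximation Var(Σ g'ₖ sₖ) ≈ (Σ g'ₖ²)·I/d: global
χ² = d/(Σ g'²) · uᵀI⁻¹u on p degrees of freedom, with the analogous
per-covariate statistic on the scaled residuals. Under PH-true
simulations the global test rejects at 4–5% at nominal α = 0.05, and
per-covariate statistics agree with an independent implementation to
four decimals.

**Paired comparisons.** All models evaluated under one master seed
consume identical bootstrap index streams and identical fold
partitions (seeds derive from (master seed, stage tag) only — never
from the model), so per-iteration C distributions are paired and the
two-sided Wilcoxon signed-rank test applies: exact distribution for
≤ 25 informative pairs without zeros or rank ties, normal approximation
with continuity correction otherwise, zeros handled by Pratt's method,
all-zero differences reported as p = 1. Nested models additionally get
a likelihood-ratio test on the column-count difference.

## Clustering and model selection

Distances are the seven classical metrics (euclidean, maximum,
manhattan, canberra, binary, minkowski, correlation), computed via
scipy. Conventions that needed fixing: canberra terms with both
coordinates zero contribute 0 (no rescaling of the remaining sum);
binary is the Jaccard distance on the nonzero pattern; correlation is
1 − Pearson r, an error for zero-variance rows; minkowski defaults to
p = 3 (exposed in the grid spec), since p = 2 would duplicate
euclidean.

Agglomeration is a direct Lance–Williams implementation of the eight
linkage criteria (ward_d, ward_d2, single, complete, average,
mcquitty, median, centroid). ward_d applies the Ward update to the
distances as supplied; ward_d2, median and centroid operate on squared
dissimilarities with square-rooted merge heights. Ties in the minimal
inter-cluster distance break toward the smallest pair of cluster ids
in creation order, making results deterministic and
permutation-invariant up to label renumbering. Trees are cut by merge
count, not height, so the height inversions median/centroid can
produce are harmless; labels are renumbered 1..k by first sample
appearance. The implementation is validated against a literal O(n³)
re-implementation across all 8 × 7 linkage-metric combinations, and
(for the monotone linkages) against scipy's `linkage`.

The **grid search** clusters each prepared layer for every
(distance, linkage, k) combination with k in 2..11, marks a candidate
infeasible when any cluster holds fewer than 10 patients or the Cox
fit on its dummy-coded label fails, and scores feasible candidates by
the bias-corrected Harrell's C of a Cox model holding the label plus
optional companion covariates. Both selection regimes are first-class:
an empty companion set reproduces the literal single-covariate
selection, while passing the clinical design selects labels in the
covariate context of the target model. Every candidate is scored with
the same bootstrap index stream, so the winner is independent of
evaluation order; ties break toward fewer clusters, then grid order.
The **cluster-of-clusters** step one-hot codes the selected per-layer
labels (one column per layer-cluster pair; each row sums to the number
of layers) and runs the identical search on the binary matrix.

A property of this selection score worth knowing: because the optimism
bootstrap only partially penalises extra dummy columns, linkages that
refine a balanced partition into ever-smaller feasible pieces (the
Ward family in particular) let the score drift toward larger k. With
outlier-peeling linkages (average, mcquitty) cuts beyond the true
structure quickly produce sub-10-patient clusters that the feasibility
rule rejects, and the search recovers planted structure cleanly; the
bundled desk-scale studies therefore default to a restricted
euclidean/manhattan × average/mcquitty grid.

Before distance computation the pipeline log-transforms (log1p) the
count-derived FPKM/RPM scales — the standard variance-stabilisation
for expression-like data, without which large-valued features dominate
every metric — and mean-imputes any residual NAs. Per-feature
z-scoring is available as an opt-in grid switch (default off).

## Feature preparation

The quality filter removes features whose combined NA-and-exact-zero
fraction strictly exceeds 5% ("more than" — the boundary is kept); on
the beta scale only NA counts, since a zero beta value is a legitimate
measurement. Selection keeps the union of the top ceil(0.25·p)
features by coefficient of variation (sample sd over non-NA entries
divided by their mean; undefined-at-zero-mean ranks last; ties break
lexicographically by feature id) and a prior-knowledge list; prior
features missing from the matrix warn rather than error, and the
filter runs before the union, so a prior feature that fails quality
control stays excluded. Probe-to-gene aggregation drops chrX/Y probes
and probes with more than 5% NA, then averages each gene's remaining
probes per sample over non-NA values; the probe→(gene, chromosome) map
is a user-supplied three-column table, keeping genome annotation
outside the package.

## The synthetic cohort generator

The emulated study is a re-analysis of an observational cohort, so the
generator is a stand-in designed to exhibit the structure the pipeline
assumes, not a model fitted to data; its defaults mirror the cohort's
published summary statistics.

* **Latent subtypes.** Each patient draws one of K_true subtypes
  (default 3, equal proportions). Informative features get a mean
  shift of `effect_size` (in noise-sd units) in the subtype they mark:
  pattern "cyclic" spreads marked subtypes across features within
  every layer; pattern "marker" dedicates each layer's informative
  features to one layer-specific subtype, giving the three layers
  complementary views of the shared structure. By default 20% of each
  layer's features are informative — subtype signatures span a
  sizeable minority of the features that survive variability-based
  selection.
* **Scales.** Expression and miRNA are normal on the log scale and
  exponentiated (nonnegative, right-skewed, FPKM/RPM-like; per-feature
  baseline log-mean ~ N(1.5, 1), unit noise sd). Methylation draws
  from Beta distributions with concentration 20 around per-feature
  baseline means ~ U(0.2, 0.8), subtype shifts expressed in the
  feature's own Beta sd; values therefore lie strictly in (0, 1).
  Sequencing depth is not modelled.
* **Clinical covariates** are sampled from category frequencies that
  mimic the emulated cohort (T: 2.9/18.0/73.8/3.5/1.7%, N:
  61.3/10.2/11.6/9.3/7.6%, M: 84.9/15.1%; age ~ N(66, 13) clipped to
  [31, 90]), so rare categories (T4b) are realistically sparse.
* **Survival.** The log-hazard is a linear combination of ordinal
  stage codes and standardised age (default per-step log-HRs 0.25 /
  0.35 / 1.6 / 0.4) plus the subtype log-HR (default (0, 0.7, 1.4)),
  centred so the baseline keeps its reference-scale meaning. Event
  times come from an exponential (or Weibull) baseline with scale
  1150 days, placing the reference median near 26 months. Censoring is
  independent uniform on (0, c_max), with c_max calibrated by
  bisection so the expected censoring fraction hits `censor_rate`
  (default 0.794). Observed times are rounded to whole days (min 1),
  producing realistic ties.
* **Limitations.** Uniform censoring couples the censoring fraction to
  the follow-up horizon: at 79% censoring, c_max falls near one year
  and the 2/3/5-year IPCW horizons lose censoring support. The
  horizon-based studies below therefore use a moderate censoring
  fraction (0.4). Real cohorts also carry administrative censoring,
  covariate-dependent missingness, batch structure and correlated
  features, none of which are modelled — passing tests demonstrate
  correctness of the machinery under the assumed structure, not
  performance on real data. Independent-per-layer subtype labels are
  available via `shared_subtypes=False`.

Missingness injection replaces exactly round(rate · n_entries)
uniformly chosen entries with NA (or 0) and returns the positions, so
filter behaviour is testable bit-for-bit.

## Bundled studies and problem sizes

`prognomics.workflows` packages two desk-scale studies, sized to run
in about a minute each on one CPU:

* **Cluster recovery** — n = 300, three layers (150/100/60 features),
  K_true = 3, effect size 2, 60% censoring; search grid
  euclidean/manhattan × average/mcquitty, k 2–11, 100-replicate
  bootstrap scores. The prognosis-driven search picks k = 3 with
  ARI ≈ 1 against the planted subtypes.
* **Integration study** — n = 400, K = 4 latent subtypes with log-HRs
  (0, 0.7, 1.05, 1.4) (spread 1.4 beyond the clinical effects),
  "marker" pattern so each layer contributes a distinct hazard
  contrast, moderate clinical effects, 40% censoring; 200-replicate
  bootstrap, 100 CV iterations. Evaluated along the chain
  C → CG → CGM → CGMm — strongest layer first, because a weaker
  contrast cannot aid discrimination while a stronger unmodelled one
  confounds the mixture it is compared against — the corrected
  Harrell's C increases monotonically and the full model beats the
  clinical-only model by ≈ 0.03 mean CV Uno's C at every horizon.

`scripts/acceptance.py` re-runs both from scratch under a caller-
supplied master seed and writes the resulting quantities as JSON.

## Reproducibility

Every random draw flows from a single master seed through named
sub-streams (CRC32-tagged `numpy` SeedSequences); no code reads global
RNG state. Output tables are written with 10-significant-digit floats
and the literal string `NA` for missing values, so file round-trips
are lossless and two runs under one master seed are byte-identical —
asserted by the test suite at the level of the command-line pipeline's
comparison tables.
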