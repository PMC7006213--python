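"""The 12-model comparison, paired significance tests, and ablation.

Model codes combine covariate blocks: ``C`` clinical (T/N/M stage +
age), ``G`` gene-expression clusters, ``M`` methylation clusters,
``m`` miRNA clusters, ``A`` the integrated cluster-of-clusters label
(mutually exclusive with G/M/m).  The canonical comparison set is
CGMm, CGM, CGm, CMm, CG, CM, Cm, C, G, M, m, CA.

Two selection regimes provide the cluster labels: models containing
clinical covariates use the labels selected with the clinical design as
companions; omics-alone models use the labels selected without
companions.  All models evaluated under one master seed share the same
bootstrap and cross-validation index streams, so per-iteration C-index
distributions are paired and Wilcoxon signed-rank tests apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterGridSpec, ClusterSearchResult, cluster_of_clusters, grid_search
from .config import EvalConfig
from .datatypes import ClinicalTable, ClusterLabels, FeatureMatrix, SurvivalData
from .survival import (
    BootstrapCResult,
    CoxFit,
    DesignMatrix,
    ModelTests,
    PHTestResult,
    cluster_design,
    concat_designs,
    cv_uno_c_multi,
    encode_covariates,
    fit_cox,
    lrt_nested,
    model_tests,
    optimism_corrected_c,
    ph_test,
)

MODEL_CODES = ("CGMm", "CGM", "CGm", "CMm", "CG", "CM", "Cm", "C", "G", "M", "m", "CA")

_LAYER_OF = {"G": "expression", "M": "methylation", "m": "mirna", "A": "coc"}
CLINICAL_BLOCKS = ("t_stage", "n_stage", "m_stage", "age")


@dataclass
class ModelSpec:
    code: str

    def __post_init__(self) -> None:
        if not self.code or any(ch not in "CGMmA" for ch in self.code):
            raise ValueError(f"invalid model code {self.code!r} (alphabet C/G/M/m/A)")
        if len(set(self.code)) != len(self.code):
            raise ValueError(f"repeated covariate in model code {self.code!r}")
        if "A" in self.code and set(self.code) & {"G", "M", "m"}:
            raise ValueError("the integrated C-o-C covariate excludes per-layer covariates")

    @property
    def uses_clinical(self) -> bool:
        return "C" in self.code

    @property
    def omics_layers(self) -> tuple:
        return tuple(_LAYER_OF[ch] for ch in self.code if ch != "C")

    @property
    def blocks(self) -> tuple:
        blocks: list = []
        if self.uses_clinical:
            blocks.extend(CLINICAL_BLOCKS)
        blocks.extend(self.omics_layers)
        return tuple(blocks)


def enumerate_models(include_coc: bool = True) -> list:
    """The canonical twelve model specifications (eleven without C-o-C)."""
    codes = MODEL_CODES if include_coc else tuple(c for c in MODEL_CODES if c != "CA")
    return [ModelSpec(c) for c in codes]


@dataclass
class CohortFeatures:
    """Everything evaluate_model needs: follow-up, the clinical design,
    and the selected cluster labels under both regimes."""

    survival: SurvivalData
    clinical_design: DesignMatrix
    labels_alone: dict = field(default_factory=dict)  # layer -> ClusterLabels
    labels_clinical: dict = field(default_factory=dict)
    coc_labels: ClusterLabels | None = None
    sample_ids: pd.Index | None = None
    search_results: dict = field(default_factory=dict)


def prepare_features(
    layers: dict,
    clinical: ClinicalTable,
    survival: SurvivalData,
    grid: ClusterGridSpec,
    eval_cfg: EvalConfig,
    models: list | None = None,
) -> CohortFeatures:
    """Run the per-layer grid searches (and C-o-C) needed by ``models``.

    Each layer is searched at most twice: once without companions (for
    omics-alone models) and once with the clinical design as companions
    (for clinical+omics models); the C-o-C search integrates the three
    companion-selected label sets, again with clinical companions.
    """
    specs = models if models is not None else enumerate_models()
    clinical_design = encode_covariates(clinical, drop_absent=True)
    feats = CohortFeatures(
        survival=survival,
        clinical_design=clinical_design,
        sample_ids=clinical.sample_ids,
    )
    need_alone = set()
    need_clin = set()
    need_coc = False
    for spec in specs:
        for layer in spec.omics_layers:
            if layer == "coc":
                need_coc = True
            elif spec.uses_clinical:
                need_clin.add(layer)
            else:
                need_alone.add(layer)
    if need_coc:
        need_clin |= {"expression", "methylation", "mirna"}

    for layer in sorted(need_alone):
        res = grid_search(layers[layer], survival, None, grid, eval_cfg, name=layer)
        feats.labels_alone[layer] = res.winner_labels
        feats.search_results[f"{layer}/alone"] = res
    for layer in sorted(need_clin):
        res = grid_search(layers[layer], survival, clinical_design, grid, eval_cfg, name=layer)
        feats.labels_clinical[layer] = res.winner_labels
        feats.search_results[f"{layer}/clinical"] = res
    if need_coc:
        label_sets = [feats.labels_clinical[l] for l in ("expression", "methylation", "mirna")]
        res = cluster_of_clusters(
            label_sets, survival, clinical_design, grid, eval_cfg,
            sample_ids=feats.sample_ids, name="coc",
        )
        feats.coc_labels = res.winner_labels
        feats.search_results["coc/clinical"] = res
    return feats


def build_design(spec: ModelSpec, feats: CohortFeatures) -> DesignMatrix:
    parts: list = []
    if spec.uses_clinical:
        parts.append(feats.clinical_design)
    for layer in spec.omics_layers:
        if layer == "coc":
            labels = feats.coc_labels
        elif spec.uses_clinical:
            labels = feats.labels_clinical.get(layer)
        else:
            labels = feats.labels_alone.get(layer)
        if labels is None:
            raise ValueError(f"cluster labels for layer {layer!r} not prepared")
        parts.append(cluster_design(labels, index=feats.sample_ids))
    if not parts:
        raise ValueError("empty model specification")
    return parts[0] if len(parts) == 1 else concat_designs(*parts)


@dataclass
class ModelEvaluation:
    spec: ModelSpec
    design: DesignMatrix
    fit: CoxFit
    bootstrap: BootstrapCResult
    cv: dict  # tau -> CVCResult
    ph: PHTestResult
    tests: ModelTests


def evaluate_design(
    design: DesignMatrix,
    survival: SurvivalData,
    eval_cfg: EvalConfig,
    spec: ModelSpec | None = None,
) -> ModelEvaluation:
    fit = fit_cox(design, survival)
    if not fit.converged:
        code = spec.code if spec is not None else "<design>"
        raise ValueError(f"Cox fit failed for model {code}: {fit.message}")
    boot = optimism_corrected_c(design, survival, B=eval_cfg.bootstrap_B, seed=eval_cfg.seed)
    cv = cv_uno_c_multi(
        design,
        survival,
        taus=eval_cfg.horizons,
        folds=eval_cfg.cv_folds,
        iters=eval_cfg.cv_iters,
        seed=eval_cfg.seed,
    )
    return ModelEvaluation(
        spec=spec if spec is not None else ModelSpec("C"),
        design=design,
        fit=fit,
        bootstrap=boot,
        cv=cv,
        ph=ph_test(fit, design, survival),
        tests=model_tests(fit),
    )


def evaluate_model(spec: ModelSpec, feats: CohortFeatures, eval_cfg: EvalConfig) -> ModelEvaluation:
    """Fit and fully evaluate one covariate combination.  All sub-seeds
    derive from the master seed only, so evaluations of different models
    are paired replicate-by-replicate."""
    design = build_design(spec, feats)
    return evaluate_design(design, feats.survival, eval_cfg, spec=spec)


# ---------------------------------------------------------------------------
# paired comparisons


def paired_wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zeros are handled by Pratt's method; the exact distribution is used
    for <= 25 informative pairs when no zeros or rank ties interfere,
    the normal approximation with continuity correction otherwise.  All
    differences zero reports p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired distributions must have equal length")
    d = x - y
    if np.all(d == 0.0):
        return 1.0
    nz = d[d != 0.0]
    no_ties = len(np.unique(np.abs(nz))) == len(nz)
    if len(d) <= 25 and len(nz) == len(d) and no_ties:
        res = stats.wilcoxon(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            x, y, alternative="two-sided", zero_method="pratt",
            correction=True, method="approx",
        )
    return float(res.pvalue)


_METRIC_KEYS = ("bootstrap", "2y", "3y", "5y")


def _metric_values(ev: ModelEvaluation) -> dict:
    taus = sorted(ev.cv)
    out = {"bootstrap": ev.bootstrap.corrected_values}
    names = ["2y", "3y", "5y"]
    for name, tau in zip(names, taus):
        out[name] = ev.cv[tau].iteration_values
    return out


def compare_models(evals: list, pairs: list | None = None) -> pd.DataFrame:
    """Pairwise ΔC (mean_a - mean_b) and paired Wilcoxon p per metric,
    plus the nested-model LRT p where one spec's blocks contain the
    other's.  ``pairs`` holds (code_a, code_b) tuples; default is every
    ordered pair."""
    by_code = {ev.spec.code: ev for ev in evals}
    if pairs is None:
        codes = list(by_code)
        pairs = [(a, b) for a in codes for b in codes if a != b]
    rows = []
    for code_a, code_b in pairs:
        ev_a, ev_b = by_code[code_a], by_code[code_b]
        va, vb = _metric_values(ev_a), _metric_values(ev_b)
        row: dict = {"model_a": code_a, "model_b": code_b}
        for key in va:
            if len(va[key]) != len(vb[key]):
                raise ValueError("paired comparison needs equal iteration counts")
            diff = va[key] - vb[key]
            row[f"delta_{key}"] = float(diff.mean())
            lo, hi = np.percentile(diff, [2.5, 97.5])
            row[f"delta_{key}_ci_low"] = float(lo)
            row[f"delta_{key}_ci_high"] = float(hi)
            row[f"wilcoxon_p_{key}"] = paired_wilcoxon_p(va[key], vb[key])
        if set(ev_b.spec.blocks) < set(ev_a.spec.blocks):
            row["lrt_p"] = lrt_nested(ev_a.fit, ev_b.fit)
        else:
            row["lrt_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


#: the headline comparison set: the full model against every other, plus
#: the chain comparisons along C -> C+one layer -> C+two layers
DEFAULT_PAIRS = (
    [("CGMm", c) for c in MODEL_CODES if c != "CGMm"]
    + [("CMm", "CG"), ("CMm", "Cm"), ("CMm", "C"), ("CG", "C"), ("Cm", "C")]
)


ABLATION_BLOCKS = (
    ("t_stage", "Without T stage"),
    ("n_stage", "Without N stage"),
    ("m_stage", "Without M stage"),
    ("age", "Without Age"),
    ("expression", "Without Gene"),
    ("methylation", "Without Methylation"),
    ("mirna", "Without miRNA"),
)


def ablation(
    feats: CohortFeatures,
    eval_cfg: EvalConfig,
    full_eval: ModelEvaluation | None = None,
) -> pd.DataFrame:
    """Leave-one-covariate-out analysis of the full CGMm model: seven
    reduced models, each re-evaluated on the same seeds and compared to
    the full model (ΔC = full - reduced, positive means the removed
    block helped)."""
    spec = ModelSpec("CGMm")
    if full_eval is None:
        full_eval = evaluate_model(spec, feats, eval_cfg)
    full_vals = _metric_values(full_eval)
    rows = []
    for block, label in ABLATION_BLOCKS:
        reduced_design = full_eval.design.drop_block(block)
        red = evaluate_design(reduced_design, feats.survival, eval_cfg, spec=spec)
        red_vals = _metric_values(red)
        row: dict = {"removed": label}
        for key in full_vals:
            diff = full_vals[key] - red_vals[key]
            row[f"delta_{key}"] = float(diff.mean())
            lo, hi = np.percentile(diff, [2.5, 97.5])
            row[f"delta_{key}_ci_low"] = float(lo)
            row[f"delta_{key}_ci_high"] = float(hi)
            row[f"wilcoxon_p_{key}"] = paired_wilcoxon_p(full_vals[key], red_vals[key])
        row["lrt_p"] = lrt_nested(full_eval.fit, red.fit)
        rows.append(row)
    return pd.DataFrame(rows)
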