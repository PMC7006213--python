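"""Per-layer feature quality filtering and selection.

Reprocessing rules applied to each omics layer before clustering:

* drop features with more than ``max_bad_frac`` (default 5%) NA-or-zero
  entries — strictly greater than, so a feature exactly at the boundary
  is kept; for beta-scale methylation only NA counts (a 0 beta value is
  a legitimate measurement);
* keep the union of the top-``top_frac`` (default 25%) features by
  coefficient of variation and a prior-knowledge feature list;
* collapse methylation probes to genes by per-sample averaging of the
  gene's probes, after removing chrX/chrY probes and probes with more
  than 5% NA (sex chromosomes are excluded because colon cancer is not
  a sex-specific disease).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix


@dataclass
class PriorList:
    """Prior-knowledge feature identifiers for one layer."""

    layer: str
    feature_ids: frozenset

    def __post_init__(self) -> None:
        self.feature_ids = frozenset(self.feature_ids)


@dataclass
class ProbeGeneMap:
    """probe -> (gene, chromosome), many probes per gene, one gene per probe."""

    table: pd.DataFrame  # columns: probe, gene, chromosome

    def __post_init__(self) -> None:
        need = {"probe", "gene", "chromosome"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"probe map needs columns {sorted(need)}")
        if self.table["probe"].duplicated().any():
            raise ValueError("each probe must map to at most one gene")


def _bad_fraction(matrix: FeatureMatrix) -> pd.Series:
    vals = matrix.values
    bad = vals.isna()
    if matrix.scale != "beta":  # a true 0 beta value is valid
        bad = bad | (vals == 0.0)
    return bad.sum(axis=0) / matrix.n_samples


def filter_low_quality(matrix: FeatureMatrix, max_bad_frac: float = 0.05) -> FeatureMatrix:
    """Drop features whose NA-or-zero fraction strictly exceeds the cutoff."""
    if matrix.n_features == 0:
        raise ValueError("empty feature matrix")
    frac = _bad_fraction(matrix)
    keep = frac.index[(frac <= max_bad_frac).to_numpy()]
    if len(keep) == 0:
        raise ValueError("no features survive the quality filter")
    return matrix.subset_features(keep)


def coefficient_of_variation(matrix: FeatureMatrix) -> pd.Series:
    """Per-feature sd/mean over non-NA entries (sample sd, n-1 denominator).

    NA when the non-NA mean is 0 (undefined); such features rank last in
    :func:`select_features`.
    """
    vals = matrix.values
    counts = vals.notna().sum(axis=0)
    if (counts < 2).any():
        raise ValueError("every feature needs >= 2 non-NA values")
    mean = vals.mean(axis=0, skipna=True)
    sd = vals.std(axis=0, ddof=1, skipna=True)
    cv = sd / mean
    cv[mean == 0.0] = np.nan
    return cv


def select_features(
    matrix: FeatureMatrix, top_frac: float = 0.25, prior: PriorList | None = None
) -> FeatureMatrix:
    """Union of the top-``top_frac`` features by CV and the prior list.

    The top count is ``ceil(top_frac * n_features)``; CV ties (and the
    rank boundary) are broken by lexicographic feature id so the output
    is deterministic.  Original feature order is preserved.
    """
    n_top = math.ceil(top_frac * matrix.n_features)
    cv = coefficient_of_variation(matrix)
    order = sorted(
        matrix.feature_ids,
        key=lambda f: (np.isnan(cv[f]), -(cv[f] if not np.isnan(cv[f]) else 0.0), f),
    )
    chosen = set(order[:n_top])
    if prior is not None:
        present = prior.feature_ids & set(matrix.feature_ids)
        absent = prior.feature_ids - present
        if absent:
            warnings.warn(
                f"{len(absent)} prior features absent from the {matrix.layer} matrix",
                stacklevel=2,
            )
        chosen |= present
    keep = [f for f in matrix.feature_ids if f in chosen]
    return matrix.subset_features(keep)


def aggregate_probes_to_genes(
    probe_matrix: FeatureMatrix,
    probe_map: ProbeGeneMap,
    excluded_chroms: tuple = ("X", "Y"),
    max_na_frac: float = 0.05,
) -> FeatureMatrix:
    """Average methylation probes to gene level.

    Probes on excluded chromosomes are dropped first, then probes with
    more than ``max_na_frac`` NA; each gene's per-sample value is the
    mean of its remaining probes' non-NA betas.  Genes with no remaining
    probes are absent from the output (sorted by gene id).
    """
    if probe_matrix.scale != "beta":
        raise ValueError("probe matrix must be on the beta scale")
    mapping = probe_map.table.set_index("probe")
    covered = [p for p in probe_matrix.feature_ids if p in mapping.index]
    if not covered:
        raise ValueError("probe map covers none of the probes in the matrix")
    chrom = mapping.loc[covered, "chromosome"].astype(str)
    keep = [p for p in covered if chrom[p] not in {str(c) for c in excluded_chroms}]
    vals = probe_matrix.values[keep]
    na_frac = vals.isna().sum(axis=0) / probe_matrix.n_samples
    keep = [p for p in keep if na_frac[p] <= max_na_frac]
    if not keep:
        raise ValueError("no probes survive chromosome and NA filtering")
    vals = probe_matrix.values[keep]
    genes = mapping.loc[keep, "gene"]
    out = vals.T.groupby(genes).mean().T  # skips NA within each gene's probes
    out = out[sorted(out.columns)]
    out.columns.name = None
    return FeatureMatrix(out, probe_matrix.layer, "beta")


def log_transform(matrix: FeatureMatrix) -> FeatureMatrix:
    """log(1 + x) variance stabilisation for the count-derived scales
    (FPKM / RPM) ahead of distance computation; beta values and binary
    indicators pass through unchanged."""
    if matrix.scale not in ("fpkm", "rpm"):
        return matrix
    return FeatureMatrix(np.log1p(matrix.values), matrix.layer, matrix.scale)


def impute_feature_means(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace remaining NA entries by the feature's non-NA mean (distance
    computations downstream require complete rows)."""
    vals = matrix.values
    if not vals.isna().any().any():
        return matrix
    filled = vals.fillna(vals.mean(axis=0, skipna=True))
    return FeatureMatrix(filled, matrix.layer, matrix.scale)


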