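"""Hierarchical patient clustering and prognosis-driven model selection.

Dimension reduction works by clustering patients per omics layer over a
grid of (distance metric) x (linkage) x (cluster count k) combinations
and keeping the combination whose dummy-coded cluster label carries the
best prognostic signal — scored by the bias-corrected Harrell's C of a
Cox model containing the label (plus optional companion covariates,
e.g. the clinical factors of the target model).  Layer-level winners
are then one-hot coded into a patients x cluster-labels binary matrix
and the same search runs once more on it: the cluster-of-clusters
(C-o-C) integration step.

The seven distance metrics and eight linkage criteria mirror the
conventional agglomerative toolkit (Ward.D / Ward.D2 / single /
complete / average / McQuitty / median / centroid); ward_d applies the
Ward update to the distances as supplied, ward_d2 to squared distances
(with square-rooted merge heights), and median/centroid carry squared-
Euclidean semantics.  Ties in the minimal inter-cluster distance are
broken by the smallest pair of cluster indices in creation order, so
results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .config import EvalConfig
from .datatypes import ClusterLabels, FeatureMatrix, SurvivalData
from .survival import DesignMatrix, cluster_design, concat_designs, optimism_corrected_c

METRICS = ("euclidean", "maximum", "manhattan", "canberra", "binary", "minkowski", "correlation")
LINKAGES = ("ward_d", "ward_d2", "single", "complete", "average", "mcquitty", "median", "centroid")

#: linkages whose Lance-Williams update runs on squared dissimilarities
_SQUARED = {"ward_d2", "median", "centroid"}


@dataclass
class DistanceSpec:
    metric: str = "euclidean"
    minkowski_p: float = 3.0

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if self.minkowski_p <= 0:
            raise ValueError("minkowski_p must be > 0")


@dataclass
class MergeTree:
    """Agglomeration record: leaves 0..n-1, internal node i created at
    merge step i-n; ``merges[s] = (left, right, height)``."""

    n_leaves: int
    merges: list


@dataclass
class ClusterGridSpec:
    distances: tuple = METRICS
    linkages: tuple = LINKAGES
    k_range: tuple = (2, 11)
    min_cluster_size: int = 10
    minkowski_p: float = 3.0
    standardize: bool = False

    def __post_init__(self) -> None:
        for m in self.distances:
            if m not in METRICS:
                raise ValueError(f"unknown metric {m!r}")
        for l in self.linkages:
            if l not in LINKAGES:
                raise ValueError(f"unknown linkage {l!r}")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValueError("k_range must be an interval within [2, n_samples]")


@dataclass
class Candidate:
    params: tuple  # (metric, linkage, k)
    labels: ClusterLabels | None
    score: float
    feasible: bool
    reason: str = ""


@dataclass
class ClusterSearchResult:
    candidates: list
    winner: tuple
    winner_labels: ClusterLabels
    score_type: str

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "distance": c.params[0],
                "linkage": c.params[1],
                "k": c.params[2],
                "feasible": c.feasible,
                "score": c.score,
                "reason": c.reason,
            }
            for c in self.candidates
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distances


def pairwise_distance(matrix, spec: DistanceSpec) -> np.ndarray:
    """Symmetric n x n distance matrix under one of the seven metrics.

    binary: among positions where at least one coordinate is nonzero,
    the fraction where exactly one is (Jaccard on the nonzero pattern).
    canberra: sum |x-y| / (|x|+|y|) with 0/0 terms contributing 0.
    correlation: 1 - Pearson r; rows with zero variance are an error.
    """
    X = matrix.values.to_numpy(dtype=float) if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("distance computation requires a complete matrix; impute or filter first")
    m = spec.metric
    if m == "correlation":
        sd = X.std(axis=1)
        bad = np.flatnonzero(sd == 0.0)
        if bad.size:
            ids = (
                list(matrix.sample_ids[bad[:5]])
                if isinstance(matrix, FeatureMatrix)
                else bad[:5].tolist()
            )
            raise ValueError(f"correlation distance undefined for zero-variance sample(s) {ids}")
        d = pdist(X, metric="correlation")
    elif m == "binary":
        d = pdist(X != 0.0, metric="jaccard")
    elif m == "maximum":
        d = pdist(X, metric="chebyshev")
    elif m == "manhattan":
        d = pdist(X, metric="cityblock")
    elif m == "minkowski":
        d = pdist(X, metric="minkowski", p=spec.minkowski_p)
    else:
        d = pdist(X, metric=m)
    return squareform(d)


# ---------------------------------------------------------------------------
# agglomeration


def _lw_coefficients(linkage: str, ni: int, nj: int, nh: int):
    """Lance-Williams (alpha_i, alpha_j, beta, gamma) for merging clusters
    i (size ni) and j (size nj), updating the distance to cluster h."""
    if linkage == "single":
        return 0.5, 0.5, 0.0, -0.5
    if linkage == "complete":
        return 0.5, 0.5, 0.0, 0.5
    if linkage == "average":
        s = ni + nj
        return ni / s, nj / s, 0.0, 0.0
    if linkage == "mcquitty":
        return 0.5, 0.5, 0.0, 0.0
    if linkage == "centroid":
        s = ni + nj
        return ni / s, nj / s, -(ni * nj) / (s * s), 0.0
    if linkage == "median":
        return 0.5, 0.5, -0.25, 0.0
    if linkage in ("ward_d", "ward_d2"):
        s = ni + nj + nh
        return (ni + nh) / s, (nj + nh) / s, -nh / s, 0.0
    raise ValueError(f"unknown linkage {linkage!r}")


def hierarchical_cluster(dist: np.ndarray, linkage: str) -> MergeTree:
    """Agglomerative merge tree via Lance-Williams updates.

    Partitions are invariant to sample permutation (up to label
    renumbering); median/centroid may produce height inversions, which
    are tolerated because trees are cut by merge count, not height.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    work = D.copy() ** 2 if linkage in _SQUARED else D.copy()

    size = 2 * n - 1
    W = np.full((size, size), np.inf)
    W[:n, :n] = work
    np.fill_diagonal(W, np.inf)
    sizes = np.ones(size, dtype=int)
    active = np.zeros(size, dtype=bool)
    active[:n] = True

    merges: list = []
    for step in range(n - 1):
        ids = np.flatnonzero(active)
        sub = W[np.ix_(ids, ids)]
        mval = sub.min()
        # tie-break: smallest (i, j) pair by creation order
        ii, jj = np.nonzero(sub == mval)
        pairs = [(ids[a], ids[b]) for a, b in zip(ii, jj) if ids[a] < ids[b]]
        i, j = min(pairs)
        new = n + step
        height = float(np.sqrt(max(mval, 0.0))) if linkage in _SQUARED else float(mval)
        merges.append((int(i), int(j), height))
        ai_n, aj_n = sizes[i], sizes[j]
        others = ids[(ids != i) & (ids != j)]
        if others.size:
            dih = W[i, others]
            djh = W[j, others]
            dij = W[i, j]
            if linkage in ("ward_d", "ward_d2"):
                nh = sizes[others].astype(float)
                s = ai_n + aj_n + nh
                dnew = ((ai_n + nh) * dih + (aj_n + nh) * djh - nh * dij) / s
            else:
                ai, aj, b, g = _lw_coefficients(linkage, ai_n, aj_n, 0)
                dnew = ai * dih + aj * djh + b * dij + g * np.abs(dih - djh)
            W[new, others] = dnew
            W[others, new] = dnew
        sizes[new] = ai_n + aj_n
        active[i] = active[j] = False
        active[new] = True
    return MergeTree(n, merges)


def cut_tree(tree: MergeTree, k: int, name: str = "clusters", params: tuple = ()) -> ClusterLabels:
    """Partition after ``n_leaves - k`` merges, labels renumbered 1..k by
    first sample appearance."""
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}]")
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for s in range(n - k):
        i, j, _ = tree.merges[s]
        new = n + s
        parent[find(i)] = new
        parent[find(j)] = new
    roots = np.array([find(x) for x in range(n)])
    labels = np.empty(n, dtype=int)
    seen: dict = {}
    for idx, r in enumerate(roots):
        if r not in seen:
            seen[r] = len(seen) + 1
        labels[idx] = seen[r]
    return ClusterLabels(labels, k, params or (None, None, k), name=name)


# ---------------------------------------------------------------------------
# prognosis-driven grid search


def grid_search(
    matrix,
    survival: SurvivalData,
    companions: DesignMatrix | None,
    grid: ClusterGridSpec,
    eval_cfg: EvalConfig,
    name: str = "clusters",
) -> ClusterSearchResult:
    """Evaluate every (distance, linkage, k) candidate and keep the one
    whose cluster label yields the best bias-corrected Harrell's C.

    A candidate is infeasible when any cluster holds fewer than
    ``min_cluster_size`` patients or the Cox fit on its dummy-coded
    label (plus companions) fails.  Every candidate is scored with the
    same bootstrap index stream, so the winner does not depend on
    evaluation order.  Ties go to fewer clusters, then grid order.
    """
    X = matrix.values.to_numpy(dtype=float) if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, dtype=float)
    if grid.standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0.0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    index = matrix.sample_ids if isinstance(matrix, FeatureMatrix) else pd.RangeIndex(X.shape[0])
    n = X.shape[0]
    if len(survival) != n:
        raise ValueError("matrix and survival must share sample order")
    k_lo, k_hi = grid.k_range
    k_hi = min(k_hi, n)

    candidates: list = []
    for metric in grid.distances:
        spec = DistanceSpec(metric, grid.minkowski_p)
        try:
            D = pairwise_distance(X, spec)
        except ValueError as exc:
            for linkage in grid.linkages:
                for k in range(k_lo, k_hi + 1):
                    candidates.append(
                        Candidate((metric, linkage, k), None, -np.inf, False, str(exc))
                    )
            continue
        for linkage in grid.linkages:
            tree = hierarchical_cluster(D, linkage)
            for k in range(k_lo, k_hi + 1):
                params = (metric, linkage, k)
                labels = cut_tree(tree, k, name=name, params=params)
                if labels.sizes().min() < grid.min_cluster_size:
                    candidates.append(
                        Candidate(params, labels, -np.inf, False,
                                  f"cluster below min size {grid.min_cluster_size}")
                    )
                    continue
                design = cluster_design(labels, index=index)
                if companions is not None and len(companions.columns):
                    design = concat_designs(design, companions)
                try:
                    boot = optimism_corrected_c(
                        design, survival, B=eval_cfg.search_B, seed=eval_cfg.seed
                    )
                except ValueError as exc:
                    candidates.append(Candidate(params, labels, -np.inf, False, str(exc)))
                    continue
                candidates.append(Candidate(params, labels, boot.corrected_mean, True))

    feasible = [c for c in candidates if c.feasible]
    if not feasible:
        raise ValueError("no feasible candidate in the clustering grid")
    best_score = max(c.score for c in feasible)
    best = min((c for c in feasible if c.score == best_score), key=lambda c: c.params[2])
    return ClusterSearchResult(
        candidates=candidates,
        winner=best.params,
        winner_labels=best.labels,
        score_type=f"optimism-corrected Harrell C (B={eval_cfg.search_B})",
    )


def one_hot_cluster_matrix(label_sets, sample_ids=None) -> FeatureMatrix:
    """Binary patients x cluster-labels matrix: one column per (layer,
    cluster) pair; each row sums to the number of label sets."""
    lengths = {len(ls) for ls in label_sets}
    if len(lengths) != 1:
        raise ValueError("label sets must share sample order (equal lengths)")
    n = lengths.pop()
    cols = {}
    for ls in label_sets:
        for j in range(1, ls.k + 1):
            cols[f"{ls.name}:cluster{j}"] = (ls.labels == j).astype(float)
    index = sample_ids if sample_ids is not None else pd.RangeIndex(n)
    return FeatureMatrix(pd.DataFrame(cols, index=index), "cluster_binary", "binary")


def cluster_of_clusters(
    label_sets,
    survival: SurvivalData,
    companions: DesignMatrix | None,
    grid: ClusterGridSpec,
    eval_cfg: EvalConfig,
    sample_ids=None,
    name: str = "coc",
) -> ClusterSearchResult:
    """Second-layer clustering of the one-hot cluster-label matrix; the
    winner's labels constitute the integrated-omics covariate."""
    binary = one_hot_cluster_matrix(label_sets, sample_ids=sample_ids)
    return grid_search(binary, survival, companions, grid, eval_cfg, name=name)
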