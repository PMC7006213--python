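"""Cox proportional-hazards fitting and the discrimination toolkit.

The model is the standard semi-parametric Cox PH model

    h(t | z) = h0(t) * exp(beta' z)

fit by Newton iterations on the Efron-tie partial likelihood (follow-up
is recorded at day resolution, so tied event times occur).  Around the
fit sit the evaluation tools the pipeline needs:

* Harrell's concordance index (pairwise, censoring-aware);
* bootstrap optimism correction of Harrell's C (resample-refit,
  per-replicate corrected value = apparent - (c_boot - c_orig));
* Uno's IPCW concordance truncated at a horizon tau, weighted by the
  inverse squared Kaplan-Meier estimate of the censoring survivor
  function;
* repeated event-stratified K-fold cross-validation of Uno's C on
  pooled out-of-fold linear predictors;
* the Grambsch-Therneau scaled-Schoenfeld test of the PH assumption;
* likelihood-ratio / score / Wald global tests and a nested-model LRT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import rng_for
from .datatypes import ClinicalTable, ClusterLabels, SurvivalData

# ---------------------------------------------------------------------------
# design construction


@dataclass
class DesignMatrix:
    """Dummy-coded covariates with block structure retained for ablation.

    ``blocks`` maps a covariate block name (t_stage / n_stage / m_stage /
    age / one name per cluster-label set) to its column names; reference
    levels carry no column (treatment coding).
    """

    df: pd.DataFrame
    blocks: dict
    reference_levels: dict

    @property
    def columns(self) -> pd.Index:
        return self.df.columns

    def __len__(self) -> int:
        return len(self.df)

    def drop_block(self, block: str) -> "DesignMatrix":
        if block not in self.blocks:
            raise KeyError(f"unknown covariate block {block!r}")
        cols = [c for c in self.df.columns if c not in set(self.blocks[block])]
        blocks = {k: v for k, v in self.blocks.items() if k != block}
        refs = {k: v for k, v in self.reference_levels.items() if k != block}
        return DesignMatrix(self.df[cols], blocks, refs)

    def select_blocks(self, names) -> "DesignMatrix":
        cols: list = []
        blocks = {}
        for b in names:
            if b not in self.blocks:
                raise KeyError(f"unknown covariate block {b!r}")
            cols.extend(self.blocks[b])
            blocks[b] = list(self.blocks[b])
        refs = {k: v for k, v in self.reference_levels.items() if k in blocks}
        return DesignMatrix(self.df[cols], blocks, refs)


def _dummy_block(codes: np.ndarray, levels: list, prefix: str, drop_absent: bool):
    """Treatment coding: first (present) level is the reference."""
    counts = {lv: int(np.sum(codes == lv)) for lv in levels}
    if drop_absent:
        levels = [lv for lv in levels if counts[lv] > 0]
    else:
        empty = [lv for lv in levels[1:] if counts[lv] == 0]
        if empty:
            raise ValueError(
                f"{prefix}: non-reference level(s) {empty} have zero samples "
                "(column would be all-zero)"
            )
    ref = levels[0]
    cols = {f"{prefix}[{lv}]": (codes == lv).astype(float) for lv in levels[1:]}
    return cols, ref


def age_quartile_bins(age: np.ndarray) -> np.ndarray:
    """Empirical quartile cutpoints producing four left-closed bins."""
    return np.quantile(np.asarray(age, float), [0.25, 0.5, 0.75])


def encode_covariates(
    clinical: ClinicalTable,
    cluster_labels: tuple = (),
    age_bins: np.ndarray | None = None,
    drop_absent: bool = False,
) -> DesignMatrix:
    """Dummy-code T/N/M stage, binned age and cluster labels.

    References: T1, N0, M0, the youngest age bin, cluster 1.  Age is cut
    into four quartile-based, left-closed right-open intervals (the last
    bin is closed on the right); user-supplied cutpoints override the
    empirical quartiles.
    """
    from .datatypes import M_LEVELS, N_LEVELS, T_LEVELS

    tab = clinical.table
    cols: dict = {}
    blocks: dict = {}
    refs: dict = {}
    for block, col, levels in (
        ("t_stage", "t_stage", list(T_LEVELS)),
        ("n_stage", "n_stage", list(N_LEVELS)),
        ("m_stage", "m_stage", list(M_LEVELS)),
    ):
        codes = tab[col].to_numpy()
        c, ref = _dummy_block(codes, levels, col, drop_absent)
        cols.update(c)
        blocks[block] = list(c)
        refs[block] = ref

    age = tab["age_years"].to_numpy(dtype=float)
    cuts = age_quartile_bins(age) if age_bins is None else np.asarray(age_bins, float)
    bin_idx = np.searchsorted(cuts, age, side="right")  # left-closed bins
    edges = [age.min(), *cuts, age.max()]
    labels = [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(3)] + [
        f"[{edges[3]:g},{edges[4]:g}]"
    ]
    c, ref = _dummy_block(bin_idx, [0, 1, 2, 3], "age", drop_absent)
    c = {f"age{labels[int(k[4:-1])]}": v for k, v in c.items()}
    cols.update(c)
    blocks["age"] = list(c)
    refs["age"] = labels[int(ref)]

    for cl in cluster_labels:
        c, ref = _dummy_block(cl.labels, list(range(1, cl.k + 1)), cl.name, drop_absent)
        c = {k.replace(f"{cl.name}[", f"{cl.name}[cluster"): v for k, v in c.items()}
        cols.update(c)
        blocks[cl.name] = list(c)
        refs[cl.name] = "cluster1"

    df = pd.DataFrame(cols, index=tab.index)
    return DesignMatrix(df, blocks, refs)


def cluster_design(labels: ClusterLabels, index=None) -> DesignMatrix:
    """Design holding a single dummy-coded cluster-label covariate."""
    cols = {
        f"{labels.name}[cluster{j}]": (labels.labels == j).astype(float)
        for j in range(2, labels.k + 1)
    }
    df = pd.DataFrame(cols, index=index)
    return DesignMatrix(df, {labels.name: list(cols)}, {labels.name: "cluster1"})


def concat_designs(*designs: DesignMatrix) -> DesignMatrix:
    df = pd.concat([d.df for d in designs], axis=1)
    blocks: dict = {}
    refs: dict = {}
    for d in designs:
        for k, v in d.blocks.items():
            if k in blocks:
                raise ValueError(f"duplicate covariate block {k!r}")
            blocks[k] = list(v)
        refs.update(d.reference_levels)
    return DesignMatrix(df, blocks, refs)


# ---------------------------------------------------------------------------
# Efron partial likelihood


class _CoxData:
    """Sorted views and tie groups; one instance per (X, survival) pair."""

    def __init__(self, X: np.ndarray, time: np.ndarray, event: np.ndarray):
        X = np.asarray(X, dtype=float)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        self.n, self.p = X.shape
        asc = np.argsort(time, kind="stable")
        self.Xa = np.ascontiguousarray(X[asc])
        self.ta = time[asc]
        self.da = event[asc].astype(bool)
        self.event_rows = np.flatnonzero(self.da)  # ascending-time order
        ev_times = self.ta[self.event_rows]
        self.ev_uniq, self.ev_counts = np.unique(ev_times, return_counts=True)
        self.group_starts = np.concatenate(([0], np.cumsum(self.ev_counts)[:-1]))
        # risk-set size for each unique event time: #{t >= te}
        self.risk_counts = self.n - np.searchsorted(self.ta, self.ev_uniq, side="left")
        self.n_events = int(event.sum())
        self.tied = bool(np.any(self.ev_counts > 1))

    def quantities(self, beta: np.ndarray):
        """Return (loglik, gradient, information) at beta (Efron ties)."""
        Xa, p = self.Xa, self.p
        eta = Xa @ beta
        w = np.exp(eta - eta.max())
        wd = w[::-1]
        Xd = Xa[::-1]
        c0 = np.cumsum(wd)
        c1 = np.cumsum(wd[:, None] * Xd, axis=0)
        c2 = np.cumsum(wd[:, None, None] * (Xd[:, :, None] * Xd[:, None, :]), axis=0)
        S0 = c0[self.risk_counts - 1]
        S1 = c1[self.risk_counts - 1]
        S2 = c2[self.risk_counts - 1]

        ev = self.event_rows
        Xe = Xa[ev]
        we = w[ev]
        etae = eta[ev]  # uncentered; the centring constant cancels exactly
        starts = self.group_starts
        sd0 = np.add.reduceat(we, starts)
        sd1 = np.add.reduceat(we[:, None] * Xe, starts, axis=0)
        sx = np.add.reduceat(Xe, starts, axis=0)
        seta = np.add.reduceat(etae, starts)

        # centred weights: log(true S0) = log(centred S0) + max(eta), and the
        # event terms use uncentred eta, so the constant cancels exactly
        c = eta.max()
        ll = float(seta.sum())
        grad = np.zeros(p)
        info = np.zeros((p, p))
        single = self.ev_counts == 1
        if np.any(single):
            S0s = S0[single]
            r = S1[single] / S0s[:, None]
            ll -= float((np.log(S0s) + c).sum())
            grad += sx[single].sum(axis=0) - r.sum(axis=0)
            info += (S2[single] / S0s[:, None, None]).sum(axis=0) - np.einsum(
                "ij,ik->jk", r, r
            )
        if self.tied:
            for g in np.flatnonzero(~single):
                D = self.ev_counts[g]
                frac = np.arange(D) / D
                rows = ev[starts[g] : starts[g] + D]
                Xg = Xa[rows]
                wg = w[rows]
                sd2g = np.einsum("i,ij,ik->jk", wg, Xg, Xg)
                M0 = S0[g] - frac * sd0[g]
                M1 = S1[g][None, :] - frac[:, None] * sd1[g][None, :]
                M2 = S2[g][None, :, :] - frac[:, None, None] * sd2g[None, :, :]
                r2 = M1 / M0[:, None]
                ll -= float((np.log(M0) + c).sum())
                grad += sx[g] - r2.sum(axis=0)
                info += (M2 / M0[:, None, None]).sum(axis=0) - np.einsum(
                    "ij,ik->jk", r2, r2
                )
        return ll, grad, info


@dataclass
class CoxFit:
    beta: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    hr: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p: pd.Series
    loglik_full: float
    loglik_null: float
    n: int
    n_events: int
    converged: bool
    iterations: int
    loglik_path: list
    info: pd.DataFrame
    score_chi2: float
    message: str = ""

    @property
    def df(self) -> int:
        return len(self.beta)

    def linear_predictor(self, design) -> np.ndarray:
        X = design.df if isinstance(design, DesignMatrix) else design
        return X[self.beta.index].to_numpy(dtype=float) @ self.beta.to_numpy()

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            }
        )


def _failed_fit(columns, n, n_events, message) -> CoxFit:
    nanv = pd.Series(np.nan, index=columns)
    nan_df = pd.DataFrame(np.nan, index=columns, columns=columns)
    return CoxFit(
        beta=nanv, se=nanv, cov=nan_df, hr=nanv, ci_low=nanv, ci_high=nanv, p=nanv,
        loglik_full=np.nan, loglik_null=np.nan, n=n, n_events=n_events,
        converged=False, iterations=0, loglik_path=[], info=nan_df,
        score_chi2=np.nan, message=message,
    )


def fit_cox(
    design,
    survival: SurvivalData,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Newton maximisation of the Efron partial likelihood.

    Convergence: |loglik change| < ``tol`` (with step-halving keeping the
    partial log-likelihood non-decreasing).  Singular information or
    non-convergence is reported through ``converged=False`` so grid
    searches can treat the candidate as infeasible instead of aborting.
    """
    X = design.df if isinstance(design, DesignMatrix) else pd.DataFrame(design)
    columns = X.columns
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    n_events = survival.n_events
    if n_events < 1:
        raise ValueError("at least one event is required to fit a Cox model")
    if p == 0:
        raise ValueError("design has no columns")
    const = np.all(Xv == Xv[0], axis=0)
    if np.any(const):
        return _failed_fit(columns, n, n_events, f"constant column(s): {list(columns[const])}")

    data = _CoxData(Xv, survival.time, survival.event)
    beta = np.zeros(p)
    ll, grad, info = data.quantities(beta)
    loglik_null = ll
    # score test at beta = 0
    try:
        score_chi2 = float(grad @ np.linalg.solve(info, grad))
    except np.linalg.LinAlgError:
        return _failed_fit(columns, n, n_events, "singular information at beta=0")

    loglik_path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return _failed_fit(columns, n, n_events, "singular information matrix")
        step = 1.0
        for _ in range(40):
            cand = beta + step * delta
            ll_new, grad_new, info_new = data.quantities(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            return _failed_fit(columns, n, n_events, "step-halving failed")
        beta, delta_ll = cand, ll_new - ll
        ll, grad, info = ll_new, grad_new, info_new
        loglik_path.append(ll)
        if abs(delta_ll) < tol:
            converged = True
            break
    if not converged:
        return _failed_fit(columns, n, n_events, f"no convergence in {max_iter} iterations")
    if np.any(np.abs(beta) > 50):
        return _failed_fit(columns, n, n_events, "diverging coefficients (monotone likelihood)")

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return _failed_fit(columns, n, n_events, "singular information at optimum")
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # inf CI bound on degenerate SEs is fine
        hr = np.exp(beta)
        ci_low = np.exp(beta - 1.96 * se)
        ci_high = np.exp(beta + 1.96 * se)
    return CoxFit(
        beta=pd.Series(beta, index=columns),
        se=pd.Series(se, index=columns),
        cov=pd.DataFrame(cov, index=columns, columns=columns),
        hr=pd.Series(hr, index=columns),
        ci_low=pd.Series(ci_low, index=columns),
        ci_high=pd.Series(ci_high, index=columns),
        p=pd.Series(pvals, index=columns),
        loglik_full=ll,
        loglik_null=loglik_null,
        n=n,
        n_events=n_events,
        converged=True,
        iterations=it,
        loglik_path=loglik_path,
        info=pd.DataFrame(info, index=columns, columns=columns),
        score_chi2=score_chi2,
    )


# ---------------------------------------------------------------------------
# concordance


@dataclass
class ConcordanceResult:
    c: float
    n_comparable_pairs: int
    variant: str
    tau: float | None = None


def harrell_c(risk: np.ndarray, survival: SurvivalData) -> ConcordanceResult:
    """Harrell's concordance: over pairs (i an event, j observed longer),
    credit 1 if risk_i > risk_j, 0.5 for tied risks."""
    r = np.asarray(risk, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("risk scores must be finite")
    t = survival.time
    d = survival.event.astype(bool)
    usable = d[:, None] & (t[None, :] > t[:, None])
    n_pairs = int(usable.sum())
    if n_pairs == 0:
        raise ValueError("no usable pairs for Harrell's C")
    conc = usable & (r[:, None] > r[None, :])
    tied = usable & (r[:, None] == r[None, :])
    credit = conc.sum() + 0.5 * tied.sum()
    return ConcordanceResult(float(credit / n_pairs), n_pairs, "harrell")


def censoring_km(survival: SurvivalData):
    """Kaplan-Meier estimate of the censoring survivor function G.

    Returns a callable ``G(t, before=True)``; with ``before`` the value
    is the left limit G(t-), i.e. the product over censoring times
    strictly below t.
    """
    t = survival.time
    c = 1 - survival.event
    order = np.argsort(t, kind="stable")
    ts, cs = t[order], c[order]
    uniq, start = np.unique(ts, return_index=True)
    n = len(ts)
    at_risk = n - start
    n_cens = np.add.reduceat(cs, start)
    factors = 1.0 - n_cens / at_risk
    surv = np.cumprod(factors)

    def G(x: np.ndarray, before: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        side = "left" if before else "right"
        idx = np.searchsorted(uniq, x, side=side)
        out = np.ones(x.shape, dtype=float)
        pos = idx > 0
        out[pos] = surv[idx[pos] - 1]
        return out

    return G


def uno_c(
    train_survival: SurvivalData,
    test_risk: np.ndarray,
    test_survival: SurvivalData,
    tau: float,
) -> ConcordanceResult:
    """Uno's IPCW concordance truncated at ``tau``.

    Pairs (i, j) with an event for i, t_i < t_j and t_i < tau are
    weighted by G(t_i-)^-2, with G the censoring KM from the training
    data.  Default horizons downstream are 2/3/5 years = 730/1095/1825
    days.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    r = np.asarray(test_risk, dtype=float)
    t = test_survival.time
    d = test_survival.event.astype(bool)
    G = censoring_km(train_survival)
    i_ok = d & (t < tau)
    later = t[None, :] > t[:, None]
    pair_mask = i_ok[:, None] & later
    n_pairs = int(pair_mask.sum())
    if n_pairs == 0:
        raise ValueError("no usable pairs for Uno's C at this tau")
    g = G(t, before=True)
    contributing = i_ok & later.any(axis=1)
    if np.any(g[contributing] == 0.0):
        raise ValueError("censoring KM reaches 0 before tau; tau too large for the support")
    w = np.zeros_like(g)
    w[contributing] = g[contributing] ** -2.0
    conc = (r[:, None] > r[None, :]).astype(float) + 0.5 * (r[:, None] == r[None, :])
    num = float((w[:, None] * pair_mask * conc).sum())
    den = float((w[:, None] * pair_mask).sum())
    return ConcordanceResult(num / den, n_pairs, "uno", tau=float(tau))


# ---------------------------------------------------------------------------
# resampling-based evaluation


@dataclass
class BootstrapCResult:
    apparent_c: float
    corrected_values: np.ndarray
    corrected_mean: float
    ci95: tuple
    optimism_mean: float
    n_failed: int
    seed: int


def optimism_corrected_c(
    design, survival: SurvivalData, B: int = 500, seed: int = 0
) -> BootstrapCResult:
    """Bootstrap optimism correction of Harrell's C.

    Per replicate b: resample with replacement, refit, and form the
    bias-corrected value apparent - (c_boot - c_orig); the mean of the B
    corrected values is the final bias-corrected C (identical to the
    classical apparent-minus-mean-optimism estimate).  Replicates whose
    fit fails are redrawn; more than 20% failures aborts.
    """
    X = design.df if isinstance(design, DesignMatrix) else pd.DataFrame(design)
    full = fit_cox(X, survival)
    if not full.converged:
        raise ValueError(f"full-data Cox fit failed: {full.message}")
    lp_full = X.to_numpy(dtype=float) @ full.beta.to_numpy()
    apparent = harrell_c(lp_full, survival).c

    rng = rng_for(seed, "bootstrap_optimism")
    n = len(survival)
    Xv = X.to_numpy(dtype=float)
    corrected = np.empty(B)
    b = 0
    failures = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        boot_surv = survival.subset(idx)
        fit_b = fit_cox(pd.DataFrame(Xv[idx], columns=X.columns), boot_surv)
        if not fit_b.converged:
            failures += 1
            if failures > 0.2 * B:
                raise ValueError(f"more than 20% of bootstrap replicates failed ({failures})")
            continue
        beta_b = fit_b.beta.to_numpy()
        c_boot = harrell_c(Xv[idx] @ beta_b, boot_surv).c
        c_orig = harrell_c(Xv @ beta_b, survival).c
        corrected[b] = apparent - (c_boot - c_orig)
        b += 1
    lo, hi = np.percentile(corrected, [2.5, 97.5])
    return BootstrapCResult(
        apparent_c=apparent,
        corrected_values=corrected,
        corrected_mean=float(corrected.mean()),
        ci95=(float(lo), float(hi)),
        optimism_mean=float(apparent - corrected.mean()),
        n_failed=failures,
        seed=seed,
    )


@dataclass
class CVCResult:
    tau: float
    iteration_values: np.ndarray
    mean: float
    fold_count: int
    seed: int
    n_redrawn: int = 0


def _stratified_folds(event: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment balanced on event status."""
    n = len(event)
    assign = np.empty(n, dtype=int)
    for value in (1, 0):
        idx = np.flatnonzero(event == value)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def cv_uno_c_multi(
    design,
    survival: SurvivalData,
    taus=(730.0, 1095.0, 1825.0),
    folds: int = 5,
    iters: int = 500,
    seed: int = 0,
    per_fold_G: bool = False,
) -> dict:
    """Repeated event-stratified K-fold CV of Uno's C at several horizons.

    Each iteration fits on K-1 folds, pools the out-of-fold linear
    predictors, and computes one Uno's C per tau; by default the
    censoring KM comes from the full sample so the pooled predictors
    share one weight function (``per_fold_G`` switches to per-training-
    fold weights, averaged over folds).  Fold partitions depend only on
    (seed, iteration), so two models evaluated under the same seed use
    identical folds.
    """
    X = design.df if isinstance(design, DesignMatrix) else pd.DataFrame(design)
    Xv = X.to_numpy(dtype=float)
    n = len(survival)
    if survival.n_events < folds:
        raise ValueError("need at least one event per fold")
    rng = rng_for(seed, "cv_folds")
    values = {float(tau): np.empty(iters) for tau in taus}
    redrawn = 0
    it = 0
    attempts = 0
    while it < iters:
        attempts += 1
        if attempts > 10 * iters:
            raise ValueError("too many failed cross-validation iterations")
        assign = _stratified_folds(survival.event, folds, rng)
        oof = np.empty(n)
        ok = True
        for f in range(folds):
            train = assign != f
            fit = fit_cox(
                pd.DataFrame(Xv[train], columns=X.columns), survival.subset(train)
            )
            if not fit.converged:
                ok = False
                break
            oof[~train] = Xv[~train] @ fit.beta.to_numpy()
        if not ok:
            redrawn += 1
            continue
        try:
            for tau in taus:
                if per_fold_G:
                    cs = []
                    for f in range(folds):
                        test = assign == f
                        cs.append(
                            uno_c(
                                survival.subset(assign != f),
                                oof[test],
                                survival.subset(test),
                                tau,
                            ).c
                        )
                    values[float(tau)][it] = float(np.mean(cs))
                else:
                    values[float(tau)][it] = uno_c(survival, oof, survival, tau).c
        except ValueError:
            redrawn += 1
            continue
        it += 1
    return {
        tau: CVCResult(
            tau=tau,
            iteration_values=vals,
            mean=float(vals.mean()),
            fold_count=folds,
            seed=seed,
            n_redrawn=redrawn,
        )
        for tau, vals in values.items()
    }


def cv_uno_c(
    design,
    survival: SurvivalData,
    tau: float,
    folds: int = 5,
    iters: int = 500,
    seed: int = 0,
) -> CVCResult:
    return cv_uno_c_multi(design, survival, taus=(tau,), folds=folds, iters=iters, seed=seed)[
        float(tau)
    ]


# ---------------------------------------------------------------------------
# model validity tests


@dataclass
class PHTestResult:
    per_covariate: pd.DataFrame  # columns chi2, p
    global_chi2: float
    global_df: int
    global_p: float


def _schoenfeld_residuals(data: _CoxData, beta: np.ndarray):
    """Efron Schoenfeld residuals per event, with event times."""
    eta = data.Xa @ beta
    w = np.exp(eta - eta.max())
    wd = w[::-1]
    Xd = data.Xa[::-1]
    c0 = np.cumsum(wd)
    c1 = np.cumsum(wd[:, None] * Xd, axis=0)
    S0 = c0[data.risk_counts - 1]
    S1 = c1[data.risk_counts - 1]
    resid = []
    times = []
    for g in range(len(data.ev_uniq)):
        D = data.ev_counts[g]
        rows = data.event_rows[data.group_starts[g] : data.group_starts[g] + D]
        Xg = data.Xa[rows]
        wg = w[rows]
        frac = np.arange(D) / D
        M0 = S0[g] - frac * wg.sum()
        M1 = S1[g][None, :] - frac[:, None] * (wg[:, None] * Xg).sum(axis=0)[None, :]
        xbar = (M1 / M0[:, None]).mean(axis=0)
        for i in range(D):
            resid.append(Xg[i] - xbar)
            times.append(data.ev_uniq[g])
    return np.asarray(resid), np.asarray(times)


def ph_test(fit: CoxFit, design, survival: SurvivalData) -> PHTestResult:
    """Grambsch-Therneau test on scaled Schoenfeld residuals against the
    KM-transformed time scale g(t) = 1 - S_KM(t)."""
    if not fit.converged:
        raise ValueError("PH test requires a converged fit")
    X = design.df if isinstance(design, DesignMatrix) else pd.DataFrame(design)
    Xv = X[fit.beta.index].to_numpy(dtype=float)
    data = _CoxData(Xv, survival.time, survival.event)
    resid, ev_times = _schoenfeld_residuals(data, fit.beta.to_numpy())
    d = resid.shape[0]

    # KM transform of the event times (survival KM of the data themselves)
    t = survival.time
    e = survival.event
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    uniq, start = np.unique(ts, return_index=True)
    at_risk = len(ts) - start
    n_dead = np.add.reduceat(es, start)
    surv = np.cumprod(1.0 - n_dead / at_risk)
    idx = np.searchsorted(uniq, ev_times, side="right") - 1
    g = 1.0 - surv[idx]
    gc = g - g.mean()

    I = fit.info.to_numpy()
    u = gc @ resid  # p-vector
    Iinv = np.linalg.inv(I)
    ssq = float((gc**2).sum())
    global_chi2 = float(d / ssq * (u @ Iinv @ u))
    global_df = len(fit.beta)
    global_p = float(stats.chi2.sf(global_chi2, global_df))
    v = Iinv @ u
    per_chi2 = d * v**2 / (np.diag(Iinv) * ssq)
    per = pd.DataFrame(
        {"chi2": per_chi2, "p": stats.chi2.sf(per_chi2, 1)}, index=fit.beta.index
    )
    return PHTestResult(per, global_chi2, global_df, global_p)


@dataclass
class ModelTests:
    lrt_stat: float
    lrt_p: float
    score_stat: float
    score_p: float
    wald_stat: float
    wald_p: float
    df: int


def model_tests(fit: CoxFit) -> ModelTests:
    """Global likelihood-ratio, score and Wald tests of the full
    coefficient vector."""
    if not fit.converged:
        raise ValueError("model tests require a converged fit")
    df = fit.df
    lrt = max(0.0, 2.0 * (fit.loglik_full - fit.loglik_null))
    beta = fit.beta.to_numpy()
    wald = float(beta @ fit.info.to_numpy() @ beta)
    return ModelTests(
        lrt_stat=lrt,
        lrt_p=float(stats.chi2.sf(lrt, df)),
        score_stat=fit.score_chi2,
        score_p=float(stats.chi2.sf(fit.score_chi2, df)),
        wald_stat=wald,
        wald_p=float(stats.chi2.sf(wald, df)),
        df=df,
    )


def lrt_nested(full: CoxFit, reduced: CoxFit) -> float:
    """p-value of the likelihood-ratio test of nested Cox models."""
    if not (full.converged and reduced.converged):
        raise ValueError("both fits must have converged")
    if not set(reduced.beta.index).issubset(full.beta.index):
        raise ValueError("reduced model's columns are not a subset of the full model's")
    if full.n != reduced.n:
        raise ValueError("models were fit on different sample counts")
    df = full.df - reduced.df
    if df == 0:
        return 1.0
    stat = max(0.0, 2.0 * (full.loglik_full - reduced.loglik_full))
    return float(stats.chi2.sf(stat, df))
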