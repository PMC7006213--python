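"""Independent brute-force reference implementations used only by tests.

Each oracle is deliberately written in the most literal way possible
(pure-Python loops, textbook formulas) and shares no code with the
package implementations it checks.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# naive O(n^3) agglomerative clustering


def _lw(linkage, di_h, dj_h, dij, ni, nj, nh):
    if linkage == "single":
        return min(di_h, dj_h)
    if linkage == "complete":
        return max(di_h, dj_h)
    if linkage == "average":
        return (ni * di_h + nj * dj_h) / (ni + nj)
    if linkage == "mcquitty":
        return 0.5 * di_h + 0.5 * dj_h
    if linkage == "median":
        return 0.5 * di_h + 0.5 * dj_h - 0.25 * dij
    if linkage == "centroid":
        s = ni + nj
        return (ni * di_h + nj * dj_h) / s - (ni * nj * dij) / (s * s)
    if linkage in ("ward_d", "ward_d2"):
        s = ni + nj + nh
        return ((ni + nh) * di_h + (nj + nh) * dj_h - nh * dij) / s
    raise ValueError(linkage)


def naive_agglomerate(D: np.ndarray, linkage: str):
    """Literal agglomeration: scan all active pairs, merge the closest
    (ties: smallest pair of creation-order ids), update distances with
    the Lance-Williams formula.  Returns the merge list
    [(left, right, height)] with internal ids n, n+1, ...."""
    n = D.shape[0]
    squared = linkage in ("ward_d2", "median", "centroid")
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j] ** 2 if squared else D[i, j]
    members = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for (i, j), d in dist.items():
            if best is None or d < best[0] or (d == best[0] and (i, j) < best[1:]):
                best = (d, i, j)
        d, i, j = best
        height = np.sqrt(max(d, 0.0)) if squared else d
        merges.append((i, j, height))
        ni, nj = len(members[i]), len(members[j])
        new = next_id
        next_id += 1
        for h in list(members):
            if h in (i, j):
                continue
            a, b = (i, h) if i < h else (h, i)
            c, e = (j, h) if j < h else (h, j)
            dist[(h, new)] = _lw(linkage, dist[(a, b)], dist[(c, e)], d, ni, nj, len(members[h]))
        members[new] = members[i] + members[j]
        for h in (i, j):
            for key in list(dist):
                if h in key:
                    del dist[key]
            del members[h]
    return merges


def naive_cut(merges, n, k):
    """Partition after n-k merges; labels 1..k by first sample appearance."""
    groups = {i: [i] for i in range(n)}
    for s in range(n - k):
        i, j, _ = merges[s]
        groups[n + s] = groups.pop(i) + groups.pop(j)
    sample_to_group = {}
    for g_idx, samples in enumerate(groups.values()):
        for s in samples:
            sample_to_group[s] = g_idx
    relabel = {}
    out = np.zeros(n, dtype=int)
    for s in range(n):
        g = sample_to_group[s]
        if g not in relabel:
            relabel[g] = len(relabel) + 1
        out[s] = relabel[g]
    return out


# ---------------------------------------------------------------------------
# concordance oracles


def harrell_oracle(risk, time, event):
    """Exhaustive pair enumeration of Harrell's C."""
    n = len(risk)
    credit = 0.0
    usable = 0
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if time[j] > time[i]:
                usable += 1
                if risk[i] > risk[j]:
                    credit += 1.0
                elif risk[i] == risk[j]:
                    credit += 0.5
    if usable == 0:
        return None
    return credit / usable, usable


def censoring_km_oracle(time, event):
    """G(t-) as an explicit product over censoring times strictly < t."""
    def G_before(t):
        out = 1.0
        for u in sorted(set(time)):
            if u >= t:
                break
            at_risk = sum(1 for v in time if v >= u)
            n_cens = sum(1 for v, e in zip(time, event) if v == u and e == 0)
            out *= 1.0 - n_cens / at_risk
        return out
    return G_before


def uno_oracle(train_time, train_event, risk, time, event, tau):
    """Literal double-loop IPCW concordance with KM weights."""
    G = censoring_km_oracle(train_time, train_event)
    num = 0.0
    den = 0.0
    for i in range(len(risk)):
        if event[i] != 1 or time[i] >= tau:
            continue
        for j in range(len(risk)):
            if time[j] <= time[i]:
                continue
            w = G(time[i]) ** -2
            den += w
            if risk[i] > risk[j]:
                num += w
            elif risk[i] == risk[j]:
                num += 0.5 * w
    return num / den if den > 0 else None


# ---------------------------------------------------------------------------
# log-rank


def logrank_statistic(time, event, group):
    """Two-group log-rank chi-square, textbook O-E/V form."""
    times = sorted({t for t, e in zip(time, event) if e == 1})
    O_minus_E = 0.0
    V = 0.0
    for t in times:
        at_risk = [(ti >= t) for ti in time]
        n_tot = sum(at_risk)
        n1 = sum(1 for r, g in zip(at_risk, group) if r and g == 1)
        d_tot = sum(1 for ti, e in zip(time, event) if ti == t and e == 1)
        d1 = sum(1 for ti, e, g in zip(time, event, group) if ti == t and e == 1 and g == 1)
        if n_tot < 2:
            continue
        e1 = d_tot * n1 / n_tot
        v = d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
        O_minus_E += d1 - e1
        V += v
    return O_minus_E**2 / V if V > 0 else 0.0
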