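"""Numba-jitted inner loops for tree growth and prediction.

Everything here works on flat arrays; the object-facing API lives in
``tree.py`` and ``forest.py``.  Trees are stored as parallel arrays indexed
by node id in breadth-first creation order (node 0 is the root; a leaf has
``feature == -1``).

Numerical conventions shared with the pure-Python layer (and with the exact
test oracle): split score for a candidate with left sum ``S_L`` and counts
``(k, m-k)`` is ``S_L^2/k + S_R^2/(m-k)``; the SSE reduction is that score
minus ``S^2/m``; thresholds sit at midpoints of adjacent distinct sorted
feature values (nudged down to the lower value if the midpoint rounds up to
the upper one, so routing by ``x <= threshold`` reproduces the enumerated
partition exactly); percentiles are type 7.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "best_split_arrays",
    "grow_arrays",
    "predict_arrays",
    "population_variance",
    "sorted_percentile",
]


@njit(cache=True)
def _pct_sorted(ys: np.ndarray, q: float) -> float:
    """Type-7 percentile of an already-sorted vector, q in [0, 100]."""
    m = ys.shape[0]
    h = (m - 1) * q / 100.0
    lo = int(np.floor(h))
    if lo >= m - 1:
        return ys[m - 1]
    frac = h - lo
    return ys[lo] + frac * (ys[lo + 1] - ys[lo])


@njit(cache=True)
def sorted_percentile(ys: np.ndarray, q: float) -> float:
    """Type-7 percentile of a sorted vector; the dataset summaries use this
    same routine so node-vs-total comparisons at theta = 1 are exact."""
    return _pct_sorted(ys, q)


@njit(cache=True)
def population_variance(y: np.ndarray) -> float:
    """Two-pass population variance, accumulated in the same order tree
    growth accumulates it."""
    m = y.shape[0]
    s = 0.0
    for i in range(m):
        s += y[i]
    mean = s / m
    ss = 0.0
    for i in range(m):
        d = y[i] - mean
        ss += d * d
    return ss / m


@njit(cache=True)
def best_split_arrays(X, y, idx, start, end, feats, min_leaf):
    """Best valid split of the node holding rows ``idx[start:end]``.

    Scans features in the given order (callers pass them ascending) and
    thresholds in ascending order, keeping the first strictly-better score —
    i.e. ties break toward the lowest feature index, then the smallest
    threshold.  "Better" means exceeding the incumbent by a small relative
    tolerance, so candidates whose scores are mathematically equal but land
    a rounding error apart still tie and the lexicographic break applies.
    Returns ``(feature, threshold, score, left_n)`` with ``feature == -1``
    when no candidate obeys the leaf-size constraint.
    """
    m = end - start
    s_tot = 0.0
    for i in range(start, end):
        s_tot += y[idx[i]]
    best_f = -1
    best_thr = 0.0
    best_score = -np.inf
    best_k = 0
    xv = np.empty(m)
    for fi in range(feats.shape[0]):
        f = feats[fi]
        for i in range(m):
            xv[i] = X[idx[start + i], f]
        order = np.argsort(xv, kind="mergesort")
        s_left = 0.0
        for i in range(m - 1):
            s_left += y[idx[start + order[i]]]
            xa = xv[order[i]]
            xb = xv[order[i + 1]]
            if xa < xb:
                k = i + 1
                if k >= min_leaf and (m - k) >= min_leaf:
                    s_right = s_tot - s_left
                    score = s_left * s_left / k + s_right * s_right / (m - k)
                    if best_f < 0 or score > best_score + 1e-10 * (1.0 + np.abs(best_score)):
                        thr = 0.5 * (xa + xb)
                        if thr >= xb:  # adjacent floats: keep routing exact
                            thr = xa
                        best_score = score
                        best_f = f
                        best_thr = thr
                        best_k = k
    return best_f, best_thr, best_score, best_k


@njit(cache=True)
def grow_arrays(
    X,
    y,
    theta_var,
    tot_var,
    theta_rng,
    tot_rng,
    theta_icr,
    tot_icr,
    q_lo,
    q_hi,
    min_parent,
    min_leaf,
    mtry,
    maxnodes,
    seed,
):
    """Grow one regression tree breadth-first on the sample ``(X, y)``.

    Disabled dispersion rules are encoded as negative thetas and a disabled
    parent-size rule as ``min_parent = 0``.  ``maxnodes`` caps the number of
    terminal nodes: a node is made a leaf if splitting it would push the
    prospective terminal count above the cap.  The mtry feature draw uses
    numba's own RNG seeded with ``seed``; when ``mtry == p`` no random
    numbers are consumed.
    """
    m0, p = X.shape
    cap = 2 * min(maxnodes, m0) + 2
    feature = np.full(cap, -1, dtype=np.int64)
    threshold = np.zeros(cap)
    left = np.full(cap, -1, dtype=np.int64)
    right = np.full(cap, -1, dtype=np.int64)
    value = np.zeros(cap)
    nnode = np.zeros(cap, dtype=np.int64)
    node_start = np.zeros(cap, dtype=np.int64)
    node_end = np.zeros(cap, dtype=np.int64)

    if mtry < p:
        np.random.seed(seed)

    idx = np.arange(m0)
    buf = np.empty(m0, dtype=np.int64)
    feats_all = np.arange(p)
    featbuf = np.arange(p)

    node_end[0] = m0
    n_nodes = 1
    n_internal = 0
    head = 0
    while head < n_nodes:
        nd = head
        head += 1
        start = node_start[nd]
        end = node_end[nd]
        mm = end - start
        s = 0.0
        ymin = y[idx[start]]
        ymax = ymin
        for i in range(start, end):
            v = y[idx[i]]
            s += v
            if v < ymin:
                ymin = v
            if v > ymax:
                ymax = v
        mean = s / mm
        value[nd] = mean
        nnode[nd] = mm

        halt = mm < 2
        if not halt and min_parent > 0 and mm < min_parent:
            halt = True
        if not halt and theta_var >= 0.0:
            ss = 0.0
            for i in range(start, end):
                d = y[idx[i]] - mean
                ss += d * d
            if ss / mm <= theta_var * tot_var:
                halt = True
        if not halt and theta_rng >= 0.0:
            if ymax - ymin <= theta_rng * tot_rng:
                halt = True
        if not halt and theta_icr >= 0.0:
            ys = np.empty(mm)
            for i in range(mm):
                ys[i] = y[idx[start + i]]
            ys.sort()
            if _pct_sorted(ys, q_hi) - _pct_sorted(ys, q_lo) <= theta_icr * tot_icr:
                halt = True
        if not halt and ymin == ymax:
            halt = True
        if not halt and (n_nodes - n_internal) + 1 > maxnodes:
            halt = True
        if halt:
            continue

        if mtry < p:
            for j in range(p):
                featbuf[j] = j
            for i in range(mtry):
                j = i + np.random.randint(0, p - i)
                t = featbuf[i]
                featbuf[i] = featbuf[j]
                featbuf[j] = t
            cand = np.sort(featbuf[:mtry])
        else:
            cand = feats_all

        bf, bthr, bscore, bk = best_split_arrays(X, y, idx, start, end, cand, min_leaf)
        if bf < 0:
            continue
        # require an SSE reduction clearly above rounding noise
        parent_score = s * s / mm
        if bscore - parent_score <= 1e-10 * (1.0 + parent_score):
            continue

        nl = 0
        nr = 0
        for i in range(start, end):
            r = idx[i]
            if X[r, bf] <= bthr:
                buf[nl] = r
                nl += 1
            else:
                buf[bk + nr] = r
                nr += 1
        for i in range(mm):
            idx[start + i] = buf[i]

        feature[nd] = bf
        threshold[nd] = bthr
        left[nd] = n_nodes
        right[nd] = n_nodes + 1
        node_start[n_nodes] = start
        node_end[n_nodes] = start + bk
        node_start[n_nodes + 1] = start + bk
        node_end[n_nodes + 1] = end
        n_nodes += 2
        n_internal += 1

    return (
        feature[:n_nodes].copy(),
        threshold[:n_nodes].copy(),
        left[:n_nodes].copy(),
        right[:n_nodes].copy(),
        value[:n_nodes].copy(),
        nnode[:n_nodes].copy(),
    )


@njit(cache=True)
def predict_arrays(feature, threshold, left, right, value, X):
    """Route each row of X to its leaf (``x <= threshold`` goes left)."""
    n = X.shape[0]
    out = np.empty(n)
    for i in range(n):
        nd = 0
        while feature[nd] >= 0:
            if X[i, feature[nd]] <= threshold[nd]:
                nd = left[nd]
            else:
                nd = right[nd]
        out[i] = value[nd]
    return out
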