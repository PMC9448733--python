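"""Independent exhaustive-search CART oracle used by the test suite.

Enumerates every candidate split of every feature and scores it in exact
rational arithmetic (``fractions.Fraction``), so the best split and its
tie-breaks (lowest feature index, then smallest threshold, among the
maximal SSE reductions) are decided without floating-point error.  Growth
is breadth-first with the same halting semantics as the package kernel:
nodes smaller than 2 (or than the minimum parent size) halt, exactly
constant nodes halt, the terminal-node cap is enforced before splitting,
and a split must strictly reduce the SSE and respect the minimum leaf size.
Only the size-based rules are supported — enough for node-for-node
equivalence sweeps with ``mtry = p``.
"""

from __future__ import annotations

from fractions import Fraction


def oracle_best_split(X, y, rows, min_leaf=1):
    """Exact best split of the node holding ``rows``; None if no valid one.

    Returns ``(feature, threshold, left_rows, right_rows)`` with rows kept
    in their incoming order (left block first), or None.
    """
    m = len(rows)
    if m < 2:
        return None
    p = len(X[0])
    s_tot = sum(Fraction(y[i]) for i in rows)
    best = None  # (score, feature, threshold, left, right)
    for f in range(p):
        vals = sorted({X[i][f] for i in rows})
        for a, b in zip(vals, vals[1:]):
            thr = 0.5 * (a + b)
            if thr >= b:  # adjacent floats
                thr = a
            left = [i for i in rows if X[i][f] <= thr]
            right = [i for i in rows if X[i][f] > thr]
            if min(len(left), len(right)) < min_leaf:
                continue
            s_l = sum(Fraction(y[i]) for i in left)
            s_r = s_tot - s_l
            score = s_l * s_l / len(left) + s_r * s_r / len(right)
            if best is None or score > best[0]:
                best = (score, f, thr, left, right)
    if best is None:
        return None
    if best[0] - s_tot * s_tot / m <= 0:
        return None
    return best[1], best[2], best[3], best[4]


def oracle_grow(X, y, min_parent=0, min_leaf=1, maxnodes=10**9):
    """Exhaustive breadth-first tree; returns nodes in creation order.

    Each node is a dict with keys feature (-1 for leaves), threshold, left,
    right, n and mean (exact Fraction).
    """
    nodes = [{"rows": list(range(len(y)))}]
    head = 0
    n_internal = 0
    while head < len(nodes):
        nd = nodes[head]
        head += 1
        rows = nd["rows"]
        m = len(rows)
        nd["n"] = m
        nd["mean"] = sum(Fraction(y[i]) for i in rows) / m
        nd["feature"] = -1
        nd["threshold"] = 0.0
        halt = m < 2 or (min_parent > 0 and m < min_parent)
        if not halt and len({y[i] for i in rows}) == 1:
            halt = True
        if not halt and (len(nodes) - n_internal) + 1 > maxnodes:
            halt = True
        if halt:
            continue
        best = oracle_best_split(X, y, rows, min_leaf)
        if best is None:
            continue
        f, thr, left_rows, right_rows = best
        nd["feature"] = f
        nd["threshold"] = thr
        nd["left"] = len(nodes)
        nd["right"] = len(nodes) + 1
        nodes.append({"rows": left_rows})
        nodes.append({"rows": right_rows})
        n_internal += 1
    return nodes


def assert_tree_matches_oracle(tree, oracle_nodes, tol=1e-9):
    """Node-for-node comparison of a package tree with the oracle's."""
    assert tree.n_nodes == len(oracle_nodes), (
        f"node count {tree.n_nodes} != oracle {len(oracle_nodes)}"
    )
    for i, nd in enumerate(oracle_nodes):
        assert int(tree.feature[i]) == nd["feature"], f"node {i}: split feature differs"
        if nd["feature"] >= 0:
            assert float(tree.threshold[i]) == nd["threshold"], f"node {i}: threshold differs"
            assert int(tree.left[i]) == nd["left"] and int(tree.right[i]) == nd["right"]
        assert int(tree.n[i]) == nd["n"], f"node {i}: size differs"
        assert abs(float(tree.value[i]) - float(nd["mean"])) <= tol, f"node {i}: mean differs"
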