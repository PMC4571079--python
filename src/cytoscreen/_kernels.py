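"""Numba kernels for tree growth, prediction and out-of-bag importance.

Flat-array tree encoding shared by all kernels: ``feature[k] >= 0`` marks an
internal node splitting on that column at ``threshold[k]`` (left branch:
value < threshold, right branch: value >= threshold); ``feature[k] == -1``
marks a leaf whose ``value[k]`` is the class-1 fraction of its training
samples.  Node 0 is the root.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _two_sided_p(z: float) -> float:
    return math.erfc(abs(z) / _SQRT2)


@njit(cache=True)
def _perm_pvalue(x, T_obs, n1, n_perm):
    """Monte-Carlo permutation p-value for the linear statistic sum(x*y)."""
    m = x.size
    z_obs = abs(T_obs)
    hits = 0
    xs = x.copy()
    for _ in range(n_perm):
        # Fisher-Yates partial shuffle: draw n1 values without replacement
        t = 0.0
        for i in range(n1):
            j = i + np.random.randint(0, m - i)
            tmp = xs[i]
            xs[i] = xs[j]
            xs[j] = tmp
            t += xs[i]
        if abs(t) >= z_obs:
            hits += 1
    return (hits + 1.0) / (n_perm + 1.0)


@njit(cache=True)
def grow_tree(X, y, samp, mtry, alpha, min_split, min_leaf, seed, use_perm_test,
              n_perm_split):
    """Grow one conditional-inference tree on the rows listed in ``samp``.

    At each node, ``mtry`` candidate columns are drawn; each is scored by the
    standardized two-sample linear statistic of the column against the 0/1
    response (permutation mean/variance, normal approximation, two-sided).
    The node is split only if the minimal Bonferroni-adjusted p-value is
    below ``alpha``; the winning column's split point is the observed value
    maximizing the standardized two-sample statistic of the induced
    partition.
    """
    np.random.seed(seed)
    n = samp.size
    p = X.shape[1]
    cap = 2 * n + 1
    feature = np.full(cap, -1, dtype=np.int64)
    threshold = np.zeros(cap, dtype=np.float64)
    left = np.full(cap, -1, dtype=np.int64)
    right = np.full(cap, -1, dtype=np.int64)
    value = np.zeros(cap, dtype=np.float64)

    buf = samp.copy()
    tmp = np.empty(n, dtype=np.int64)

    stack_node = np.empty(cap, dtype=np.int64)
    stack_lo = np.empty(cap, dtype=np.int64)
    stack_hi = np.empty(cap, dtype=np.int64)
    top = 0
    stack_node[top] = 0
    stack_lo[top] = 0
    stack_hi[top] = n
    top += 1
    n_nodes = 1

    m_eff = min(mtry, p)

    while top > 0:
        top -= 1
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        m = hi - lo

        s1 = 0.0
        for i in range(lo, hi):
            s1 += y[buf[i]]
        value[node] = s1 / m

        if m < min_split or s1 == 0.0 or s1 == m:
            continue

        ybar = s1 / m
        vary = ybar * (1.0 - ybar)  # population variance of 0/1 labels
        n1 = int(s1)

        cand = np.random.permutation(p)[:m_eff]
        best_p = 2.0
        best_j = -1
        n_tested = 0
        for c in range(m_eff):
            j = cand[c]
            T = 0.0
            sx = 0.0
            sxx = 0.0
            for i in range(lo, hi):
                v = X[buf[i], j]
                T += v * y[buf[i]]
                sx += v
                sxx += v * v
            xbar = sx / m
            varx = sxx / m - xbar * xbar
            if varx <= 1e-300:
                continue
            n_tested += 1
            var_T = n1 * (m - n1) / (m - 1.0) * varx
            z = (T - n1 * xbar) / math.sqrt(var_T)
            if use_perm_test and m <= 30:
                xc = np.empty(m, dtype=np.float64)
                for i in range(m):
                    xc[i] = X[buf[lo + i], j] - xbar
                pj = _perm_pvalue(xc, T - n1 * xbar, n1, n_perm_split)
            else:
                pj = _two_sided_p(z)
            if pj < best_p:
                best_p = pj
                best_j = j

        if best_j < 0:
            continue
        p_adj = best_p * n_tested
        if p_adj > 1.0:
            p_adj = 1.0
        if p_adj >= alpha:
            continue

        # split-point search on the selected column
        xv = np.empty(m, dtype=np.float64)
        yv = np.empty(m, dtype=np.float64)
        for i in range(m):
            xv[i] = X[buf[lo + i], best_j]
            yv[i] = y[buf[lo + i]]
        order = np.argsort(xv)
        best_stat = -1.0
        best_pos = -1
        csum = 0.0
        for k in range(m - 1):
            csum += yv[order[k]]
            nl = k + 1
            if nl < min_leaf or (m - nl) < min_leaf:
                continue
            if xv[order[k]] == xv[order[k + 1]]:
                continue
            var_c = nl * (m - nl) / (m - 1.0) * vary
            if var_c <= 0.0:
                continue
            stat = abs(csum - nl * ybar) / math.sqrt(var_c)
            if stat > best_stat:
                best_stat = stat
                best_pos = k
        if best_pos < 0:
            continue
        cut = xv[order[best_pos + 1]]  # left: x < cut (an observed value)

        # stable in-place partition of buf[lo:hi]
        nl = 0
        for i in range(lo, hi):
            if X[buf[i], best_j] < cut:
                tmp[nl] = buf[i]
                nl += 1
        nr = nl
        for i in range(lo, hi):
            if not (X[buf[i], best_j] < cut):
                tmp[nr] = buf[i]
                nr += 1
        for i in range(m):
            buf[lo + i] = tmp[i]

        lchild = n_nodes
        rchild = n_nodes + 1
        n_nodes += 2
        feature[node] = best_j
        threshold[node] = cut
        left[node] = lchild
        right[node] = rchild

        stack_node[top] = lchild
        stack_lo[top] = lo
        stack_hi[top] = lo + nl
        top += 1
        stack_node[top] = rchild
        stack_lo[top] = lo + nl
        stack_hi[top] = hi
        top += 1

    return (feature[:n_nodes], threshold[:n_nodes], left[:n_nodes],
            right[:n_nodes], value[:n_nodes])


@njit(cache=True)
def predict_tree(X, rows, feature, threshold, left, right, value):
    """Leaf class-1 fraction for each row index in ``rows``."""
    out = np.empty(rows.size, dtype=np.float64)
    for i in range(rows.size):
        node = 0
        while feature[node] >= 0:
            if X[rows[i], feature[node]] < threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = value[node]
    return out


@njit(cache=True)
def _oob_accuracy_permuted(X, y, oob, feature, threshold, left, right, value,
                           var, perm):
    """OOB accuracy with column ``var`` read through the permutation ``perm``
    (perm[i] gives the OOB row whose value substitutes for row oob[i])."""
    correct = 0
    for i in range(oob.size):
        node = 0
        while feature[node] >= 0:
            f = feature[node]
            if f == var:
                v = X[oob[perm[i]], f]
            else:
                v = X[oob[i], f]
            if v < threshold[node]:
                node = left[node]
            else:
                node = right[node]
        pred = 1 if value[node] > 0.5 else 0
        if pred == y[oob[i]]:
            correct += 1
    return correct / oob.size


@njit(cache=True)
def tree_permutation_importance(X, y, oob, feature, threshold, left, right,
                                value, n_vars, seed):
    """Per-variable OOB accuracy drop for one tree (0 for unused columns)."""
    np.random.seed(seed)
    imp = np.zeros(n_vars, dtype=np.float64)
    if oob.size == 0:
        return imp
    identity = np.arange(oob.size)
    acc0 = _oob_accuracy_permuted(X, y, oob, feature, threshold, left, right,
                                  value, -1, identity)
    used = np.zeros(n_vars, dtype=np.bool_)
    for k in range(feature.size):
        if feature[k] >= 0:
            used[feature[k]] = True
    for v in range(n_vars):
        if not used[v]:
            continue
        perm = np.random.permutation(oob.size)
        acc_v = _oob_accuracy_permuted(X, y, oob, feature, threshold, left,
                                       right, value, v, perm)
        imp[v] = acc0 - acc_v
    return imp
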