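"""Compiled random-forest importance backend for network inference.

Implements the classic tree-ensemble regulator ranking: for one target,
grow ``n_trees`` CART regression trees on bootstrap samples, choosing at
every node the best variance-reducing split among K randomly drawn
candidate regulators, and accumulate each regulator's total
sum-of-squares reduction over all nodes and trees.  With K = sqrt(p)
this is the standard random-forest variant of the approach; importances
are later normalised per target.

The implementation is deliberately small and fully deterministic given
a seed (xorshift RNG embedded in the kernel), and is numba-compiled
because the permutation null recomputes importances hundreds of times.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MAX_U64 = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _xorshift(state: np.uint64) -> np.uint64:
    state ^= state << np.uint64(13)
    state &= _MAX_U64
    state ^= state >> np.uint64(7)
    state ^= state << np.uint64(17)
    state &= _MAX_U64
    return state


@njit(cache=True)
def _forest_importance(x: np.ndarray, y: np.ndarray, n_trees: int, k_features: int,
                       seed: np.uint64) -> np.ndarray:
    """Total impurity (SS) reduction per feature over a bootstrap forest."""
    n, p = x.shape
    importance = np.zeros(p)
    state = seed | np.uint64(1)

    # preallocated work arrays
    boot = np.empty(n, np.int64)
    stack_lo = np.empty(4 * n + 8, np.int64)
    stack_hi = np.empty(4 * n + 8, np.int64)
    idx = np.empty(n, np.int64)
    feat_perm = np.empty(p, np.int64)
    xv = np.empty(n)
    yv = np.empty(n)

    for _tree in range(n_trees):
        for i in range(n):
            state = _xorshift(state)
            boot[i] = np.int64(state % np.uint64(n))
        for i in range(n):
            idx[i] = boot[i]
        top = 0
        stack_lo[top] = 0
        stack_hi[top] = n
        top += 1
        while top > 0:
            top -= 1
            lo = stack_lo[top]
            hi = stack_hi[top]
            m = hi - lo
            if m < 2:
                continue
            # node statistics
            s = 0.0
            s2 = 0.0
            for i in range(lo, hi):
                v = y[idx[i]]
                s += v
                s2 += v * v
            node_ss = s2 - s * s / m
            if node_ss <= 1e-12:
                continue
            # draw K candidate features (partial Fisher-Yates)
            for j in range(p):
                feat_perm[j] = j
            kk = k_features if k_features < p else p
            for j in range(kk):
                state = _xorshift(state)
                swap = j + np.int64(state % np.uint64(p - j))
                tmp = feat_perm[j]
                feat_perm[j] = feat_perm[swap]
                feat_perm[swap] = tmp

            best_gain = 0.0
            best_feat = -1
            best_thresh = 0.0
            for j in range(kk):
                f = feat_perm[j]
                for i in range(m):
                    xv[i] = x[idx[lo + i], f]
                    yv[i] = y[idx[lo + i]]
                order = np.argsort(xv[:m], kind="mergesort")
                # prefix scan over sorted order
                ls = 0.0
                ls2 = 0.0
                cnt = 0
                for oi in range(m - 1):
                    v = yv[order[oi]]
                    ls += v
                    ls2 += v * v
                    cnt += 1
                    xa = xv[order[oi]]
                    xb = xv[order[oi + 1]]
                    if xb <= xa:
                        continue
                    rs = s - ls
                    rc = m - cnt
                    ss_l = ls2 - ls * ls / cnt
                    ss_r = (s2 - ls2) - rs * rs / rc
                    gain = node_ss - ss_l - ss_r
                    if gain > best_gain:
                        best_gain = gain
                        best_feat = f
                        best_thresh = 0.5 * (xa + xb)
            if best_feat < 0:
                continue
            importance[best_feat] += best_gain
            # partition idx[lo:hi] in place around the threshold
            left = lo
            right = hi - 1
            while left <= right:
                if x[idx[left], best_feat] <= best_thresh:
                    left += 1
                else:
                    tmp = idx[left]
                    idx[left] = idx[right]
                    idx[right] = tmp
                    right -= 1
            stack_lo[top] = lo
            stack_hi[top] = left
            top += 1
            stack_lo[top] = left
            stack_hi[top] = hi
            top += 1
    return importance


def forest_importance(
    x: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    k_features: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-feature total impurity reduction for one regression target."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if x.ndim != 2 or y.ndim != 1 or x.shape[0] != y.size:
        raise ValueError("x must be (n_samples, n_features) matching y")
    p = x.shape[1]
    if k_features is None:
        k_features = max(1, int(round(np.sqrt(p))))
    return _forest_importance(x, y, int(n_trees), int(k_features),
                              np.uint64(seed & 0xFFFFFFFFFFFFFFFF))
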