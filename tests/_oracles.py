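"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (loops, exhaustive enumeration) and
shares no code with the package's computational paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Entrywise (A+I)_ij / sqrt(d_i d_j) with loops."""
    m = A.shape[0]
    At = A + np.eye(m)
    d = [sum(At[i, j] for j in range(m)) for i in range(m)]
    S = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            S[i, j] = At[i, j] / np.sqrt(d[i] * d[j])
    return S


def naive_layer(S: np.ndarray, H: np.ndarray, W: np.ndarray,
                alpha: float = 0.0, relu: bool = True) -> np.ndarray:
    """Per-node message passing: out_i = act(sum_j S_ij h_j + alpha h_i) W."""
    m, d_in = H.shape
    d_out = W.shape[1]
    out = np.zeros((m, d_out))
    for i in range(m):
        agg = np.zeros(d_in)
        for j in range(m):
            agg += S[i, j] * H[j]
        agg += alpha * H[i]
        for k in range(d_out):
            val = sum(agg[t] * W[t, k] for t in range(d_in))
            out[i, k] = max(val, 0.0) if relu else val
    return out


def brute_confusion(preds: np.ndarray, labels: np.ndarray) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) counted one subject at a time; positive class is 1."""
    tp = fp = tn = fn = 0
    for p, y in zip(preds, labels):
        if p == 1 and y == 1:
            tp += 1
        elif p == 1 and y == 0:
            fp += 1
        elif p == 0 and y == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def exhaustive_betweenness(A: np.ndarray) -> np.ndarray:
    """Unnormalized weighted betweenness by enumerating all simple paths.

    Edge length is 1/weight; for each ordered node pair the shortest-path
    length is found by exhaustive enumeration and every minimal path
    contributes its fraction to intermediate nodes. Only feasible for m <= 7.
    """
    m = A.shape[0]
    bc = np.zeros(m)
    nodes = range(m)
    for s in nodes:
        for t in nodes:
            if t <= s:
                continue
            best = np.inf
            minimal: list[tuple[int, ...]] = []
            others = [v for v in nodes if v not in (s, t)]
            for r in range(len(others) + 1):
                for mid in itertools.permutations(others, r):
                    path = (s, *mid, t)
                    length = 0.0
                    ok = True
                    for u, v in zip(path[:-1], path[1:]):
                        if A[u, v] <= 0:
                            ok = False
                            break
                        length += 1.0 / A[u, v]
                    if not ok:
                        continue
                    if length < best - 1e-12:
                        best = length
                        minimal = [path]
                    elif abs(length - best) <= 1e-12:
                        minimal.append(path)
            if not minimal:
                continue
            for path in minimal:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(minimal)
    return bc


def exact_wilcoxon_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments.

    Assumes no zero differences and no rank ties (continuous data).
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    w_plus = ranks[diffs > 0].sum()
    stats = []
    for signs in itertools.product((0, 1), repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats)
    p_low = np.mean(stats <= w_plus)
    p_high = np.mean(stats >= w_plus)
    return float(min(1.0, 2.0 * min(p_low, p_high)))
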