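"""Independent, loop-based reference implementations.

Literal transcriptions of the score and significance definitions using
plain Python loops and sorts — deliberately naive, sharing no code paths
with the vectorized package internals — used to pin down expected values
on small random inputs.
"""

from __future__ import annotations

import math

import numpy as np


def od_brute(x: np.ndarray, j: int, k: int) -> list[float]:
    """Outlying degree for sample j: sum of the k smallest |x_ij - x_ij'|."""
    n, m = x.shape
    out = []
    for i in range(n):
        d = sorted(abs(x[i, j] - x[i, jp]) for jp in range(m) if jp != j)
        out.append(sum(d[:k]))
    return out


def weights_brute(x: np.ndarray) -> np.ndarray:
    n, m = x.shape
    w = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            w[a, b] = math.sqrt(sum((x[i, a] - x[i, b]) ** 2 for i in range(n)))
    return w


def woda_brute(x: np.ndarray, w: np.ndarray, j: int, k: int) -> list[float]:
    """Weighted OD (a): weighted mean of the k unweighted-nearest distances.

    Neighbor order: increasing distance, ties by original sample index.
    """
    n, m = x.shape
    others = [jp for jp in range(m) if jp != j]
    out = []
    for i in range(n):
        pairs = sorted(((abs(x[i, j] - x[i, jp]), jp) for jp in others))
        nearest = pairs[:k]
        num = sum(w[j, jp] * d for d, jp in nearest)
        den = sum(w[j, jp] for _, jp in nearest)
        out.append(num / den if den > 0 else sum(d for d, _ in nearest) / k)
    return out


def wodb_brute(x: np.ndarray, w: np.ndarray, j: int, k: int) -> list[float]:
    """Weighted OD (b): weight each distance by w/sum(w), then sum the k
    smallest weighted distances. Tie order: original sample index."""
    n, m = x.shape
    others = [jp for jp in range(m) if jp != j]
    wtot = sum(w[j, jp] for jp in others)
    out = []
    for i in range(n):
        weighted = sorted(
            ((w[j, jp] * abs(x[i, j] - x[i, jp]) / wtot, jp) for jp in others)
        )
        out.append(sum(v for v, _ in weighted[:k]))
    return out


def pvalue_brute(T, g1: int) -> float:
    n = len(T)
    greater = sum(1 for i in range(n) if i != g1 and T[i] > T[g1])
    equal = sum(1 for i in range(n) if i != g1 and T[i] == T[g1])
    return (greater + 0.5 * equal) / (n - 1)


def fdr_brute(T, true_set) -> float:
    n = len(T)
    order = sorted(range(n), key=lambda i: (-T[i], i))
    S = len(true_set)
    top = order[:S]
    return sum(1 for i in top if i not in set(true_set)) / S
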