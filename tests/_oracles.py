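"""Independent brute-force reference implementations used only by tests.

Each oracle follows the written definition with explicit loops and never
shares code with the package; the suite compares the vectorized package
implementations against these.
"""

from __future__ import annotations

import math

import numpy as np


def mse_loop(g_true: np.ndarray, g_hat: np.ndarray) -> float:
    n, m = g_true.shape
    total = 0.0
    for i in range(n):
        for j in range(m):
            total += (g_true[i, j] - g_hat[i, j]) ** 2
    return total / (n * m)


def bce_loop(y: np.ndarray, p: np.ndarray, eps: float = 1e-7) -> float:
    total = 0.0
    for i in range(len(y)):
        pi = min(max(p[i], eps), 1 - eps)
        total += y[i] * math.log(pi) + (1 - y[i]) * math.log(1 - pi)
    return -total / len(y)


def spatial_loop(preds: np.ndarray, labels: np.ndarray, neighbors: list) -> float:
    """Literal definition: over all directed (central, neighbor) pairs with
    matching annotation, mean-over-genes squared prediction difference,
    divided by the number K of such pairs (0 when K = 0)."""
    n, m = preds.shape
    k = 0
    total = 0.0
    for i in range(n):
        for j in neighbors[i]:
            if labels[i] == labels[j]:
                k += 1
                acc = 0.0
                for g in range(m):
                    acc += (preds[i, g] - preds[j, g]) ** 2
                total += acc / m
    return total / k if k else 0.0


def pearson_loop(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation of two vectors."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    sxx = sum((x[i] - mx) ** 2 for i in range(n))
    syy = sum((y[i] - my) ** 2 for i in range(n))
    return sxy / math.sqrt(sxx * syy)


def grid_neighbors_loop(rc: np.ndarray) -> list:
    """O(n^2) pairwise scan for the 3x3-window neighbor relation."""
    n = len(rc)
    out = []
    for i in range(n):
        nbrs = []
        for j in range(n):
            if i == j:
                continue
            dr = abs(int(rc[i, 0]) - int(rc[j, 0]))
            dc = abs(int(rc[i, 1]) - int(rc[j, 1]))
            if dr <= 1 and dc <= 1:
                nbrs.append(j)
        out.append(sorted(nbrs))
    return out


def finite_difference(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar f at x."""
    grad = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy()
        xm = x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        grad[idx] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return grad
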