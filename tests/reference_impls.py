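"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately naive (exhaustive enumeration, plain
double loops over textbook formulas) and shares no code with the
package, so it can serve as an independent check of the fast paths.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np


def dtw_bruteforce(x, y) -> float:
    """DTW by exhaustive recursion over all monotone warping paths
    (moves: match, insert, delete; cost = squared difference)."""
    x = list(map(float, x))
    y = list(map(float, y))

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        c = (x[i] - y[j]) ** 2
        if i == 0 and j == 0:
            return c
        prev = []
        if i > 0:
            prev.append(best(i - 1, j))
        if j > 0:
            prev.append(best(i, j - 1))
        if i > 0 and j > 0:
            prev.append(best(i - 1, j - 1))
        return c + min(prev)

    return math.sqrt(best(len(x) - 1, len(y) - 1))


def dtw_matrix_naive(X) -> np.ndarray:
    """Plain double loop of single-pair DP distances."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = _dtw_dp(X[i], X[j])
    return out


def _dtw_dp(x, y) -> float:
    nx, ny = len(x), len(y)
    D = np.full((nx + 1, ny + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, nx + 1):
        for j in range(1, ny + 1):
            c = (x[i - 1] - y[j - 1]) ** 2
            D[i, j] = c + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return math.sqrt(D[nx, ny])


# --- validity indices, straight from their definitions ----------------------


def _medoid(D, members):
    best, best_tot = None, math.inf
    for i in members:
        tot = sum(D[i, j] for j in members)
        if tot < best_tot:
            best, best_tot = i, tot
    return best


def silhouette_ref(D, labels) -> float:
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    vals = []
    for i in range(len(labels)):
        own = [j for j in range(len(labels)) if labels[j] == labels[i]]
        if len(own) == 1:
            vals.append(0.0)
            continue
        a = sum(D[i, j] for j in own if j != i) / (len(own) - 1)
        b = math.inf
        for c in uniq:
            if c == labels[i]:
                continue
            other = [j for j in range(len(labels)) if labels[j] == c]
            b = min(b, sum(D[i, j] for j in other) / len(other))
        vals.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(vals))


def dunn_ref(D, labels) -> float:
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    clusters = {c: [j for j in range(len(labels)) if labels[j] == c] for c in uniq}
    diam = max(max((D[i, j] for i in m for j in m), default=0.0) for m in clusters.values())
    sep = math.inf
    for a in range(len(uniq)):
        for b in range(a + 1, len(uniq)):
            sep = min(sep, min(D[i, j] for i in clusters[uniq[a]] for j in clusters[uniq[b]]))
    return sep / diam


def db_ref(D, labels, modified: bool = False) -> float:
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    clusters = [np.flatnonzero(labels == c).tolist() for c in uniq]
    med = [_medoid(D, m) for m in clusters]
    S = [sum(D[i, med[c]] for i in m) / len(m) for c, m in enumerate(clusters)]
    k = len(uniq)
    terms = []
    for i in range(k):
        if modified:
            num = max(S[i] + S[j] for j in range(k) if j != i)
            den = min(D[med[i], med[j]] for j in range(k) if j != i)
            terms.append(num / den)
        else:
            terms.append(max((S[i] + S[j]) / D[med[i], med[j]] for j in range(k) if j != i))
    return float(np.mean(terms))


def calinski_harabasz_ref(D, labels) -> float:
    labels = np.asarray(labels)
    n = len(labels)
    uniq = sorted(set(labels.tolist()))
    clusters = [np.flatnonzero(labels == c).tolist() for c in uniq]
    med = [_medoid(D, m) for m in clusters]
    gmed = _medoid(D, list(range(n)))
    W = sum(D[i, med[c]] ** 2 for c, m in enumerate(clusters) for i in m)
    B = sum(len(m) * D[med[c], gmed] ** 2 for c, m in enumerate(clusters))
    k = len(uniq)
    return (B / (k - 1)) / (W / (n - k))


# --- survey estimators, replicate-by-formula -------------------------------


def weighted_mean_se_ref(y, w, strata, psu):
    """Textbook Taylor-linearized ratio mean for a stratified
    with-replacement PSU design, written as explicit loops."""
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    wsum = w.sum()
    mean = float((w * y).sum() / wsum)
    z = w * (y - mean) / wsum
    var = 0.0
    for h in sorted(set(strata)):
        rows_h = [i for i in range(len(y)) if strata[i] == h]
        psus = sorted({psu[i] for i in rows_h})
        n_h = len(psus)
        totals = []
        for p in psus:
            totals.append(sum(z[i] for i in rows_h if psu[i] == p))
        tbar = sum(totals) / n_h
        var += n_h / (n_h - 1) * sum((t - tbar) ** 2 for t in totals)
    return mean, math.sqrt(var)
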