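"""Dynamic time warping distances between hourly intake profiles.

DTW aligns two sequences by a monotone warping path with moves
{match, insert, delete}; pointwise cost is the squared difference and
the reported distance is the square root of the accumulated cost, so
for perfectly aligned sequences it coincides with the Euclidean
distance.  An optional Sakoe-Chiba band restricts |i - j| <= radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DistanceMatrix:
    """Pairwise DTW distances: symmetric, non-negative, zero diagonal."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _check_band(nx: int, ny: int, band: int | None) -> None:
    if band is not None:
        if band < 0:
            raise ValueError("band radius must be >= 0")
        if abs(nx - ny) > band:
            raise ValueError(f"band {band} admits no warping path for lengths {nx},{ny}")


def dtw_distance(x, y, band: int | None = None) -> float:
    """DTW distance between two 1-D sequences (sqrt of accumulated
    squared pointwise cost along the optimal monotone path)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("sequences must be non-empty")
    _check_band(x.size, y.size, band)
    nx, ny = x.size, y.size
    prev = np.full(ny + 1, np.inf)
    prev[0] = 0.0
    for i in range(nx):
        cur = np.full(ny + 1, np.inf)
        lo = 0 if band is None else max(0, i - band)
        hi = ny if band is None else min(ny, i + band + 1)
        for j in range(lo, hi):
            c = (x[i] - y[j]) ** 2
            cur[j + 1] = c + min(prev[j + 1], cur[j], prev[j])
        prev = cur
    return float(np.sqrt(prev[ny]))


def _dtw_one_vs_many(x: np.ndarray, Y: np.ndarray, band: int | None) -> np.ndarray:
    """Accumulated-cost DTW of ``x`` against every row of ``Y``,
    vectorized over rows (the j-recursion stays sequential)."""
    m, L = Y.shape
    nx = x.size
    prev = np.full((m, L + 1), np.inf)
    prev[:, 0] = 0.0
    for i in range(nx):
        cur = np.full((m, L + 1), np.inf)
        lo = 0 if band is None else max(0, i - band)
        hi = L if band is None else min(L, i + band + 1)
        for j in range(lo, hi):
            c = (x[i] - Y[:, j]) ** 2
            cur[:, j + 1] = c + np.minimum(np.minimum(prev[:, j + 1], cur[:, j]), prev[:, j])
        prev = cur
    return np.sqrt(prev[:, L])


def dtw_matrix(profiles, ids=None, band: int | None = None) -> DistanceMatrix:
    """Pairwise DTW over equal-length sequences (rows of ``profiles``).

    Each pair is computed once; the result is symmetric by construction.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValueError("profiles must be a 2-D array (n sequences x length)")
    n, L = X.shape
    if n < 2:
        raise ValueError("need at least 2 profiles")
    _check_band(L, L, band)
    if ids is None:
        ids = list(range(n))
    D = np.zeros((n, n))
    for i in range(n - 1):
        D[i, i + 1:] = _dtw_one_vs_many(X[i], X[i + 1:], band)
    D = D + D.T
    return DistanceMatrix(ids=list(ids), values=D)
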