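"""Dynamic time warping for short clinical score series.

Conventions used throughout the package:

* local cost is the squared difference of aligned values;
* admissible warping paths are monotone, align both endpoints, and use
  steps ``(1,0), (0,1), (1,1)``;
* the reported distance is the square root of the minimal accumulated
  squared cost, so a K-means inertia under this distance is a sum of
  squared DTW distances, mirroring the Euclidean convention.

DTW is symmetric and ``dtw(x, x) == 0`` but it is *not* a metric: the
triangle inequality can fail.  That is acceptable here — it is used only as
a within-cohort dissimilarity, never as an embedding metric.

An optional Sakoe-Chiba band (half-width ``band``) restricts alignment to
``|i - j| <= band``; it must be at least ``|len(x) - len(y)|`` to be
feasible.  The trajectories clustered in this package are length 13, so no
band is applied by default.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dtw_distance",
    "dtw_path",
    "dtw_distance_to_many",
    "pairwise_dtw",
]


def _as_series(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    return arr


def _check_band(n: int, m: int, band: int | None) -> None:
    if band is not None:
        if band < 0 or band < abs(n - m):
            raise ValueError(f"band {band} infeasible for lengths ({n}, {m})")


def _accumulated(x: np.ndarray, y: np.ndarray, band: int | None) -> np.ndarray:
    """Accumulated-cost matrix ``D[i, j]`` (inf outside the band)."""
    n, m = len(x), len(y)
    cost = (x[:, None] - y[None, :]) ** 2
    if band is not None:
        i, j = np.ogrid[:n, :m]
        cost = np.where(np.abs(i - j) <= band, cost, np.inf)
    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, n):
        Dim1 = D[i - 1]
        Di = D[i]
        ci = cost[i]
        for j in range(1, m):
            Di[j] = ci[j] + min(Dim1[j], Di[j - 1], Dim1[j - 1])
    return D


def dtw_distance(x, y, band: int | None = None) -> float:
    """DTW distance: sqrt of minimal accumulated squared pointwise cost."""
    xa, ya = _as_series(x, "x"), _as_series(y, "y")
    _check_band(len(xa), len(ya), band)
    return float(np.sqrt(_accumulated(xa, ya, band)[-1, -1]))


def _backtrack(D: np.ndarray) -> list[tuple[int, int]]:
    """Optimal path from an accumulated-cost matrix; ties prefer the diagonal."""
    i, j = D.shape[0] - 1, D.shape[1] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, up, left = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
            best = min(diag, up, left)
            if diag == best:
                i, j = i - 1, j - 1
            elif up == best:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return path


def dtw_path(x, y, band: int | None = None) -> list[tuple[int, int]]:
    """An optimal warping path as ordered ``(i, j)`` index pairs.

    Starts at ``(0, 0)``, ends at ``(len(x)-1, len(y)-1)``; the accumulated
    squared cost along it equals ``dtw_distance(x, y) ** 2``.
    """
    xa, ya = _as_series(x, "x"), _as_series(y, "y")
    _check_band(len(xa), len(ya), band)
    return _backtrack(_accumulated(xa, ya, band))


def _accumulated_many(c: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Accumulated-cost matrices of one series ``c`` against rows of ``X``.

    Returns an array of shape ``(N, len(c), ncols)``; the dynamic program is
    vectorized over the N series, which is what makes pure-numpy DTW K-means
    fast enough on cohort-sized inputs.
    """
    n, m = len(c), X.shape[1]
    cost = (c[None, :, None] - X[:, None, :]) ** 2  # (N, n, m)
    D = np.empty_like(cost)
    D[:, 0, 0] = cost[:, 0, 0]
    for i in range(1, n):
        D[:, i, 0] = D[:, i - 1, 0] + cost[:, i, 0]
    for j in range(1, m):
        D[:, 0, j] = D[:, 0, j - 1] + cost[:, 0, j]
    for i in range(1, n):
        for j in range(1, m):
            np.minimum(D[:, i - 1, j], D[:, i, j - 1], out=D[:, i, j])
            np.minimum(D[:, i, j], D[:, i - 1, j - 1], out=D[:, i, j])
            D[:, i, j] += cost[:, i, j]
    return D


def dtw_distance_to_many(c, X) -> np.ndarray:
    """DTW distances from one series to every row of a 2-D array."""
    ca = _as_series(c, "c")
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim != 2 or Xa.shape[1] == 0:
        raise ValueError("X must be a non-empty 2-D array")
    return np.sqrt(_accumulated_many(ca, Xa)[:, -1, -1])


def pairwise_dtw(X) -> np.ndarray:
    """Symmetric matrix of pairwise DTW distances between rows of ``X``."""
    Xa = np.asarray(X, dtype=float)
    N = Xa.shape[0]
    out = np.zeros((N, N))
    for i in range(N - 1):
        d = dtw_distance_to_many(Xa[i], Xa[i + 1 :])
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return out
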