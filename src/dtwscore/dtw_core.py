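"""Dynamic time warping between two expression time series.

The accumulated-cost grid is built with the unweighted three-way
recursion

    gamma(1,1) = d(1,1)
    gamma(m,1) = d(m,1) + gamma(m-1,1)
    gamma(1,n) = d(1,n) + gamma(1,n-1)
    gamma(m,n) = d(m,n) + min(gamma(m,n-1), gamma(m-1,n-1), gamma(m-1,n))

(1-based indices in this docstring; storage is 0-based).  The DTW
distance is gamma(n1, n2) — the minimum summed local dissimilarity over
all monotone warping paths — and the normalized distance divides it by
n1 + n2, the path-length normalization that makes alignments of series
of different lengths comparable.

An optional symmetric step pattern with diagonal weight 2 is provided
for cross-checks against implementations that pair that weighting with
the same (n1 + n2) normalization; the unweighted recursion above is the
default.

A brute-force path enumerator serves as an exact oracle on short
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "Alignment",
    "local_distance",
    "dtw_align",
    "dtw_distance",
    "brute_force_dtw",
    "METRICS",
]

METRICS = ("euclidean", "squared", "manhattan")


def local_distance(x: float, y: float, metric: str = "euclidean") -> float:
    """Non-negative local dissimilarity d(m,n) = f(x, y) between two scalars.

    ``euclidean`` and ``manhattan`` coincide for scalars (|x - y|);
    ``squared`` is (x - y)^2.
    """
    if metric in ("euclidean", "manhattan"):
        return abs(x - y)
    if metric == "squared":
        return (x - y) ** 2
    raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")


def _local_matrix(s1: np.ndarray, s2: np.ndarray, metric: str) -> np.ndarray:
    diff = np.subtract.outer(s1, s2)
    if metric in ("euclidean", "manhattan"):
        return np.abs(diff)
    if metric == "squared":
        return diff**2
    raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")


@dataclass(frozen=True)
class Alignment:
    """Result of aligning two series.

    Attributes
    ----------
    cost_grid
        (n1 x n2) accumulated-cost grid gamma.
    distance
        gamma(n1, n2), the minimum total local distance over all
        monotone warping paths.
    normalized_distance
        distance / (n1 + n2).
    path
        Optimal warping path as 0-based (m, n) index pairs from (0, 0)
        to (n1-1, n2-1); steps are (+1,0), (0,+1) or (+1,+1).
    """

    cost_grid: np.ndarray
    distance: float
    normalized_distance: float
    path: tuple[tuple[int, int], ...]


def dtw_align(
    s1,
    s2,
    metric: str = "euclidean",
    *,
    diagonal_weight: float = 1.0,
) -> Alignment:
    """Align two value sequences and return the full :class:`Alignment`.

    ``diagonal_weight`` multiplies the local distance on diagonal steps;
    the default 1.0 is the unweighted recursion, 2.0 gives the symmetric
    weighted step pattern some DTW implementations pair with the
    (n1 + n2) normalization.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise ValidationError("cannot align an empty sequence")
    if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))):
        raise ValidationError("sequences must contain finite values only")

    d = _local_matrix(s1, s2, metric)
    n1, n2 = d.shape
    g = np.empty_like(d)
    w = float(diagonal_weight)
    g[0, 0] = d[0, 0]
    for m in range(1, n1):
        g[m, 0] = d[m, 0] + g[m - 1, 0]
    for n in range(1, n2):
        g[0, n] = d[0, n] + g[0, n - 1]
    for m in range(1, n1):
        gm, gm1, dm = g[m], g[m - 1], d[m]
        for n in range(1, n2):
            left = gm[n - 1] + dm[n]
            up = gm1[n] + dm[n]
            diag = gm1[n - 1] + w * dm[n]
            gm[n] = min(diag, left, up)

    # Traceback; ties prefer diagonal, then left, then up.
    path = [(n1 - 1, n2 - 1)]
    m, n = n1 - 1, n2 - 1
    while (m, n) != (0, 0):
        if m == 0:
            n -= 1
        elif n == 0:
            m -= 1
        else:
            here = g[m, n]
            if np.isclose(g[m - 1, n - 1] + w * d[m, n], here):
                m, n = m - 1, n - 1
            elif np.isclose(g[m, n - 1] + d[m, n], here):
                n -= 1
            else:
                m -= 1
        path.append((m, n))
    path.reverse()

    dist = float(g[-1, -1])
    return Alignment(
        cost_grid=g,
        distance=dist,
        normalized_distance=dist / (n1 + n2),
        path=tuple(path),
    )


def dtw_distance(s1, s2, metric: str = "euclidean") -> float:
    """Unnormalized DTW distance only — no grid or path kept.

    Equivalent to ``dtw_align(s1, s2, metric).distance`` but computed
    row-by-row in O(min length) memory; used in the all-pairs scoring
    loop.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise ValidationError("cannot align an empty sequence")
    d = _local_matrix(s1, s2, metric)
    prev = np.cumsum(d[0])
    for m in range(1, d.shape[0]):
        row = np.empty_like(prev)
        row[0] = prev[0] + d[m, 0]
        dm = d[m]
        for n in range(1, len(prev)):
            row[n] = dm[n] + min(prev[n], prev[n - 1], row[n - 1])
        prev = row
    return float(prev[-1])


def brute_force_dtw(s1, s2, metric: str = "euclidean") -> float:
    """Exact DTW distance by exhaustive enumeration of all monotone paths.

    Walks every path from (0,0) to (n1-1, n2-1) with steps (+1,0),
    (0,+1), (+1,+1) and returns the minimum total local distance.
    Guarded to n1*n2 <= 64; this is an oracle for testing, not a tool
    for real series.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise ValidationError("cannot align an empty sequence")
    n1, n2 = len(s1), len(s2)
    if n1 * n2 > 64:
        raise ValidationError(
            f"brute-force enumeration limited to n1*n2 <= 64 (got {n1 * n2})"
        )
    d = _local_matrix(s1, s2, metric)

    best = [np.inf]

    def walk(m: int, n: int, cost: float) -> None:
        cost += d[m, n]
        if cost >= best[0]:
            return  # prune: all local distances are non-negative
        if m == n1 - 1 and n == n2 - 1:
            best[0] = cost
            return
        if m + 1 < n1 and n + 1 < n2:
            walk(m + 1, n + 1, cost)
        if n + 1 < n2:
            walk(m, n + 1, cost)
        if m + 1 < n1:
            walk(m + 1, n, cost)

    walk(0, 0, 0.0)
    return float(best[0])
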