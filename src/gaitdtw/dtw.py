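"""Dynamic time warping between a reference and a measured sequence.

DTW aligns two time series r[1:n] and t[1:m] of possibly different
lengths by a monotone warping that minimizes the accumulated local
distance.  The accumulated-cost matrix F is filled by the standard
recurrence

    F(0, 0) = 0,   F(i, 0) = F(0, j) = +inf   (i, j >= 1)
    F(k, l) = d(r_k, t_l) + min[F(k-1, l), F(k, l-1), F(k-1, l-1)]

with the local distance d taken as the absolute difference of the two
samples.  The total distance is F(n, m) and the optimal warping path is
recovered by backtracking the argmin predecessors from (n, m) to (1, 1).

No warping window, slope constraint or path-length normalization is
applied; any normalization of distances happens downstream in scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf, isfinite

import numpy as np

__all__ = ["DTWResult", "local_distance", "dtw", "dtw_distance", "dtw_brute_force"]


@dataclass
class DTWResult:
    """Accumulated-cost matrix, total distance and optimal warping path.

    ``matrix`` is (n+1) x (m+1) with sentinel boundaries (+inf except the
    origin); ``path`` is a list of 1-based index pairs (k, l) from (1, 1)
    to (n, m) whose successive elements differ by (+1, 0), (0, +1) or
    (+1, +1).  The local distances along the path sum to ``distance``.
    """

    distance: float
    matrix: np.ndarray
    path: list[tuple[int, int]]
    n: int
    m: int


def local_distance(r_k: float, t_l: float) -> float:
    """Local cost between two samples: the absolute difference."""
    if not (isfinite(r_k) and isfinite(t_l)):
        raise ValueError("local_distance requires finite inputs")
    return abs(r_k - t_l)


def _as_seq(x, name: str) -> list[float]:
    seq = [float(v) for v in np.asarray(x, dtype=float).ravel()]
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    if not all(isfinite(v) for v in seq):
        raise ValueError(f"{name} must be finite")
    return seq


def _fill(r: list[float], t: list[float]) -> list[list[float]]:
    n, m = len(r), len(t)
    F = [[inf] * (m + 1) for _ in range(n + 1)]
    F[0][0] = 0.0
    for k in range(1, n + 1):
        rk = r[k - 1]
        prev = F[k - 1]
        row = F[k]
        acc = inf
        for l in range(1, m + 1):
            d = abs(rk - t[l - 1])
            up = prev[l]
            diag = prev[l - 1]
            best = diag if diag <= up else up
            if acc < best:
                best = acc
            acc = d + best
            row[l] = acc
    return F


def dtw(r, t) -> DTWResult:
    """Full DTW: accumulated-cost matrix, distance and warping path.

    Backtracking tie-break is deterministic: diagonal first, then the
    predecessor that reduces k, then the one that reduces l.
    """
    rs, ts = _as_seq(r, "r"), _as_seq(t, "t")
    n, m = len(rs), len(ts)
    F = _fill(rs, ts)

    path = [(n, m)]
    k, l = n, m
    while (k, l) != (1, 1):
        candidates = (
            (F[k - 1][l - 1], (k - 1, l - 1)),
            (F[k - 1][l], (k - 1, l)),
            (F[k][l - 1], (k, l - 1)),
        )
        best = min(candidates, key=lambda c: c[0])
        k, l = best[1]
        path.append((k, l))
    path.reverse()
    return DTWResult(
        distance=F[n][m], matrix=np.array(F), path=path, n=n, m=m
    )


def dtw_distance(r, t) -> float:
    """DTW distance only (no matrix/path retained).

    Memory-light variant keeping two matrix rows; returns exactly the
    same value as ``dtw(r, t).distance``.
    """
    rs, ts = _as_seq(r, "r"), _as_seq(t, "t")
    m = len(ts)
    prev = [0.0] + [inf] * m
    for rk in rs:
        row = [inf] * (m + 1)
        acc = inf
        for l in range(1, m + 1):
            d = abs(rk - ts[l - 1])
            up = prev[l]
            diag = prev[l - 1]
            best = diag if diag <= up else up
            if acc < best:
                best = acc
            acc = d + best
            row[l] = acc
        prev = row
    return prev[m]


def dtw_brute_force(r, t, max_len: int = 7) -> float:
    """Exhaustive-enumeration oracle for small sequences.

    Enumerates every monotone path from (1, 1) to (n, m) with steps
    (1, 0), (0, 1), (1, 1) and returns the minimum total local cost.
    Exponential in sequence length; intended for cross-checking ``dtw``
    on tiny inputs.
    """
    rs, ts = _as_seq(r, "r"), _as_seq(t, "t")
    n, m = len(rs), len(ts)
    if n > max_len or m > max_len:
        raise ValueError(f"brute force limited to sequences of length <= {max_len}")

    def paths(k: int, l: int):
        if (k, l) == (1, 1):
            yield [(1, 1)]
            return
        for pk, pl in ((k - 1, l - 1), (k - 1, l), (k, l - 1)):
            if pk >= 1 and pl >= 1:
                for p in paths(pk, pl):
                    yield p + [(k, l)]

    return min(
        sum(abs(rs[k - 1] - ts[l - 1]) for k, l in p) for p in paths(n, m)
    )
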