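"""Dynamic time warping with pluggable per-sample cost.

The dynamic program is the classic unconstrained three-step pattern
((1,0), (0,1), (1,1)); ties are broken preferring the diagonal step, then
(0,1) (advance signal 2), then (1,0), which makes the returned path
deterministic across platforms.  The normalized distance (DTWND) is the
total path cost divided by the number of path pairs, keeping it on the
scale of the cost function regardless of signal lengths.

The inner DP/backtrack runs through a numba-jitted kernel when numba is
importable; a pure-Python fallback with identical semantics is used
otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "WarpingPath",
    "MatchingVectors",
    "dtw",
    "dtw_from_cost_matrix",
    "dtw_quat",
    "dtw_multichannel",
    "normalized_distance",
    "matching_vectors",
    "quat_cost_matrix",
]


def _dp_backtrack_py(C):
    n, m = C.shape
    D = np.empty((n, m))
    D[0, 0] = C[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + C[0, j]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + C[i, 0]
        for j in range(1, m):
            best = D[i - 1, j - 1]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            D[i, j] = C[i, j] + best
    lmax = n + m - 1
    pi = np.empty(lmax, np.int64)
    pj = np.empty(lmax, np.int64)
    i, j = n - 1, m - 1
    k = lmax - 1
    while True:
        pi[k] = i
        pj[k] = j
        if i == 0 and j == 0:
            break
        if i > 0 and j > 0:
            d = D[i - 1, j - 1]
            l = D[i, j - 1]
            u = D[i - 1, j]
            if d <= l and d <= u:
                i -= 1
                j -= 1
            elif l <= u:
                j -= 1
            else:
                i -= 1
        elif j > 0:
            j -= 1
        else:
            i -= 1
        k -= 1
    return pi[k:], pj[k:], D[n - 1, m - 1]


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _dp_backtrack = njit(cache=True)(_dp_backtrack_py)
except ImportError:  # pragma: no cover
    _dp_backtrack = _dp_backtrack_py


@dataclass
class WarpingPath:
    """Optimal monotone alignment between two signals.

    ``pairs`` is an ``(L, 2)`` integer array running from ``(0, 0)`` to
    ``(n-1, m-1)``; ``costs`` holds the per-pair cost and ``total_cost``
    their sum.
    """

    pairs: np.ndarray
    costs: np.ndarray
    total_cost: float
    n: int
    m: int

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64)
        self.costs = np.asarray(self.costs, dtype=float)
        if len(self.pairs) != len(self.costs):
            raise ValueError("pairs and costs length mismatch")
        if len(self.pairs) == 0:
            raise ValueError("warping path cannot be empty")
        if tuple(self.pairs[0]) != (0, 0) or tuple(self.pairs[-1]) != (self.n - 1, self.m - 1):
            raise ValueError("warping path must run from (0,0) to (n-1,m-1)")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def normalized_distance(self) -> float:
        return self.total_cost / len(self.pairs)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n": self.n,
            "m": self.m,
            "total_cost": self.total_cost,
            "normalized_distance": self.normalized_distance,
            "pairs": self.pairs.tolist(),
            "costs": self.costs.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class MatchingVectors:
    """Per-index correspondence maps between two DTW-aligned signals.

    ``map1to2[i]`` is the last index of signal 2 matched with index ``i``
    of signal 1 along the path, and vice versa; both are monotone
    non-decreasing.
    """

    map1to2: np.ndarray
    map2to1: np.ndarray

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"map1to2": self.map1to2.tolist(), "map2to1": self.map2to1.tolist()})
        if path is not None:
            Path(path).write_text(text)
        return text


def dtw_from_cost_matrix(cost: np.ndarray, band: int | None = None) -> WarpingPath:
    """Run the DP on a precomputed ``(n, m)`` pairwise cost matrix.

    ``band`` optionally applies a Sakoe-Chiba constraint (cells further
    than ``band`` from the stretched diagonal are forbidden); it is widened
    to ``|n - m|`` when needed so a boundary-to-boundary path always
    exists.  Default is the unconstrained program.
    """
    cost = np.ascontiguousarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] == 0 or cost.shape[1] == 0:
        raise ValueError("cost matrix must be 2-D and non-empty")
    if band is not None:
        n, m = cost.shape
        width = max(int(band), abs(n - m) + 1)
        ii = np.arange(n)[:, None]
        jj = np.arange(m)[None, :]
        diag = jj * (n - 1) / max(m - 1, 1)
        cost = np.where(np.abs(ii - diag) <= width, cost, np.inf)
    pi, pj, total = _dp_backtrack(cost)
    pairs = np.column_stack([pi, pj])
    per_pair = cost[pi, pj]
    return WarpingPath(pairs=pairs, costs=per_pair, total_cost=float(total), n=cost.shape[0], m=cost.shape[1])


def quat_cost_matrix(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Pairwise quaternion DTW cost ``1 - |q_i . q_j|`` for two (n,4)/(m,4) signals."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    return np.clip(1.0 - np.abs(q1 @ q2.T), 0.0, None)


def dtw(sig1: Sequence, sig2: Sequence, cost: Callable = None) -> WarpingPath:
    """DTW-align two sequences of arbitrary samples under a pairwise cost.

    ``cost`` is called on every sample pair; signals already stored as
    numeric arrays should go through :func:`dtw_quat` /
    :func:`dtw_multichannel`, which build the cost matrix vectorized.
    """
    if len(sig1) == 0 or len(sig2) == 0:
        raise ValueError("signals must be non-empty")
    if cost is None:
        raise ValueError("a cost function is required")
    C = np.array([[cost(a, b) for b in sig2] for a in sig1], dtype=float)
    return dtw_from_cost_matrix(C)


def dtw_quat(q1: np.ndarray, q2: np.ndarray) -> WarpingPath:
    """DTW between two quaternion signals under the ``1 - |dot|`` cost."""
    if len(q1) == 0 or len(q2) == 0:
        raise ValueError("signals must be non-empty")
    return dtw_from_cost_matrix(quat_cost_matrix(q1, q2))


def dtw_multichannel(x1: np.ndarray, x2: np.ndarray) -> WarpingPath:
    """DTW between two feature-vector sequences under Euclidean cost."""
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape[0] == 0 or x2.shape[0] == 0:
        raise ValueError("signals must be non-empty")
    return dtw_from_cost_matrix(cdist(x1, x2))


def normalized_distance(path: WarpingPath) -> float:
    """Total path cost divided by path length (pair count)."""
    return path.normalized_distance


def matching_vectors(path: WarpingPath) -> MatchingVectors:
    """Collapse a warping path into its two per-index matching vectors."""
    map1to2 = np.zeros(path.n, dtype=np.int64)
    map2to1 = np.zeros(path.m, dtype=np.int64)
    for i, j in path.pairs:
        map1to2[i] = j
        map2to1[j] = i
    return MatchingVectors(map1to2=map1to2, map2to1=map2to1)
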