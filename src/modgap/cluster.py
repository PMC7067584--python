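"""Exact optimal partitioning of one-dimensional data.

For univariate data the minimum within-cluster-sum-of-squares (WCSS)
partition into ``k`` groups is always contiguous on the sorted values, so
the global optimum can be found by dynamic programming instead of
restart-based k-means.  Exactness matters here: the pooled dispersion
``W_k`` feeds a Monte-Carlo-calibrated test, and any restart stochasticity
in ``W_k`` would leak into the calibrated thresholds.

Two routes are provided:

* :func:`optimal_partition` — scalar DP with backtracking, returns the
  partition itself (boundaries, WCSS).
* :func:`wk_batch` — vectorised DP over a stack of equally sized datasets,
  returning only ``W_k`` for ``k = 1..kmax``.  This is the workhorse for the
  reference-set simulations, where hundreds of thousands of small datasets
  must be partitioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Partition", "optimal_partition", "within_dispersion", "wk_batch"]


@dataclass(frozen=True)
class Partition:
    """An optimal contiguous partition of sorted 1-D values.

    Attributes
    ----------
    sorted_values : np.ndarray
        The input values in ascending order.
    k : int
        Number of blocks.
    boundaries : np.ndarray
        Start indices of blocks 2..k in ``sorted_values`` (strictly
        increasing, length ``k - 1``).  Block ``r`` spans
        ``[boundaries[r-1], boundaries[r])`` with sentinels 0 and ``n``.
    wcss : float
        Pooled within-block sum of squared deviations from block means.
    """

    sorted_values: np.ndarray
    k: int
    boundaries: np.ndarray
    wcss: float

    @property
    def blocks(self) -> list[np.ndarray]:
        """The k contiguous blocks as arrays of values."""
        edges = np.concatenate(([0], self.boundaries, [len(self.sorted_values)]))
        return [self.sorted_values[a:b] for a, b in zip(edges[:-1], edges[1:])]

    @property
    def labels(self) -> np.ndarray:
        """Block index (0-based) for each element of ``sorted_values``."""
        lab = np.zeros(len(self.sorted_values), dtype=int)
        for i, b in enumerate(self.boundaries):
            lab[b:] = i + 1
        return lab


def _check_values(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    return values


def _segment_cost(x: np.ndarray) -> np.ndarray:
    """Cost matrix C[a, b]: WCSS of sorted x[a..b] inclusive (inf for a > b)."""
    n = len(x)
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))
    a = np.arange(n)[:, None]
    b = np.arange(n)[None, :]
    length = b - a + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        seg1 = s1[b + 1] - s1[a]
        seg2 = s2[b + 1] - s2[a]
        cost = seg2 - seg1 * seg1 / length
    cost[length < 1] = np.inf
    # guard tiny negatives from cancellation
    np.maximum(cost, 0.0, out=cost, where=length >= 1)
    return cost


def optimal_partition(values, k: int) -> Partition:
    """Globally optimal (minimum-WCSS) partition of 1-D values into k groups.

    Deterministic; ties are broken toward the leftmost boundary set (the DP
    keeps the smallest split index on equal cost).

    Parameters
    ----------
    values : array-like of float
        Finite observations, ``len(values) >= k``.
    k : int
        Number of clusters, ``1 <= k <= len(values)``.
    """
    values = _check_values(values)
    n = len(values)
    if not (1 <= k <= n):
        raise ValueError(f"k must satisfy 1 <= k <= n; got k={k}, n={n}")
    x = np.sort(values)
    cost = _segment_cost(x)

    # dp[j, i]: minimal cost of splitting x[0..i] into j+1 blocks
    dp = np.full((k, n), np.inf)
    split = np.zeros((k, n), dtype=int)
    dp[0] = cost[0]
    for j in range(1, k):
        for i in range(j, n):
            # block j starts at some s in [j, i]
            cand = dp[j - 1, j - 1 : i] + cost[j : i + 1, i]
            best = int(np.argmin(cand))  # argmin takes first => leftmost split
            dp[j, i] = cand[best]
            split[j, i] = best + j
    # backtrack boundaries
    bounds = np.empty(k - 1, dtype=int)
    i = n - 1
    for j in range(k - 1, 0, -1):
        s = split[j, i]
        bounds[j - 1] = s
        i = s - 1
    return Partition(sorted_values=x, k=k, boundaries=bounds, wcss=float(dp[k - 1, n - 1]))


def within_dispersion(partition: Partition) -> float:
    """Pooled within-cluster dispersion W_k via the pairwise-distance form.

    ``W_k = Σ_r D_r / (2 n_r)`` where ``D_r`` is the sum over all ordered
    pairs within block r of squared distances.  Algebraically identical to
    the block WCSS; computed here from pairwise distances as an independent
    route (tests assert the identity).
    """
    total = 0.0
    for block in partition.blocks:
        nr = len(block)
        d = block[:, None] - block[None, :]
        total += float(np.sum(d * d)) / (2.0 * nr)
    return total


def _wk_batch_numpy(data: np.ndarray, kmax: int) -> np.ndarray:
    """Vectorised-numpy route for :func:`wk_batch` (fallback / cross-check)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (m datasets x n points)")
    m, n = data.shape
    if not (1 <= kmax <= n):
        raise ValueError(f"kmax must satisfy 1 <= kmax <= n; got {kmax}, n={n}")
    x = np.sort(data, axis=1)
    s1 = np.concatenate([np.zeros((m, 1)), np.cumsum(x, axis=1)], axis=1)
    s2 = np.concatenate([np.zeros((m, 1)), np.cumsum(x * x, axis=1)], axis=1)
    a = np.arange(n)[:, None]
    b = np.arange(n)[None, :]
    length = (b - a + 1).astype(float)
    valid = length >= 1
    # C[i, a, b] = WCSS of row i segment a..b
    seg1 = s1[:, None, 1:] - s1[:, :-1, None]
    seg2 = s2[:, None, 1:] - s2[:, :-1, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        C = seg2 - seg1 * seg1 / length
    C = np.where(valid, np.maximum(C, 0.0), np.inf)

    out = np.empty((m, kmax))
    # prev[i, j] = optimal cost of x[i, 0..j] in (k-1) blocks
    prev = C[:, 0, :].copy()
    out[:, 0] = prev[:, -1]
    for k in range(2, kmax + 1):
        # new block starts at j in [1, n-1]; cost prev[j-1] + C[j, i]
        cand = prev[:, : n - 1, None] + C[:, 1:, :]
        prev = np.min(cand, axis=1)
        out[:, k - 1] = prev[:, -1]
    return out


try:  # JIT-compiled row-wise DP; ~50x faster on the Monte-Carlo sweeps
    import numba as _numba

    @_numba.njit(cache=True)
    def _wk_rows_jit(x, kmax):  # pragma: no cover - exercised via wk_batch
        m, n = x.shape
        out = np.empty((m, kmax))
        for r in range(m):
            v = np.sort(x[r])
            s1 = np.empty(n + 1)
            s2 = np.empty(n + 1)
            s1[0] = 0.0
            s2[0] = 0.0
            for i in range(n):
                s1[i + 1] = s1[i] + v[i]
                s2[i + 1] = s2[i] + v[i] * v[i]
            prev = np.empty(n)
            cur = np.empty(n)
            for i in range(n):
                seg = s1[i + 1]
                prev[i] = max(s2[i + 1] - seg * seg / (i + 1.0), 0.0)
            out[r, 0] = prev[n - 1]
            for k in range(2, kmax + 1):
                for i in range(n):
                    cur[i] = np.inf
                for i in range(k - 1, n):
                    best = np.inf
                    for j in range(k - 1, i + 1):
                        seg = s1[i + 1] - s1[j]
                        c = s2[i + 1] - s2[j] - seg * seg / (i - j + 1.0)
                        if c < 0.0:
                            c = 0.0
                        t = prev[j - 1] + c
                        if t < best:
                            best = t
                    cur[i] = best
                for i in range(n):
                    prev[i] = cur[i]
                out[r, k - 1] = prev[n - 1]
        return out

except ImportError:  # pragma: no cover
    _wk_rows_jit = None


def wk_batch(data: np.ndarray, kmax: int) -> np.ndarray:
    """W_k for k = 1..kmax for every row of ``data``.

    Parameters
    ----------
    data : np.ndarray, shape (m, n)
        m datasets of n observations each (need not be sorted).
    kmax : int
        Largest number of clusters; ``kmax <= n``.

    Returns
    -------
    np.ndarray, shape (m, kmax)
        ``out[i, k-1]`` is the optimal W_k of row i.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (m datasets x n points)")
    m, n = data.shape
    if not (1 <= kmax <= n):
        raise ValueError(f"kmax must satisfy 1 <= kmax <= n; got {kmax}, n={n}")
    if _wk_rows_jit is not None:
        return _wk_rows_jit(np.ascontiguousarray(data), kmax)
    return _wk_batch_numpy(data, kmax)
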