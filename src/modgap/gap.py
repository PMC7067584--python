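"""Modified gap statistic with Monte-Carlo-calibrated per-k thresholds.

The gap statistic compares the log pooled within-cluster dispersion of a
dataset, ``log W_k``, with its expectation under a continuous (uniform)
reference distribution spanning the observed range:

    Gap(k) = mean_b log W*_kb  -  log W_k,

where ``W*_kb`` is the dispersion of the b-th of ``B`` reference datasets.
With few observations per animal the classical stopping rule is prone to
false positives, so the decision rule here is re-calibrated by simulation:

* evidence for k modes is ``e_k = Gap(k) - Gap(1)`` for ``k >= 2``;
* per-k thresholds ``T_k`` are chosen on a large sample of uniform nulls so
  that the full decision rule selects each specific k with probability
  ``alpha_per_k`` (default 0.01);
* the candidate is ``k* = argmax_k (e_k - T_k)`` (ties toward smaller k)
  and ``k_est = k*`` if ``e_{k*} > T_{k*}``, else ``k_est = 1``.

With ``kmax = 8`` and ``alpha_per_k = 0.01`` the overall null
false-positive rate P(k_est >= 2) is ~0.07.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cluster import wk_batch

__all__ = [
    "GapCurve",
    "ThresholdTable",
    "DetectionResult",
    "CalibrationError",
    "gap_curve",
    "calibrate_thresholds",
    "estimate_modes",
    "estimate_modes_batch",
]

_LOG_FLOOR = 1e-300  # W_k of duplicate-only blocks can be exactly 0


class CalibrationError(RuntimeError):
    """No finite threshold achieves the requested per-k false-positive rate."""


@dataclass(frozen=True)
class GapCurve:
    """Per-k gap-statistic quantities for one dataset."""

    k_values: np.ndarray  # 1..kmax
    log_w_obs: np.ndarray
    gap: np.ndarray  # mean reference log W_k minus observed log W_k
    s_k: np.ndarray  # sd_b(log W*_kb) * sqrt(1 + 1/B)
    B: int
    reference_range: tuple[float, float]
    degenerate: bool = False  # zero-variance input; detection must return 1

    def to_frame(self):
        """Export as a pandas DataFrame (columns k, logW_obs, gap, s_k)."""
        import pandas as pd

        return pd.DataFrame(
            {"k": self.k_values, "logW_obs": self.log_w_obs, "gap": self.gap, "s_k": self.s_k}
        )


@dataclass(frozen=True)
class ThresholdTable:
    """Calibrated per-k decision thresholds for a given n, kmax, alpha.

    ``thresholds[j]`` applies to ``k = j + 2`` (one per k in 2..kmax).
    """

    n: int
    kmax: int
    alpha_per_k: float
    thresholds: np.ndarray
    null_reps: int
    B: int
    seed: int

    def __post_init__(self):
        if len(self.thresholds) != self.kmax - 1:
            raise ValueError("thresholds must have length kmax - 1")
        if not (0.0 < self.alpha_per_k < 1.0):
            raise ValueError("alpha_per_k must lie in (0, 1)")

    def compatible_n(self, n: int, tol: float = 0.10) -> bool:
        """Whether a dataset of size n may reuse this table (within ±10%)."""
        return abs(n - self.n) <= tol * self.n

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["thresholds"] = [float(t) for t in self.thresholds]
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdTable":
        doc = json.loads(Path(path).read_text())
        doc["thresholds"] = np.asarray(doc["thresholds"], dtype=float)
        return cls(**doc)


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of the modularity test on one dataset."""

    k_est: int
    gap_curve: GapCurve
    evidence: np.ndarray  # e_k for k = 2..kmax
    thresholds_used: ThresholdTable
    clustered: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "clustered", self.k_est >= 2)


def _safe_log(w: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(w, _LOG_FLOOR))


def gap_curve(values, kmax: int, B: int = 100, rng=None) -> GapCurve:
    """Gap statistic curve of one dataset against uniform references.

    References are drawn uniformly over ``[min(values), max(values)]`` with
    the same n, which makes the statistic invariant to affine rescaling of
    the data.  Reproducible given ``rng`` (an int seed or a Generator).
    """
    rng = np.random.default_rng(rng)
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    n = len(values)
    if n < 2:
        raise ValueError("need at least two observations")
    if kmax > n:
        raise ValueError(f"kmax ({kmax}) cannot exceed n ({n})")
    if B < 10:
        raise ValueError("B must be at least 10")
    lo, hi = float(values.min()), float(values.max())
    ks = np.arange(1, kmax + 1)
    if hi <= lo:
        z = np.zeros(kmax)
        return GapCurve(ks, _safe_log(z), z, z, B, (lo, hi), degenerate=True)
    log_w_obs = _safe_log(wk_batch(values[None, :], kmax)[0])
    refs = rng.uniform(lo, hi, size=(B, n))
    log_w_ref = _safe_log(wk_batch(refs, kmax))
    gap = log_w_ref.mean(axis=0) - log_w_obs
    s_k = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    return GapCurve(ks, log_w_obs, gap, s_k, B, (lo, hi))


# ---------------------------------------------------------------------------
# batched evidence machinery (shared by calibration, detection and power)
# ---------------------------------------------------------------------------


def _chunk_rows(n: int) -> int:
    # keep the (m, n, n) cost tensor around ~200 MB
    return max(64, int(2.5e7 / (n * n)))


def _log_wk_many(data: np.ndarray, kmax: int) -> np.ndarray:
    """log W_k (k=1..kmax) for each row, chunked for memory."""
    m, n = data.shape
    out = np.empty((m, kmax))
    step = _chunk_rows(n)
    for i in range(0, m, step):
        out[i : i + step] = _safe_log(wk_batch(data[i : i + step], kmax))
    return out


def evidence_batch(datasets: np.ndarray, kmax: int, B: int, rng) -> np.ndarray:
    """Evidence matrix e_k = Gap(k) - Gap(1) for k = 2..kmax, per dataset.

    Each row of ``datasets`` gets its own B uniform reference draws over its
    own range.  Returns shape (m, kmax - 1).
    """
    rng = np.random.default_rng(rng)
    datasets = np.asarray(datasets, dtype=float)
    m, n = datasets.shape
    log_w_obs = _log_wk_many(datasets, kmax)
    lo = datasets.min(axis=1)
    hi = datasets.max(axis=1)
    span = hi - lo
    gap_mean = np.zeros((m, kmax))
    # process reference draws in blocks of datasets to bound memory
    step = max(1, _chunk_rows(n) // B)
    u = np.empty((0,))
    for i in range(0, m, step):
        block = slice(i, min(i + step, m))
        nb = block.stop - block.start
        u = rng.random(size=(nb, B, n))
        refs = lo[block, None, None] + span[block, None, None] * u
        lw = _log_wk_many(refs.reshape(nb * B, n), kmax).reshape(nb, B, kmax)
        gap_mean[block] = lw.mean(axis=1) - log_w_obs[block]
    degenerate = span <= 0
    ev = gap_mean[:, 1:] - gap_mean[:, :1]
    ev[degenerate] = -np.inf
    return ev


def _select_k(evidence: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Apply the decision rule to an evidence matrix; returns k_est per row."""
    score = evidence - thresholds[None, :]
    j = np.argmax(score, axis=1)  # first max => smaller k on ties
    rows = np.arange(len(evidence))
    passed = evidence[rows, j] > thresholds[j]
    return np.where(passed, j + 2, 1)


def calibrate_thresholds(
    n: int,
    kmax: int = 8,
    alpha_per_k: float = 0.01,
    null_reps: int = 1000,
    B: int = 100,
    rng=None,
    seed: int | None = None,
) -> ThresholdTable:
    """Calibrate per-k thresholds on simulated uniform nulls.

    Chooses ``T_k`` (k = 2..kmax) so that on fresh uniform datasets of size
    ``n`` the decision rule selects each specific k with probability
    ``alpha_per_k``.  Because the rule picks the argmax over k, per-k
    selections interact; thresholds are found by coordinate descent on the
    order-statistic rank of each ``e_k`` null sample until every per-k
    selection count equals ``round(alpha_per_k * null_reps)``.
    """
    if alpha_per_k * (kmax - 1) >= 1.0:
        raise ValueError("alpha_per_k * (kmax - 1) must be < 1")
    if null_reps < 100:
        raise ValueError("null_reps too small to calibrate (need >= 100)")
    if seed is None:
        seed = int(np.random.default_rng(rng).integers(2**31))
    gen = np.random.default_rng(seed)
    nulls = gen.random(size=(null_reps, n))
    ev = evidence_batch(nulls, kmax, B, gen)

    target = int(round(alpha_per_k * null_reps))
    if target < 1:
        raise CalibrationError(
            f"alpha_per_k={alpha_per_k} with null_reps={null_reps} targets "
            "fewer than one null selection per k; increase null_reps"
        )
    nk = kmax - 1
    desc = -np.sort(-ev, axis=0)  # descending null evidence per k
    # threshold at rank m admits exactly m marginal exceedances
    pad = np.min(desc, axis=0) - 1.0

    def thr(k_idx: int, m: int) -> float:
        if m <= 0:
            return float(desc[0, k_idx] + 1.0)
        hi = desc[m - 1, k_idx]
        lo = desc[m, k_idx] if m < null_reps else pad[k_idx]
        return float(0.5 * (hi + lo))

    ranks = np.full(nk, target)
    T = np.array([thr(j, ranks[j]) for j in range(nk)])
    for _ in range(60):
        changed = False
        counts = np.bincount(_select_k(ev, T), minlength=kmax + 1)[2:]
        for j in range(nk):
            while counts[j] < target and ranks[j] < null_reps:
                ranks[j] += 1
                T[j] = thr(j, ranks[j])
                counts = np.bincount(_select_k(ev, T), minlength=kmax + 1)[2:]
                changed = True
            while counts[j] > target and ranks[j] > 0:
                ranks[j] -= 1
                T[j] = thr(j, ranks[j])
                counts = np.bincount(_select_k(ev, T), minlength=kmax + 1)[2:]
                changed = True
        if not changed:
            break
    counts = np.bincount(_select_k(ev, T), minlength=kmax + 1)[2:]
    if np.any(np.abs(counts - target) > max(2, 0.5 * target)):
        raise CalibrationError(
            f"per-k selection counts {counts.tolist()} did not converge to "
            f"target {target} at null_reps={null_reps}"
        )
    return ThresholdTable(
        n=n,
        kmax=kmax,
        alpha_per_k=alpha_per_k,
        thresholds=T,
        null_reps=null_reps,
        B=B,
        seed=seed,
    )


def estimate_modes(values, table: ThresholdTable, B: int | None = None, rng=None) -> DetectionResult:
    """Estimate the number of modes k_est of one dataset.

    Returns ``k_est = 1`` (continuous) when no per-k evidence exceeds its
    calibrated threshold, or the winning ``k >= 2`` otherwise.  Degenerate
    input (constant values) yields ``k_est = 1``.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least four observations to test modularity")
    if not table.compatible_n(len(values)):
        import warnings

        warnings.warn(
            f"dataset n={len(values)} differs from table n={table.n} by more "
            "than 10%; recalibration recommended",
            stacklevel=2,
        )
    B = table.B if B is None else B
    curve = gap_curve(values, table.kmax, B=B, rng=rng)
    if curve.degenerate:
        ev = np.full(table.kmax - 1, -np.inf)
        return DetectionResult(1, curve, ev, table)
    ev = curve.gap[1:] - curve.gap[0]
    k_est = int(_select_k(ev[None, :], table.thresholds)[0])
    return DetectionResult(k_est, curve, ev, table)


def estimate_modes_batch(datasets: np.ndarray, table: ThresholdTable, rng=None) -> np.ndarray:
    """k_est for each row of ``datasets`` (vectorised detection path)."""
    datasets = np.asarray(datasets, dtype=float)
    ev = evidence_batch(datasets, table.kmax, table.B, rng)
    return _select_k(ev, table.thresholds)
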