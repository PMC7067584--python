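"""Exact binomial inference: Clopper–Pearson intervals and exact tests.

Detection outcomes are summarised as x successes in n trials (animals or
simulation replicates).  Intervals use the exact Clopper–Pearson
construction (beta-quantile form); the two-sided test uses the
minimum-likelihood convention (sum the probabilities of all outcomes no
more likely than the observed one).  Both are delegated to scipy and
cross-checked against enumeration oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["BinomialSummary", "binomial_summary", "clopper_pearson", "exact_binomial_pvalue"]


@dataclass(frozen=True)
class BinomialSummary:
    x: int
    n: int
    p_hat: float
    conf: float
    ci_lo: float
    ci_hi: float
    p0: float | None = None
    p_value: float | None = None


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided confidence interval for x/n.

    Boundary cases are closed-form: x=0 gives (0, 1 - (alpha/2)^(1/n)) and
    x=n gives ((alpha/2)^(1/n), 1).
    """
    if not 0 <= x <= n:
        raise ValueError("require 0 <= x <= n")
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return lo, hi


def exact_binomial_pvalue(x: int, n: int, p0: float) -> float:
    """Two-sided exact binomial test p-value (minimum-likelihood method)."""
    return float(stats.binomtest(x, n, p0, alternative="two-sided").pvalue)


def binomial_summary(x: int, n: int, conf: float = 0.95, p0: float | None = None) -> BinomialSummary:
    """Point estimate, exact CI and (optionally) exact test for x/n."""
    if not 0 <= x <= n:
        raise ValueError("require 0 <= x <= n")
    lo, hi = clopper_pearson(x, n, conf)
    pv = None if p0 is None else exact_binomial_pvalue(x, n, p0)
    return BinomialSummary(x=x, n=n, p_hat=x / n, conf=conf, ci_lo=lo, ci_hi=hi, p0=p0, p_value=pv)
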