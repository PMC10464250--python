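"""Operating-characteristic functions for attribute sampling plans.

Covers the multiple dependent state sampling plan (MDSSP) and the
classical single sampling plan (SSP), both under a binomial lot model:
each of the ``n`` sampled items independently fails before the test
truncation time with probability ``p``.

The MDSSP sentences a lot from its failure count ``d`` in three bands:
accept outright when ``d <= c1``, reject outright when ``d > c2``, and in
the conditional band ``c1 < d <= c2`` accept only if each of the ``m``
preceding lots was accepted outright.  For i.i.d. lots the stationary
acceptance probability is

    Pa(p) = A + (B - A) * A**m,   A = P(d <= c1),  B = P(d <= c2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MDSSPPlan", "SSPPlan", "RiskSpec", "binom_cdf", "oc_mdssp", "oc_ssp", "asn"]

from .distribution import QuantileSpec


@dataclass(frozen=True)
class MDSSPPlan:
    """Design parameters of a multiple dependent state sampling plan.

    Attributes
    ----------
    n : int
        Sample size per lot, > 1.
    c1 : int
        Unconditional acceptance number, >= 0.
    c2 : int
        Conditional acceptance number, > c1.
    m : int
        Number of preceding lots that must each have been accepted
        unconditionally for a conditional acceptance, >= 1.
    """

    n: int
    c1: int
    c2: int
    m: int

    # validation relaxed for the internal constructor used in tests
    _allow_degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n <= 1:
            raise ValueError(f"n must be > 1, got {self.n}")
        if self.c1 < 0:
            raise ValueError(f"c1 must be >= 0, got {self.c1}")
        lower = self.c1 if self._allow_degenerate else self.c1 + 1
        if self.c2 < lower:
            raise ValueError(f"c2 must be > c1 (got c1={self.c1}, c2={self.c2})")
        if self.c2 >= self.n:
            raise ValueError(f"n must exceed c2 (got n={self.n}, c2={self.c2})")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")


@dataclass(frozen=True)
class SSPPlan:
    """Single sampling plan: accept iff the failure count is <= c."""

    n: int
    c: int

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")
        if self.n <= self.c:
            raise ValueError(f"n must exceed c (got n={self.n}, c={self.c})")


@dataclass(frozen=True)
class RiskSpec:
    """Producer/consumer risk contract for plan design.

    Attributes
    ----------
    alpha : float
        Producer's risk: maximum probability of rejecting a lot at the
        acceptable quality level (AQL), in (0, 1).
    beta : float
        Consumer's risk: maximum probability of accepting a lot at the
        limiting quality level (LQL), in (0, 1).
    quantile : QuantileSpec
        Life-test geometry (quantile level q, quantile ratio r,
        termination ratio k) from which the AQL and LQL failure
        probabilities are derived.
    """

    alpha: float
    beta: float
    quantile: QuantileSpec

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {value!r}")


def binom_cdf(d_max, n, p):
    """P(D <= d_max) for D ~ Binomial(n, p).

    Thin wrapper over the regularized-incomplete-beta implementation in
    scipy, with argument validation matching the plan domain.
    """
    d_arr = np.asarray(d_max)
    if np.any(d_arr < 0) or np.any(d_arr > n):
        raise ValueError(f"d_max must lie in [0, n], got d_max={d_max}, n={n}")
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0.0) or np.any(p_arr > 1.0) or np.any(np.isnan(p_arr)):
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    out = stats.binom.cdf(d_max, n, p)
    return out if np.ndim(out) else float(out)


def oc_mdssp(plan: MDSSPPlan, p):
    """MDSSP acceptance probability ``A + (B - A) A^m`` at failure rate p."""
    a = binom_cdf(plan.c1, plan.n, p)
    b = binom_cdf(plan.c2, plan.n, p)
    out = a + (b - a) * a**plan.m
    return out if np.ndim(out) else float(out)


def oc_ssp(plan: SSPPlan, p):
    """SSP acceptance probability: binomial CDF at the acceptance number."""
    return binom_cdf(plan.c, plan.n, p)


def asn(plan: MDSSPPlan) -> int:
    """Average sample number per lot.

    Every lot draws exactly ``n`` items regardless of the sentencing
    outcome, so the expected inspection effort equals ``n``.
    """
    return plan.n
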