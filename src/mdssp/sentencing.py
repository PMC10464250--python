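"""Lot sentencing under the multiple dependent state rule.

Operating procedure for one lot: draw n items, run the truncated life
test to time t0, count the failures d, then

* ``d <= c1``       -> accept (unconditional),
* ``d >  c2``       -> reject,
* ``c1 < d <= c2``  -> conditional band: accept only if each of the m
  most recent lots had a failure count <= c1 (i.e. was accepted
  unconditionally).

With fewer than m prior lots on record the conditional band defaults to
rejection — the conservative, consumer-protecting cold-start choice —
unless ``cold_start='accept'`` is requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .oc import MDSSPPlan, oc_mdssp

__all__ = [
    "Decision",
    "LotRecord",
    "LotHistory",
    "count_failures",
    "sentence_lot",
    "simulate_acceptance_rate",
]


class Decision(str, Enum):
    ACCEPT = "accept"
    REJECT = "reject"
    DEFERRED_ACCEPT = "deferred-accept"
    DEFERRED_REJECT = "deferred-reject"

    @property
    def accepted(self) -> bool:
        return self in (Decision.ACCEPT, Decision.DEFERRED_ACCEPT)


@dataclass(frozen=True)
class LotRecord:
    """Failure count and sentencing outcome of one inspected lot."""

    failures: int
    decision: Decision

    def __post_init__(self) -> None:
        if self.failures < 0:
            raise ValueError(f"failures must be >= 0, got {self.failures}")


@dataclass
class LotHistory:
    """Chronological record of previously sentenced lots (most recent last)."""

    records: list[LotRecord] = field(default_factory=list)

    def append(self, record: LotRecord) -> None:
        self.records.append(record)

    def last(self, m: int) -> list[LotRecord]:
        return self.records[-m:] if m > 0 else []

    def __len__(self) -> int:
        return len(self.records)


def count_failures(lifetimes, t0: float) -> int:
    """Number of items failing at or before the truncation time t0.

    The comparison is inclusive: a lifetime exactly equal to t0 counts
    as a failure.
    """
    if not (t0 > 0.0):
        raise ValueError(f"t0 must be > 0, got {t0!r}")
    arr = np.asarray(lifetimes, dtype=float)
    if arr.size == 0:
        warnings.warn("empty lifetime vector: zero failures by convention")
        return 0
    if np.any(arr < 0.0) or np.any(np.isnan(arr)):
        raise ValueError("lifetimes must be non-negative and finite")
    return int(np.count_nonzero(arr <= t0))


def sentence_lot(
    d: int,
    plan: MDSSPPlan,
    history: LotHistory | None = None,
    cold_start: str = "reject",
) -> Decision:
    """Sentence the current lot from its failure count and the lot history.

    Parameters
    ----------
    d : int
        Failure count in the current lot's sample, 0 <= d <= plan.n.
    history : LotHistory, optional
        Previously sentenced lots; only the last ``plan.m`` entries
        matter.  May be shorter than m (cold start).
    cold_start : {'reject', 'accept'}
        Conditional-band outcome when fewer than m prior lots exist.
    """
    if d < 0 or d > plan.n:
        raise ValueError(f"d must lie in [0, n={plan.n}], got {d}")
    if cold_start not in ("reject", "accept"):
        raise ValueError(f"cold_start must be 'reject' or 'accept', got {cold_start!r}")
    if d <= plan.c1:
        return Decision.ACCEPT
    if d > plan.c2:
        return Decision.REJECT
    # conditional band
    records = history.last(plan.m) if history is not None else []
    if len(records) < plan.m:
        return Decision.DEFERRED_ACCEPT if cold_start == "accept" else Decision.DEFERRED_REJECT
    ok = all(rec.failures <= plan.c1 for rec in records)
    return Decision.DEFERRED_ACCEPT if ok else Decision.DEFERRED_REJECT


def simulate_acceptance_rate(
    plan: MDSSPPlan, p: float, n_lots: int = 100_000, seed=None
) -> dict:
    """Monte-Carlo acceptance frequency of the sentencing rule.

    Simulates ``n_lots`` i.i.d. lots whose failure counts are
    Binomial(n, p), applies the sentencing rule with the rolling
    m-preceding-lots condition, and returns the empirical acceptance
    rate with its standard error alongside the analytic OC value.

    The first m lots (cold start) are excluded from the frequency so
    the estimate targets the stationary acceptance probability.
    """
    rng = np.random.default_rng(seed)
    d = rng.binomial(plan.n, p, size=n_lots)
    uncond = d <= plan.c1                       # unconditional accept
    in_band = (d > plan.c1) & (d <= plan.c2)
    # rolling check: all of the m preceding lots unconditionally accepted
    window_ok = np.ones(n_lots, dtype=bool)
    for lag in range(1, plan.m + 1):
        shifted = np.empty(n_lots, dtype=bool)
        shifted[:lag] = False
        shifted[lag:] = uncond[:-lag]
        window_ok &= shifted
    accepted = uncond | (in_band & window_ok)
    valid = accepted[plan.m:]
    rate = float(valid.mean())
    # consecutive decisions share window entries, so the i.i.d. binomial
    # standard error understates the MC error; use batch means with
    # batches much longer than the dependence range m
    n_batches = max(min(valid.size // (50 * plan.m), 200), 10)
    usable = (valid.size // n_batches) * n_batches
    batches = valid[:usable].reshape(n_batches, -1).mean(axis=1)
    se = float(batches.std(ddof=1) / np.sqrt(n_batches))
    return {
        "acceptance_rate": rate,
        "standard_error": se,
        "oc": oc_mdssp(plan, p),
        "n_lots": int(valid.size),
    }
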