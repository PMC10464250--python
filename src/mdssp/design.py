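"""Minimal-sample-size design of MDSSP and SSP plans.

A plan is feasible when its operating characteristic satisfies both risk
constraints

    Pa(p1) >= 1 - alpha      (producer protection at the AQL)
    Pa(p2) <= beta           (consumer protection at the LQL)

with p1 the failure probability at the stated quantile ratio and p2 the
failure probability at ratio 1.  The design objective is the average
sample number, which for these plans equals n, so the search scans n
upward and returns the first n with a feasible plan; among feasible
plans at that n the tie-break is lexicographic ascending (c2, c1, m).

The inner enumeration over (c1, c2, m) is vectorised: for each n only
two binomial CDF vectors (at p1 and at p2) are needed, and the MDSSP OC
over the full (c1, c2, m) grid is a broadcasted array expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distribution import QuantileSpec, failure_probability
from .oc import MDSSPPlan, RiskSpec, SSPPlan

__all__ = [
    "SearchBounds",
    "DesignResult",
    "InfeasibleDesignError",
    "aql_lql",
    "design_mdssp",
    "design_ssp",
    "generate_plan_table",
    "plan_table_to_csv",
]


class InfeasibleDesignError(ValueError):
    """No plan within the search bounds satisfies both risk constraints."""


@dataclass(frozen=True)
class SearchBounds:
    """Upper limits of the exhaustive design search."""

    n_max: int = 500
    c_max: int = 20
    m_max: int = 10

    def __post_init__(self) -> None:
        if self.n_max < 2 or self.c_max < 1 or self.m_max < 1:
            raise ValueError(f"invalid search bounds {self!r}")


@dataclass(frozen=True)
class DesignResult:
    """A designed plan together with the risk points it was checked at."""

    plan: MDSSPPlan | SSPPlan
    p1: float
    p2: float
    pa_p1: float
    pa_p2: float


def aql_lql(spec: QuantileSpec, theta: float) -> tuple[float, float]:
    """AQL and LQL failure probabilities (p1 at the stated ratio, p2 at ratio 1)."""
    p1 = failure_probability(spec, theta)
    p2 = failure_probability(
        QuantileSpec(q=spec.q, ratio=1.0, k=spec.k), theta
    )
    return p1, p2


def _mdssp_oc_grid(n: int, c_max: int, m_max: int, p: float) -> np.ndarray:
    """MDSSP OC over the (c1, c2, m) grid for one n; invalid combos -> NaN."""
    c_hi = min(c_max, n - 1)
    cdf = stats.binom.cdf(np.arange(c_hi + 1), n, p)
    a = cdf[:, None, None]                      # c1 axis
    b = cdf[None, :, None]                      # c2 axis
    m = np.arange(1, m_max + 1)[None, None, :]  # m axis
    oc = a + (b - a) * a**m
    c1_idx = np.arange(c_hi + 1)[:, None, None]
    c2_idx = np.arange(c_hi + 1)[None, :, None]
    oc = np.where(c2_idx > c1_idx, oc, np.nan)
    return oc


def design_mdssp(
    theta: float, risk: RiskSpec, bounds: SearchBounds = SearchBounds()
) -> DesignResult:
    """Exhaustive minimal-n MDSSP design.

    Scans n = 2..n_max; within each n enumerates all 0 <= c1 < c2 <=
    min(c_max, n-1) and 1 <= m <= m_max, keeping plans that meet both
    risk constraints.  Returns the plan at the smallest feasible n,
    ties broken by smallest (c2, c1, m) lexicographically.

    Raises
    ------
    InfeasibleDesignError
        If no plan within ``bounds`` is feasible; the message names the
        binding constraint.
    """
    p1, p2 = aql_lql(risk.quantile, theta)
    target = 1.0 - risk.alpha
    for n in range(2, bounds.n_max + 1):
        oc1 = _mdssp_oc_grid(n, bounds.c_max, bounds.m_max, p1)
        oc2 = _mdssp_oc_grid(n, bounds.c_max, bounds.m_max, p2)
        with np.errstate(invalid="ignore"):
            feasible = (oc1 >= target) & (oc2 <= risk.beta)
        if not feasible.any():
            continue
        c1s, c2s, ms = np.nonzero(feasible)
        order = np.lexsort((ms, c1s, c2s))
        i = order[0]
        plan = MDSSPPlan(n=n, c1=int(c1s[i]), c2=int(c2s[i]), m=int(ms[i] + 1))
        return DesignResult(
            plan=plan,
            p1=p1,
            p2=p2,
            pa_p1=float(oc1[c1s[i], c2s[i], ms[i]]),
            pa_p2=float(oc2[c1s[i], c2s[i], ms[i]]),
        )
    # diagnose which constraint binds: check each alone at the largest n
    oc1 = _mdssp_oc_grid(bounds.n_max, bounds.c_max, bounds.m_max, p1)
    oc2 = _mdssp_oc_grid(bounds.n_max, bounds.c_max, bounds.m_max, p2)
    with np.errstate(invalid="ignore"):
        prod_ok = bool((oc1 >= target).any())
        cons_ok = bool((oc2 <= risk.beta).any())
    binding = (
        "both constraints" if not prod_ok and not cons_ok
        else "the producer constraint Pa(p1) >= 1 - alpha" if not prod_ok
        else "the consumer constraint Pa(p2) <= beta" if not cons_ok
        else "the joint constraint set"
    )
    raise InfeasibleDesignError(
        f"no feasible MDSSP within bounds {bounds}; binding: {binding}"
    )


def design_ssp(
    theta: float, risk: RiskSpec, bounds: SearchBounds = SearchBounds()
) -> DesignResult:
    """Exhaustive minimal-n single-sampling-plan design (c tie-break ascending)."""
    p1, p2 = aql_lql(risk.quantile, theta)
    target = 1.0 - risk.alpha
    for n in range(1, bounds.n_max + 1):
        cs = np.arange(min(bounds.c_max, n - 1) + 1)
        oc1 = stats.binom.cdf(cs, n, p1)
        oc2 = stats.binom.cdf(cs, n, p2)
        feasible = (oc1 >= target) & (oc2 <= risk.beta)
        if feasible.any():
            c = int(cs[feasible][0])
            plan = SSPPlan(n=n, c=c)
            return DesignResult(
                plan=plan, p1=p1, p2=p2,
                pa_p1=float(oc1[c]), pa_p2=float(oc2[c]),
            )
    raise InfeasibleDesignError(f"no feasible SSP within bounds {bounds}")


def round_half_up(x: float, decimals: int = 4) -> float:
    """Round half away from zero, the convention used in printed plan tables."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def generate_plan_table(
    theta: float,
    betas=(0.25, 0.10, 0.05, 0.01),
    ratios=(2.0, 4.0, 6.0, 8.0, 10.0),
    ks=(0.5, 0.7, 1.0),
    alpha: float = 0.05,
    q: float = 0.5,
    bounds: SearchBounds = SearchBounds(),
    kind: str = "mdssp",
) -> pd.DataFrame:
    """Designed plans over a (beta, ratio, k) grid, long format.

    One row per grid cell with columns ``beta, ratio, k, n, c1, c2, m,
    pa_p1, pa_p2`` (``c1/c2/m`` replaced by ``c`` for ``kind='ssp'``).
    Infeasible cells are kept with NaN plan columns and an ``error``
    note rather than aborting the table.
    """
    if not (len(betas) and len(ratios) and len(ks)):
        raise ValueError("betas, ratios and ks must be non-empty")
    designer = {"mdssp": design_mdssp, "ssp": design_ssp}[kind]
    rows = []
    for beta in betas:
        for ratio in ratios:
            for k in ks:
                risk = RiskSpec(
                    alpha=alpha, beta=beta,
                    quantile=QuantileSpec(q=q, ratio=ratio, k=k),
                )
                row = {"beta": beta, "ratio": ratio, "k": k}
                try:
                    res = designer(theta, risk, bounds)
                except InfeasibleDesignError as exc:
                    row["error"] = str(exc)
                else:
                    plan = res.plan
                    row["n"] = plan.n
                    if kind == "mdssp":
                        row.update(c1=plan.c1, c2=plan.c2, m=plan.m)
                    else:
                        row["c"] = plan.c
                    row["pa_p1"] = res.pa_p1
                    row["pa_p2"] = res.pa_p2
                rows.append(row)
    return pd.DataFrame(rows)


def plan_table_to_csv(table: pd.DataFrame, path) -> None:
    """Write a plan table as CSV with probabilities at full precision."""
    table.to_csv(path, index=False)
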