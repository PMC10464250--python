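"""New Lomax Rayleigh distribution (NLRD).

The NLRD is a right-skewed lifetime law on (0, inf) with CDF

    G(t; theta, lam, sigma) = 1 - [1 + t^2 / (2 lam sigma^2)]^(-theta)

where ``theta`` is a shape parameter and ``lam``, ``sigma`` are scale
components.  The two scale components are redundant: every probability
depends on them only through the effective squared scale
``s^2 = lam * sigma^2``.  Equivalently, if ``X ~ Lomax(theta)`` then
``T = sqrt(2 s^2 X)`` is NLRD — the law is the square-root transform of a
unit-scale Lomax (Pareto type II) variable.

This module provides the closed-form CDF, PDF, quantile function, median,
inverse-CDF random sampling, and the failure probability of a truncated
life test, which drives every sampling-plan calculation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NLRDParams",
    "QuantileSpec",
    "nlrd_cdf",
    "nlrd_pdf",
    "nlrd_quantile",
    "nlrd_median",
    "nlrd_sample",
    "failure_probability",
]


@dataclass(frozen=True)
class NLRDParams:
    """Parameters of the New Lomax Rayleigh distribution.

    Parameters
    ----------
    theta : float
        Shape parameter, > 0.  Controls tail heaviness: smaller ``theta``
        gives a heavier right tail.
    lam : float
        Scale component, dimensionless, > 0.
    sigma : float
        Scale component in the units of the lifetime variable, > 0.

    Notes
    -----
    ``lam`` and ``sigma`` enter every probability only through the product
    ``lam * sigma**2``; parameter sets with equal ``theta`` and equal
    ``lam * sigma**2`` define the same distribution.  The canonical
    internal quantity is :attr:`scale_sq`.
    """

    theta: float
    lam: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("theta", "lam", "sigma"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")

    @property
    def scale_sq(self) -> float:
        """Effective squared scale ``s^2 = lam * sigma^2``."""
        return self.lam * self.sigma**2


@dataclass(frozen=True)
class QuantileSpec:
    """Specification of a truncated life test anchored at a quantile.

    Parameters
    ----------
    q : float
        Probability level of the anchoring quantile, in (0, 1).  The
        median (``q = 0.5``) is the usual choice.
    ratio : float
        Quantile ratio ``r = t_q / t_q0``: the true q-quantile expressed
        as a multiple of the specified (contracted) quantile.  ``r >= 1``;
        ``r > 1`` means quality better than specification.
    k : float
        Termination ratio ``k = t0 / t_q0``: the test truncation time as
        a multiple of the specified quantile.
    """

    q: float = 0.5
    ratio: float = 2.0
    k: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError(f"q must lie in (0, 1), got {self.q!r}")
        if not (self.ratio >= 1.0):
            raise ValueError(f"ratio must be >= 1, got {self.ratio!r}")
        if not (self.k > 0.0):
            raise ValueError(f"k must be > 0, got {self.k!r}")


def _as_nonnegative_array(t, name: str = "t") -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0.0) or np.any(np.isnan(arr)):
        raise ValueError(f"{name} must be non-negative and finite")
    return arr


def nlrd_cdf(t, params: NLRDParams):
    """CDF of the NLRD: ``1 - [1 + t^2/(2 lam sigma^2)]^(-theta)``.

    Evaluated in log space (``expm1``/``log1p``) so small probabilities
    near ``t = 0`` keep full relative precision.
    """
    arr = _as_nonnegative_array(t)
    z = arr**2 / (2.0 * params.scale_sq)
    out = -np.expm1(-params.theta * np.log1p(z))
    return out if out.ndim else float(out)


def nlrd_pdf(t, params: NLRDParams):
    """PDF of the NLRD: ``(theta t / (lam sigma^2)) [1 + t^2/(2 lam sigma^2)]^(-(theta+1))``."""
    arr = _as_nonnegative_array(t)
    s2 = params.scale_sq
    z = arr**2 / (2.0 * s2)
    out = (params.theta * arr / s2) * np.exp(-(params.theta + 1.0) * np.log1p(z))
    return out if out.ndim else float(out)


def nlrd_quantile(q, params: NLRDParams):
    """Quantile function: ``t_q = sigma * sqrt(2 lam ((1-q)^(-1/theta) - 1))``.

    Inverse of :func:`nlrd_cdf`.  ``q`` must lie strictly inside (0, 1);
    the limits would be 0 and infinity and are rejected.
    """
    arr = np.asarray(q, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0) or np.any(np.isnan(arr)):
        raise ValueError("q must lie strictly in (0, 1)")
    # (1-q)^(-1/theta) - 1 computed as expm1(-log1p(-q)/theta) for accuracy
    growth = np.expm1(-np.log1p(-arr) / params.theta)
    out = np.sqrt(2.0 * params.scale_sq * growth)
    return out if out.ndim else float(out)


def nlrd_median(params: NLRDParams) -> float:
    """Median lifetime, ``t_0.5 = sigma * sqrt(2 lam (2^(1/theta) - 1))``."""
    return float(nlrd_quantile(0.5, params))


def nlrd_sample(n: int, params: NLRDParams, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. NLRD lifetimes by inverse-CDF sampling.

    Parameters
    ----------
    n : int
        Number of draws, >= 1.
    seed : int, numpy.random.Generator, or None
        Seed or generator.  An integer seed gives reproducible draws via
        ``numpy.random.default_rng`` (PCG64).
    """
    if int(n) < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=int(n))
    # u == 0 maps to the support minimum; quantile() rejects exact 0/1
    growth = np.expm1(-np.log1p(-u) / params.theta)
    return np.sqrt(2.0 * params.scale_sq * growth)


def failure_probability(spec: QuantileSpec, theta: float) -> float:
    """Probability a lifetime fails before the truncation time ``t0 = k t_q0``.

    For a lot whose true q-quantile sits at ``ratio`` times the specified
    quantile, the NLRD failure probability at truncation reduces to

        p = 1 - [1 + k^2 ((1-q)^(-1/theta) - 1) / ratio^2]^(-theta)

    which depends only on ``theta``, ``k``, ``q`` and ``ratio`` — the
    scale components ``lam`` and ``sigma`` cancel.  This is why plan
    tables computed at different ``lam`` values coincide.

    The acceptable quality level p1 is this value at the stated ratio;
    the limiting quality level p2 is the value at ratio 1.
    """
    if not np.isfinite(theta) or theta <= 0.0:
        raise ValueError(f"theta must be finite and > 0, got {theta!r}")
    growth = np.expm1(-np.log1p(-spec.q) / theta)
    z = (spec.k / spec.ratio) ** 2 * growth
    return float(-np.expm1(-theta * np.log1p(z)))
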