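"""Maximum-likelihood fitting and goodness of fit for lifetime models.

The model catalog contains the New Lomax Rayleigh distribution and the
comparator laws commonly fitted to right-skewed lifetime data: Rayleigh,
Lomax, Pareto type II, power Lomax and Lomax-Rayleigh.  Each model is
fitted by maximizing the log-likelihood over log-transformed parameters
(so positivity is built in) with a multistart Nelder-Mead/L-BFGS-B
scheme; standard errors come from the numerically inverted observed
information.

Goodness of fit is summarised by the one-sample Kolmogorov-Smirnov
statistic with its asymptotic p-value, the Cramer-von Mises statistic
W^2 and the Anderson-Darling statistic A^2 (classical forms, no
small-sample modification), and the usual information criteria
(AIC, BIC, CAIC, HQIC).

A note on the NLRD scale parameters: the likelihood depends on lam and
sigma only through s^2 = lam * sigma^2, so the three-parameter fit is
not identifiable beyond (theta, s^2).  The fitter therefore estimates
(theta, s^2) and reports the factorization lam = s^2, sigma = 1 with an
explicit non-uniqueness flag; fixing sigma gives the identifiable
two-parameter mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .distribution import NLRDParams, nlrd_cdf, nlrd_pdf

__all__ = [
    "FitResult",
    "GOFReport",
    "MODELS",
    "fit_mle_nlrd",
    "fit_model",
    "comparator_cdf",
    "comparator_pdf",
    "gof_statistics",
    "info_criteria",
    "compare_models",
]


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    model: str
    params: dict[str, float]
    se: dict[str, float]
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    notes: list[str] = field(default_factory=list)

    @property
    def neg2ll(self) -> float:
        return -2.0 * self.loglik

    def cdf(self, t):
        return MODELS[self.model].cdf(t, self.params)

    def pdf(self, t):
        return MODELS[self.model].pdf(t, self.params)


@dataclass
class GOFReport:
    """Goodness-of-fit statistics and information criteria for one fit."""

    ks_D: float
    ks_p: float
    W_star: float
    A_star: float
    neg2ll: float
    AIC: float
    BIC: float
    CAIC: float
    HQIC: float


# ---------------------------------------------------------------------------
# model catalog


@dataclass(frozen=True)
class _Model:
    name: str
    param_names: tuple[str, ...]
    cdf: callable
    pdf: callable
    logpdf: callable
    init: callable  # data -> list of starting parameter dicts


def _nlrd_cdf_p(t, p):
    return nlrd_cdf(t, NLRDParams(p["theta"], p.get("lam", 1.0), p.get("sigma", 1.0)))


def _nlrd_pdf_p(t, p):
    return nlrd_pdf(t, NLRDParams(p["theta"], p.get("lam", 1.0), p.get("sigma", 1.0)))


def _nlrd_logpdf(t, p):
    s2 = p["lam"] * p.get("sigma", 1.0) ** 2
    z = t**2 / (2.0 * s2)
    return np.log(p["theta"] * t / s2) - (p["theta"] + 1.0) * np.log1p(z)


def _nlrd_init(data):
    med = float(np.median(data))
    starts = []
    for theta in (0.5, 1.0, 2.0, 5.0):
        # match the median: s^2 = med^2 / (2 (2^(1/theta) - 1))
        s2 = med**2 / (2.0 * np.expm1(np.log(2.0) / theta))
        starts.append({"theta": theta, "lam": s2})
    return starts


def _rayleigh_init(data):
    # MLE has closed form: sigma^2 = mean(t^2)/2; jitter for multistart
    s = float(np.sqrt(np.mean(np.square(data)) / 2.0))
    return [{"sigma": s}, {"sigma": 1.5 * s}]


def _lomax_init(data):
    med = float(np.median(data))
    return [
        {"theta": th, "lam": med / np.expm1(np.log(2.0) / th)}
        for th in (0.5, 1.0, 2.0, 5.0)
    ]


def _plomax_init(data):
    med = float(np.median(data))
    starts = []
    for alpha in (1.0, 2.0):
        for beta in (1.0, 2.0):
            lam = med**beta / np.expm1(np.log(2.0) / alpha)
            starts.append({"alpha": alpha, "beta": beta, "lam": lam})
    return starts


def _lrd_init(data):
    med = float(np.median(data))
    return [
        {"alpha": np.expm1(np.log(2.0) / th) / med**2, "theta": th}
        for th in (0.5, 1.0, 2.0, 5.0)
    ]


MODELS: dict[str, _Model] = {
    "nlrd": _Model(
        "nlrd", ("theta", "lam"), _nlrd_cdf_p, _nlrd_pdf_p, _nlrd_logpdf, _nlrd_init
    ),
    "rayleigh": _Model(
        "rayleigh",
        ("sigma",),
        lambda t, p: stats.rayleigh.cdf(t, scale=p["sigma"]),
        lambda t, p: stats.rayleigh.pdf(t, scale=p["sigma"]),
        lambda t, p: stats.rayleigh.logpdf(t, scale=p["sigma"]),
        _rayleigh_init,
    ),
    "lomax": _Model(
        "lomax",
        ("theta", "lam"),
        lambda t, p: stats.lomax.cdf(t, p["theta"], scale=p["lam"]),
        lambda t, p: stats.lomax.pdf(t, p["theta"], scale=p["lam"]),
        lambda t, p: stats.lomax.logpdf(t, p["theta"], scale=p["lam"]),
        _lomax_init,
    ),
    # Pareto type II is the Lomax law under its alternative name/notation
    "pareto2": _Model(
        "pareto2",
        ("alpha", "sigma"),
        lambda t, p: stats.lomax.cdf(t, p["alpha"], scale=p["sigma"]),
        lambda t, p: stats.lomax.pdf(t, p["alpha"], scale=p["sigma"]),
        lambda t, p: stats.lomax.logpdf(t, p["alpha"], scale=p["sigma"]),
        lambda data: [
            {"alpha": d["theta"], "sigma": d["lam"]} for d in _lomax_init(data)
        ],
    ),
    "power_lomax": _Model(
        "power_lomax",
        ("alpha", "beta", "lam"),
        lambda t, p: -np.expm1(
            -p["alpha"] * np.log1p(np.asarray(t, float) ** p["beta"] / p["lam"])
        ),
        lambda t, p: np.exp(
            np.log(p["alpha"] * p["beta"] / p["lam"])
            + (p["beta"] - 1.0) * np.log(np.asarray(t, float))
            - (p["alpha"] + 1.0) * np.log1p(np.asarray(t, float) ** p["beta"] / p["lam"])
        ),
        lambda t, p: (
            np.log(p["alpha"] * p["beta"] / p["lam"])
            + (p["beta"] - 1.0) * np.log(t)
            - (p["alpha"] + 1.0) * np.log1p(t ** p["beta"] / p["lam"])
        ),
        _plomax_init,
    ),
    "lomax_rayleigh": _Model(
        "lomax_rayleigh",
        ("alpha", "theta"),
        lambda t, p: -np.expm1(
            -p["theta"] * np.log1p(p["alpha"] * np.asarray(t, float) ** 2)
        ),
        lambda t, p: (
            2.0 * p["alpha"] * p["theta"] * np.asarray(t, float)
            * np.exp(-(p["theta"] + 1.0) * np.log1p(p["alpha"] * np.asarray(t, float) ** 2))
        ),
        lambda t, p: (
            np.log(2.0 * p["alpha"] * p["theta"] * t)
            - (p["theta"] + 1.0) * np.log1p(p["alpha"] * t**2)
        ),
        _lrd_init,
    ),
}


def comparator_cdf(model: str, params: dict[str, float], t):
    """CDF of a catalog model at lifetimes t."""
    return MODELS[model].cdf(t, _validated(model, params))


def comparator_pdf(model: str, params: dict[str, float], t):
    """PDF of a catalog model at lifetimes t."""
    return MODELS[model].pdf(t, _validated(model, params))


def _validated(model: str, params: dict[str, float]) -> dict[str, float]:
    spec = MODELS[model]
    for name in spec.param_names:
        if name not in params:
            raise ValueError(f"model {model!r} needs parameter {name!r}")
        if not np.isfinite(params[name]) or params[name] <= 0.0:
            raise ValueError(f"{name} must be finite and > 0, got {params[name]!r}")
    return params


# ---------------------------------------------------------------------------
# maximum likelihood


def _hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar f at x."""
    k = x.size
    H = np.empty((k, k))
    steps = h * np.maximum(np.abs(x), 1.0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return H


def fit_model(data, model: str, fixed: dict[str, float] | None = None) -> FitResult:
    """Fit a catalog model to positive lifetime data by maximum likelihood.

    Optimizes over log-parameters (multistart Nelder-Mead followed by an
    L-BFGS-B polish), converging to 1e-8 on the log-likelihood.  Standard
    errors are delta-method transforms of the inverted observed
    information in log-parameter space.
    """
    arr = np.sort(np.asarray(data, dtype=float))
    if arr.size < 5:
        raise ValueError(f"need at least 5 observations, got {arr.size}")
    if np.any(arr <= 0.0) or np.any(~np.isfinite(arr)):
        raise ValueError("lifetimes must be strictly positive and finite")
    spec = MODELS[model]
    fixed = dict(fixed or {})
    free = [name for name in spec.param_names if name not in fixed]
    if not free:
        raise ValueError("at least one parameter must be free")

    def negll_log(logx: np.ndarray) -> float:
        if np.any(np.abs(logx) > 500.0):  # keep exp() in range
            return 1e12
        p = dict(fixed)
        p.update({name: float(np.exp(v)) for name, v in zip(free, logx)})
        with np.errstate(all="ignore"):
            ll = np.sum(spec.logpdf(arr, p))
        return -ll if np.isfinite(ll) else 1e12

    best = None
    for start in spec.init(arr):
        x0 = np.log([max(start.get(name, 1.0), 1e-8) for name in free])
        res = optimize.minimize(
            negll_log, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
        )
        res = optimize.minimize(negll_log, res.x, method="L-BFGS-B",
                                options={"ftol": 1e-12, "gtol": 1e-10})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(f"MLE for model {model!r} failed to converge: {best}")

    params = dict(fixed)
    params.update({name: float(np.exp(v)) for name, v in zip(free, best.x)})
    se = {name: float("nan") for name in free}
    try:
        H = _hessian(negll_log, best.x)
        cov_log = np.linalg.inv(H)
        diag = np.diag(cov_log)
        if np.all(diag > 0):
            # delta method: Var(exp(u)) ~ exp(u)^2 Var(u)
            for i, name in enumerate(free):
                se[name] = float(np.exp(best.x[i]) * np.sqrt(diag[i]))
    except np.linalg.LinAlgError:
        pass
    return FitResult(
        model=model,
        params=params,
        se=se,
        loglik=float(-best.fun),
        n_params=len(free),
        n_obs=int(arr.size),
        converged=True,
    )


def fit_mle_nlrd(data, fix_sigma: float | None = None) -> FitResult:
    """Maximum-likelihood fit of the NLRD.

    With ``fix_sigma`` set (typically 1), fits the identifiable
    two-parameter mode (theta, lam).  With ``fix_sigma`` unset, fits the
    identifiable pair (theta, s^2 = lam * sigma^2) and reports
    lam = s^2, sigma = 1 with a note that the (lam, sigma) factorization
    is not unique.
    """
    if fix_sigma is not None:
        if fix_sigma <= 0:
            raise ValueError(f"fix_sigma must be > 0, got {fix_sigma!r}")
        result = fit_model(data, "nlrd", fixed={"sigma": float(fix_sigma)})
        return result
    result = fit_model(data, "nlrd", fixed={"sigma": 1.0})
    result.params["sigma"] = 1.0
    result.notes.append(
        "scale factorization non-unique: only theta and s^2 = lam*sigma^2 are "
        "identifiable; reported lam is s^2 with sigma normalised to 1"
    )
    return result


# ---------------------------------------------------------------------------
# goodness of fit


def gof_statistics(data, cdf) -> dict[str, float]:
    """K-S, Cramer-von Mises and Anderson-Darling statistics for a fitted CDF.

    Classical definitions over the order statistics t_(1) <= ... <= t_(n)
    with u_(i) = F(t_(i)):

        D   = max_i max(i/n - u_(i), u_(i) - (i-1)/n)
        W^2 = sum_i (u_(i) - (2i-1)/(2n))^2 + 1/(12n)
        A^2 = -n - (1/n) sum_i (2i-1) [ln u_(i) + ln(1 - u_(n+1-i))]

    The K-S p-value uses the asymptotic Kolmogorov distribution at
    sqrt(n) * D, with no correction for estimated parameters.
    """
    arr = np.sort(np.asarray(data, dtype=float))
    n = arr.size
    u = np.asarray(cdf(arr), dtype=float)
    i = np.arange(1, n + 1)
    D = float(np.max(np.maximum(i / n - u, u - (i - 1) / n)))
    ks_p = float(stats.kstwobign.sf(np.sqrt(n) * D))
    W2 = float(np.sum((u - (2 * i - 1) / (2 * n)) ** 2) + 1.0 / (12 * n))
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        warnings.warn("fitted CDF hit 0 or 1 at a data point; clipping for A^2")
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
    A2 = float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))))
    return {"ks_D": D, "ks_p": ks_p, "W_star": W2, "A_star": A2}


def info_criteria(fit: FitResult) -> dict[str, float]:
    """Information criteria from a converged fit.

    AIC = -2ll + 2k;  BIC = -2ll + k ln n;
    CAIC = AIC + 2k(k+1)/(n-k-1)  (the small-sample corrected AIC);
    HQIC = -2ll + 2k ln(ln n).
    """
    n, k = fit.n_obs, fit.n_params
    if n <= np.e:
        raise ValueError("HQIC undefined for n <= e")
    if n <= k + 1:
        raise ValueError("corrected AIC undefined for n <= k + 1")
    neg2ll = fit.neg2ll
    aic = neg2ll + 2 * k
    return {
        "neg2ll": neg2ll,
        "AIC": aic,
        "BIC": neg2ll + k * np.log(n),
        "CAIC": aic + 2 * k * (k + 1) / (n - k - 1),
        "HQIC": neg2ll + 2 * k * np.log(np.log(n)),
    }


def gof_report(data, fit: FitResult) -> GOFReport:
    """Full goodness-of-fit report (distance statistics + criteria)."""
    gof = gof_statistics(data, fit.cdf)
    ic = info_criteria(fit)
    return GOFReport(**gof, **ic)


def compare_models(data, models=("nlrd", "rayleigh", "lomax", "pareto2",
                                 "power_lomax", "lomax_rayleigh")) -> pd.DataFrame:
    """Fit several models and rank them by AIC.

    Returns a long-format table with one row per model: parameter
    estimates, distance statistics and information criteria, sorted by
    AIC ascending with per-criterion minima flagged.  Per-model fit
    failures are recorded in an ``error`` column rather than raised.
    """
    if len(models) < 1:
        raise ValueError("need at least one model")
    rows = []
    for model in models:
        row: dict = {"model": model}
        try:
            fit = fit_model(data, model)
            row["params"] = ", ".join(
                f"{k}={v:.4f}" for k, v in fit.params.items()
            )
            row.update(gof_statistics(data, fit.cdf))
            row.update(info_criteria(fit))
        except Exception as exc:  # per-model failure is not fatal
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    if "AIC" in table:
        table = table.sort_values("AIC", na_position="last").reset_index(drop=True)
        for crit in ("AIC", "BIC", "CAIC", "HQIC", "ks_D", "W_star", "A_star"):
            if crit in table and table[crit].notna().any():
                table[f"best_{crit}"] = table[crit] == table[crit].min()
    return table
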