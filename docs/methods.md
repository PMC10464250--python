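# Methods

## The lifetime model

The New Lomax Rayleigh distribution (NLRD) has CDF
`G(t) = 1 − [1 + t²/(2λσ²)]^(−θ)` on `t > 0`. It arises as the
square-root transform of a scaled Lomax (Pareto type II) variable: if
`X ~ Lomax(θ)` with unit scale then `T = sqrt(2λσ² X)` is NLRD. Two
consequences shape the implementation:

* **Scale redundancy.** The two scale components enter every probability
  only through `s² = λσ²`. Internally all formulas use `s²`; the public
  API accepts `(θ, λ, σ)` so published parameter tables can be keyed in
  as printed. Two parameter sets with equal `θ` and equal `λσ²` produce
  bitwise-identical probabilities.
* **Non-identifiability in fitting.** A likelihood can determine only
  `(θ, s²)`. The three-parameter fit therefore estimates `(θ, s²)` and
  reports `λ = s², σ = 1` with an explicit non-uniqueness note; fixing
  `σ` gives the identifiable two-parameter mode used for the bundled
  failure-time data.

Numerics: `(1+x)^(−θ)` terms are evaluated as `expm1/log1p` compositions
so probabilities near 0 and 1 keep full relative precision;
`(1−q)^(−1/θ) − 1` is computed as `expm1(−log1p(−q)/θ)`. The quantile
function rejects `q ∈ {0, 1}` (the limits are 0 and ∞) rather than
returning infinities, and parameter validation rejects non-positive
`θ, λ, σ`.

## The truncated life test

A lot's items are tested until `t0 = k·t_q0`, a multiple of the
*specified* life quantile `t_q0` (the contract value; `q = 0.5` —
median life — throughout the published tables). If the lot's *true*
quantile is `t_q = r·t_q0`, the per-item failure probability reduces to

    p(θ, k, r, q) = 1 − [1 + k²((1−q)^(−1/θ) − 1)/r²]^(−θ),

independent of `λ` and `σ`. The acceptable quality level is
`p1 = p(θ, k, r, q)` at the stated `r > 1` (good lots), the limiting
quality level `p2 = p(θ, k, 1, q)` (lots exactly at specification).
`p` is strictly increasing in `k`, strictly decreasing in `r`, so
`p2 > p1` whenever `r > 1`. Because `λ` cancels, design tables computed
at different `λ` coincide cell for cell; the test suite verifies the
cancellation numerically through the explicit CDF route (calibrating
`σ` from each `λ` and evaluating `G(k·t_q0)`), to 1e−12 relative.

## Sampling plans

The lot model is binomial: failure counts are `Binomial(n, p)`; the lot
size `N` plays no computational role. The MDSSP operating characteristic
is `Pa(p) = A + (B−A)·A^m` with `A = P(d ≤ c1)`, `B = P(d ≤ c2)`; the
SSP's is `P(d ≤ c)`. Binomial CDFs go through the regularized
incomplete beta function. ASN equals `n` for both plan families (every
lot draws exactly `n` items regardless of outcome); no
deferred-sentencing inflation is modelled.

**Sentencing rule.** The operating procedure's bands are accept
(`d ≤ c1`), conditional (`c1 < d ≤ c2`, accept iff each of the `m` most
recent lots had `d ≤ c1`), reject (`d > c2`) — the three-band rule that
matches the OC function (a literal reading of the procedure's first
clause would contradict its conditional clause, so the consistent rule
is implemented). Failures are counted inclusively (`lifetime ≤ t0`).
With fewer than `m` prior lots the conditional band rejects by default —
the conservative, consumer-protecting choice — configurable via
`cold_start='accept'`. Only past lots are consulted.

For i.i.d. lots the stationary acceptance frequency equals `Pa(p)`
exactly; the Monte-Carlo validator simulates 10⁵ lots with the rolling
window and checks agreement within 3 standard errors. Because
consecutive decisions share window entries they are serially correlated,
so the standard error is estimated by batch means (batches ≥ 50·m lots)
rather than the i.i.d. binomial formula, which understates it.

## Design search

Minimize `n` subject to `Pa(p1) ≥ 1−α` and `Pa(p2) ≤ β`, exhaustively
over `n` ascending (so the first feasible `n` is minimal), with default
bounds `n ≤ 500`, `c ≤ 20`, `m ≤ 10` — all published plans fall well
inside; bounds are user-overridable and an infeasibility error names the
binding constraint. Within one `n` the whole `(c1, c2, m)` grid is a
single broadcast array expression over two binomial CDF vectors, so a
full 60-cell table regenerates in well under a second. Ties at the
minimal `n` are broken lexicographically by ascending `(c2, c1, m)`; the
published tables evidently used a different (unstated) tie-break, so
tuples at equal `n` can differ — e.g. we select `(37, 3, 7, 2)` where
the published table prints `(37, 3, 9, 2)`; both are feasible at the
same minimal `n = 37`, and the test suite asserts minimal-`n` agreement
plus feasibility of the printed tuples rather than tuple identity.
Table cells print probabilities rounded half-up to 4 decimals; CSV
output keeps full precision.

## Fitting and goodness of fit

Each catalog model (NLRD, Rayleigh, Lomax, Pareto II, power Lomax,
Lomax-Rayleigh) is fitted by maximizing the log-likelihood over
log-transformed parameters — multistart Nelder-Mead (moment-style starts
across a shape grid, each matching the sample median) polished by
L-BFGS-B, tolerance 1e−12 on the objective. Standard errors are
delta-method transforms of the inverted central-difference observed
information; on a non-identifiable ridge they are large and should be
read as such.

Distance statistics use the classical order-statistic forms
(`u_(i) = F(t_(i))`):

* `D = max_i max(i/n − u_(i), u_(i) − (i−1)/n)`, p-value from the
  asymptotic Kolmogorov distribution at `√n·D`. No correction for
  estimated parameters is applied; this matches common practice for
  these tables but is anti-conservative (the p-value is biased upward
  when parameters are fitted from the same data).
* `W² = Σ(u_(i) − (2i−1)/(2n))² + 1/(12n)` and
  `A² = −n − (1/n)Σ(2i−1)[ln u_(i) + ln(1 − u_(n+1−i))]`, without
  small-sample modification factors (a dialect choice; definitions
  vary). `u` values of exactly 0 or 1 are clipped at 1e−12 with a
  warning before `A²`.

Information criteria: `AIC = −2ℓℓ + 2k`, `BIC = −2ℓℓ + k·ln n`,
`HQIC = −2ℓℓ + 2k·ln ln n`, and `CAIC = AIC + 2k(k+1)/(n−k−1)` — in
this package CAIC denotes the small-sample *corrected* AIC, the
definition consistent with the published comparator tables this module
reproduces (not Bozdogan's consistent AIC).

Model-comparison caveat: the Lomax-Rayleigh comparator
(`1 − (1+αt²)^(−θ)`) is the NLRD family in another parameterization,
and power Lomax at `β = 2` nests it; on NLRD data their maximized
likelihoods tie (or the 3-parameter model edges ahead within its AIC
penalty by sampling noise). Rankings should be read accordingly; the
tests assert clear AIC separation only against the non-nested laws.

A note on the bundled failure-time fit: the two-parameter MLE on the 30
repairable-component failure times is `θ̂ = 1.9274, λ̂ = 1.8690`
(σ = 1), at which the K-S distance is `D = 0.0863` (p ≈ 0.979). A
commonly cited `λ̂` of 1.8958 for these data is not a maximizer of this
likelihood — it lies on the `λσ²` ridge (1.8958 × 0.9929² ≈ 1.8690) —
and evaluating the CDF there gives `D = 0.0891`, not the cited 0.0862;
the package reports the true optimum.

## Synthetic data

The generator draws i.i.d. NLRD lifetimes by inverse-CDF sampling from
a single seeded PCG64 generator and arranges them into lots
(`lot, lifetime` CSV). It emulates exactly the i.i.d.-within-lot,
i.i.d.-across-lot world the OC algebra assumes; real inspection streams
exhibit drift, autocorrelation between lots and measurement rounding,
none of which are modelled — passing simulation checks validate the
plan algebra, not robustness to those departures. Default validation
sizes (10⁵ lots for the OC check; 20 replicates of n = 5000 for
recovery; n = 500, 10 replicates for model ranking) were chosen as the
smallest sizes at which Monte-Carlo error is comfortably below the
tolerances being checked.

## Known limitations

* No censored-data or Bayesian estimation; no hazard/reliability
  function API.
* The K-S p-value is asymptotic and uncorrected for estimated
  parameters (see above).
* ASN = n by definition here; plans are not compared on expected total
  inspection including deferred resolution.
* The worldwide suicide-rate extract is not bundled; fits to it run
  only when the user supplies the file (single-column CSV).
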