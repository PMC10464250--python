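# mdssp

Design, evaluation and application of **multiple dependent state sampling
plans (MDSSP)** for truncated life tests when the quality variable follows
the **New Lomax Rayleigh distribution (NLRD)**.

## The problem

Attribute acceptance sampling sentences a lot from the number of failures
`d` observed when `n` sampled items are life-tested up to a truncation time
`t0`. The single sampling plan (SSP) accepts iff `d <= c`. The MDSSP
exploits the serial structure of a continuous inspection stream to get by
with a smaller sample: a lot is

* accepted outright when `d <= c1`,
* rejected outright when `d > c2`,
* and in the borderline band `c1 < d <= c2` accepted only if each of the
  `m` preceding lots was accepted outright.

This family of plans is used in statistical quality control wherever lots
arrive in sequence — manufacturing reliability testing, and increasingly
health-indicator monitoring (e.g. sentencing groups of regional suicide or
mortality rates against a target median).

## The model

Lifetimes follow the NLRD, a right-skewed law on `(0, ∞)` with CDF

    G(t; θ, λ, σ) = 1 − [1 + t² / (2λσ²)]^(−θ)

(shape `θ > 0`, scale components `λ, σ > 0`; only `θ` and `s² = λσ²` are
identifiable — the law is the square root of a scaled Lomax variable).
For a median-anchored truncated life test with termination ratio
`k = t0 / t_q0` and quantile ratio `r = t_q / t_q0`, the per-item failure
probability reduces to

    p = 1 − [1 + k² ((1−q)^(−1/θ) − 1) / r²]^(−θ)

in which `λ` and `σ` cancel. The acceptable quality level `p1` uses the
stated ratio `r > 1`; the limiting quality level `p2` uses `r = 1`. With
`A = P(d ≤ c1)` and `B = P(d ≤ c2)` binomial CDFs, the MDSSP operating
characteristic is

    Pa(p) = A + (B − A) · A^m

and a plan is designed by minimizing `n` subject to
`Pa(p1) ≥ 1 − α` and `Pa(p2) ≤ β`.

The package also fits the NLRD (and the Rayleigh, Lomax, Pareto type II,
power Lomax and Lomax-Rayleigh comparators) to lifetime data by maximum
likelihood, with Kolmogorov–Smirnov, Cramér–von Mises and
Anderson–Darling statistics and AIC/BIC/CAIC/HQIC model ranking.

## Worked example

Design a plan for sentencing lots of worldwide late-adolescent suicide
rates, with the NLRD shape fitted from WHO data (`θ = 1.0559`), producer
and consumer risks of 5%, a median-anchored test truncated at half the
specified median (`k = 0.5`) and quantile ratio 2:

```sh
$ mdssp --output json design --theta 1.0559 --alpha 0.05 --beta 0.05 --k 0.5 --ratio 2
{
  "n": 37,
  "c1": 3,
  "c2": 7,
  "m": 2,
  "p1": 0.05779102489286509,
  "p2": 0.19771285601567454,
  "pa_p1": 0.9501172962076906,
  "pa_p2": 0.049299811945317025
}
```

Read: inspect 37 units per lot; accept at ≤ 3 failures, reject at > 7,
and in between accept only if both preceding lots were accepted outright.
The plan accepts 95.0% of lots at the AQL failure rate `p1 = 0.0578` and
only 4.93% at the LQL rate `p2 = 0.1977`. (At equal `n = 37` several
`(c1, c2, m)` tuples are feasible; the search breaks ties by smallest
`(c2, c1, m)`.)

Sentence a lot of 30 repairable components (the bundled failure-time
data) under plan `(30, 2, 4, 1)` with truncation at 0.65 days:

```sh
$ mdssp --output json sentence --plan 30,2,4,1 --t0 0.65
{
  "d": 6,
  "decision": "reject",
  "band": "outright-reject"
}
```

Six failures exceed `c2 = 4`, so the lot is rejected regardless of
history. Fitting the NLRD to the same data (`σ` fixed at 1):

```sh
$ mdssp --output json fit --fix-sigma 1
{
  "model": "nlrd",
  "params": { "sigma": 1.0, "theta": 1.927..., "lam": 1.868... },
  "ks_D": 0.0862...,
  "ks_p": 0.9788...,
  ...
}
```

The K-S distance 0.086 (p ≈ 0.98) shows the NLRD fits these right-skewed
failure times well. The same functionality is available as a library:

```python
from mdssp import QuantileSpec, RiskSpec, design_mdssp

risk = RiskSpec(alpha=0.05, beta=0.05,
                quantile=QuantileSpec(q=0.5, ratio=2.0, k=0.5))
result = design_mdssp(1.0559, risk)
print(result.plan.n)   # 37
```

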