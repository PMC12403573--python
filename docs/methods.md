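# Methods

This note documents the statistical machinery behind `nextri`: the models,
the numerical choices, the defaults and why they were chosen, and what the
synthetic-data tests do and do not establish about real laboratory data.

## The BCPE distribution

Concentrations are modelled with the Box–Cox power exponential family.
A positive value `y` is standardized through a Box–Cox map,

    z = ((y/mu)^nu - 1) / (nu*sigma)        nu != 0
    z = log(y/mu) / sigma                   nu == 0

and `z` follows a standard power exponential with kurtosis parameter `tau`
(density ∝ exp(-|z/c|^tau / 2) with c chosen so Var(Z) = 1). The four
parameters have direct clinical readings: `mu` is the median concentration,
`sigma` the relative spread (≈ CV for small sigma), `nu` the skewness power
(1 = symmetric on the raw scale, 0 = log-symmetric), and `tau` the tail
weight (2 = normal-type tails, < 2 heavier).

Because the Box–Cox map reaches only `z > -1/(sigma*nu)` (for `nu > 0`;
mirrored for `nu < 0`), the exact distribution is the power exponential
*truncated* to that range. `nextri` implements the truncated, exactly
normalized form: the pdf integrates to 1 for every admissible parameter
combination and quantile/cdf are exact inverses. In the biomarker regime
(`sigma` ≈ 0.2–0.3, `|nu|` ≤ 1, `tau` ≈ 2) the truncated mass is below
1e-15 — usually below 1e-40 — so the convenient untruncated formulas
(available via `truncate=False`) and the median property `quantile(0.5) =
mu` hold to machine precision. The truncation only becomes visible in
deliberately extreme corners such as `sigma = 0.3, |nu| = 1, tau = 1.5`,
where the untruncated density would integrate to ≈ 0.9983.

Special cases used as independent oracles in the tests: `(nu=1, tau=2)` is
Normal(mu, mu·sigma); `(nu=0, tau=2)` is Lognormal(log mu, sigma).

## The centile model

`BCPECentileModel` fits `Y_i ~ BCPE(mu(age_i), sigma, nu, tau)` by
maximizing the penalized log-likelihood

    sum_i log f(y_i) - (lambda/2) * Int mu''(t)^2 dt.

Design choices, in the order they matter:

- **mu(age) is a cubic B-spline on an identity link** with 13 interior
  knots spread evenly over the observed age range. The identity link makes
  the penalty exactly the curvature of the median curve and makes the
  fitted 50th centile equal `mu(age)` itself; positivity of `mu` is guarded
  by a barrier during optimization and checked after the fit. The penalty
  matrix Int B''B''ᵀ is computed exactly (2-point Gauss–Legendre per knot
  interval; cubic-spline second derivatives are piecewise linear).
- **sigma, nu, tau are constant** (intercept-only, fitted on log/identity/
  log scales). Age-varying spread or skewness is a plausible extension but
  not implemented; `SmoothSpec` validates and refuses spline requests for
  them rather than silently ignoring the option.
- **Smoothness is specified as effective degrees of freedom (edf)**, the
  trace of the smoother matrix B(BᵀWB + lambda·P)⁻¹BᵀW with W the observed
  per-record likelihood curvature in `mu`. The default target edf = 5 is
  the conventional flexibility for adult biomarker medians — enough for one
  plateau and one rise, too stiff to chase noise. `lambda` is found by
  Brent root-finding on the monotone edf(lambda) map, re-weighted from the
  current fit until the realized edf is within 0.05 of target; the fitted
  edf is reported and tested to land within 0.2.
- **Optimization** is L-BFGS-B over (spline coefficients, log sigma, nu,
  log tau) with an analytic gradient in the coefficients and central
  differences for the three scalars, wrapped in an outer loop that records
  the penalized deviance after each pass. The recorded sequence is
  non-increasing by construction (a candidate that increases the objective
  is discarded) and the convergence flag requires a relative deviance
  change below 1e-6 (at most 200 outer passes). Initialisation: `mu⁰` from
  an 11-year running median projected onto the basis, `sigma⁰ =
  IQR/(1.349·median)`, `nu⁰ = 1`, `tau⁰ = 2` (the normal special case).
- **Scalar bounds**: sigma ∈ [1e-4, 10], nu ∈ [-5, 5], tau ∈ [0.5, 20].
  The tau floor avoids the non-smooth |z|^(tau-1) score near tau ≤ 0.5.
- **Age jitter** (uniform ±0.5 years) is available for integer-age designs
  but off by default: the knots are fixed and equally spaced, not
  data-driven, so integer ties cannot degenerate knot placement, and a
  deterministic default keeps pipeline artifacts digest-stable.
- **Extrapolation** beyond the fitted age range is refused unless
  explicitly requested (the spline is held at its boundary value).

`predict_centile(p, ages)` maps the fit through the BCPE quantile function;
centiles are strictly increasing in `p` at every age and continuous in age.

## Partitioning and nonparametric limits

The Harris–Boyd criterion compares `z = |m_a - m_b| / sqrt(s_a²/n_a +
s_b²/n_b)` against `z* = 3·sqrt(((n_a + n_b)/2)/120)`; partitioning is
warranted when `z > z*`. It is computed on raw-scale means/SDs by default
(transformed-scale summaries can be passed explicitly), and is invariant
under common location shifts and positive rescalings.

The nonparametric URL uses the rank convention `r = p(n+1)` with linear
interpolation between order statistics (clamped to the sample maximum when
`r > n`). Its 90% CI is the narrowest symmetric-in-rank pair of order
statistics whose exact Binomial(n, p) coverage reaches 90%; when no such
pair exists near the sample edge the CI falls back to a seeded percentile
bootstrap (2000 resamples) and says so in the result's `ci_method`.
Estimation refuses n < 20 and warns below n = 120 (the minimum for a valid
90% CI on the 97.5th percentile). Because the discrete rank search can only
overshoot the nominal coverage, realized coverage sits slightly above 90%
(~91% at n = 2000 in the test simulations).

## Screening and preprocessing

The eligibility funnel applies rules in a fixed order — duplicates,
residency, age window, NSE negativity, creatinine — and attributes each
excluded record to the *first* rule it fails, so the ledger partitions the
input exactly (`initial = retained + sum(excluded)`, property-tested).
Conventions that matter for reproducing printed tables:

- NSE negativity is strict `<` (16.4 µg/L males; 14.47 females < 50;
  17.25 females ≥ 50): a value exactly at threshold is excluded.
  Creatinine excludes strictly `> 133` µmol/L. Missing analytes pass.
- Quartiles everywhere use linear interpolation at position (n-1)·p.
- The Box–Cox power is the profile-likelihood MLE (scipy); Tukey fences
  (k = 1.5) are applied once, on the transformed values of the full
  screened cohort, not per age stratum and not iteratively. Whether fences
  belong on the raw or transformed scale is genuinely open in practice;
  the transformed-global choice is recorded in the output metadata.
- Printed percentages use round-half-up (2.675 → 2.68), not banker's
  rounding; flagging uses strict `>` (a value equal to the URL is inside
  the interval).

## Rank statistics

Mann–Whitney U uses midranks; the two-sided p is exact — full enumeration
of the C(n, n_x) permutation distribution of U — for combined n ≤ 20
(including ties, so identical samples give p = 1), and the tie-corrected
normal approximation without continuity correction above. Cohen's d uses
the pooled-SD (n₁+n₂−2) denominator with no small-sample correction.
Dunn's post hoc z uses pooled midranks with the tie-corrected SE; the sign
follows the first-listed group. The default multiplicity adjustment is
Bonferroni (capped at 1, matching how such tables are printed); Holm and
none are available. All tests are two-sided.

## The synthetic cohort generator

The generator *is* the study condition for every simulation test. Defaults:

- **Structure**: decade-by-sex counts of the reference population table
  (508/1267/1054/745/410/109 per decade; 2306 male, 1787 female; n = 4093),
  ages uniform integers within each decade (only decade totals are known).
- **Values**: BCPE(mu(age), sigma = 0.28, nu = 0.3, tau = 1.8) with mu(age)
  piecewise-linear through (20, 31), (40, 31.9), (80, 41) pg/mL. Since mu
  is the BCPE median, the anchors are the target medians directly; these
  settings reproduce the tabulated per-decade medians within ±2 pg/mL and
  IQRs of ~10–13 pg/mL.
- **Sex** has no effect on clean values (the real-data sex effect is
  trivial, Cohen's d ≈ 0.07); an additive male offset is available for
  partitioning experiments.
- **Contamination** (off by default) multiplies floor(rate × group size)
  records per group by a fixed scale ≥ 2, providing gross high outliers for
  screening/Tukey tests without touching the clean value stream (separate
  RNG stream, so the clean cohort is bit-identical across contamination
  settings).
- **Screening analytes** are injected on demand: each record independently
  violates the NSE and creatinine rules with a configurable probability.

What passing tests on this generator show — and what they do not: the
generator draws from the same BCPE family the fitter assumes, so recovery
tests certify the estimation machinery (correct curves recovered at
realistic n, correctly calibrated 2.5% flagging on fresh draws), not
robustness to misspecification. Real cohorts add assay imprecision,
pre-analytical drift, residual unhealthy subjects and age-varying spread
(the real data's 97.5th centile rises ~50% from 40 to 80 while its median
rises ~30%, impossible with constant sigma — the generator's proportional
tails rise in lockstep with the median). None of these are emulated.

## Problem sizes

Default test and acceptance runs use the study-scale training cohort
(n = 4093), a 100 000-record evaluation cohort for flagging calibration,
500 replicates of n = 2000 for CI coverage, and 1000 random small inputs
for oracle-equivalence checks; the full suite runs in well under a minute
on one CPU.

## Known limitations

- Constant sigma/nu/tau: no age-varying spread, skewness or kurtosis.
- No model selection across distribution families (BCT, BCCG, …) and no
  worm-plot/Q-statistic diagnostics; the edf target is an input, not chosen
  by information criteria.
- One-sided intervals only: no lower reference limit machinery.
- The bootstrap CI fallback is percentile-type; at the extreme sample edge
  (n barely above 20) its coverage is approximate.
- Harris–Boyd is applied to two pre-specified candidate splits; there is no
  search over cutpoints.
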