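# Methods

This note documents the statistical machinery in `aeroyield`: the models,
the estimators, their tunable parameters, the synthetic data the test suite
relies on, and the numerical choices made where the design was open.

## Problem setting

Bioaerosol samplers capture airborne environmental DNA on membrane filters.
A sampling *session* (typically 1 h) with `k` filter sheets returns a total
DNA yield in nanograms. Downstream amplicon metabarcoding needs roughly
10 ng of template, so the design questions are: how is the yield of a given
sampler distributed, what is the probability a session reaches 10 ng, and
how many filter sheets would a weaker sampler need to get there reliably?
A companion question is which ambient air-quality conditions (particle
counts by size bin, temperature, humidity) separate yield-sufficient from
yield-insufficient sessions.

## Skew-t yield model

Per-session yields are positive, right-skewed and heavy-tailed. They are
modelled with the Azzalini skew-t family, parameterized either directly
(DP: location ξ, scale ω, slant α, tail df ν) or by its first four moments
(CP: mean μ, sd σ, skewness γ₁, excess kurtosis γ₂). The density for finite
ν is

    f(x) = (2/ω) t_ν(z) T_{ν+1}( α z √((ν+1)/(ν+z²)) ),   z = (x−ξ)/ω,

with `t_ν` / `T_{ν+1}` the Student-t density and CDF; ν = ∞ (sentinel
`INF_DF`) is the skew-normal member and α = 0 the symmetric Student-t.
γ₂ is always *excess* kurtosis (normal = 0). Finite γ₁ needs ν > 3,
finite γ₂ needs ν > 4.

Fitting is by moment matching, mirroring the `dp2cp`/`cp2dp` bridge of R's
`sn` package: the sample CP is computed (population-moment estimators
`g1 = m₃/m₂^{3/2}`, `g2 = m₄/m₂² − 3` by default, with the sample sd on the
unbiased n−1 denominator; bias-adjusted G1/G2 variants are available behind
`bias_adjusted=True` since either convention is defensible), then inverted
to DP.

**CP→DP inversion.** The map DP→CP is closed-form; the inverse is computed
by nested deterministic bracketed root finding, no random starts:

* inner: for a fixed slant δ = α/√(1+α²), γ₂(δ, ν) decreases monotonically
  in ν from +∞ (ν→4⁺) to the skew-normal value (ν→∞), so ν is found by
  `brentq` on log(ν−4);
* outer: the residual γ₁(δ, ν(δ)) − γ₁* is scanned on an atanh-spaced δ
  grid (dense near |δ| = 1) seeded at δ = 0 where the residual is −|γ₁*|,
  and the bracketed upcrossing is solved by `brentq`.

Then ω = σ/σ_z(δ,ν) and ξ = μ − ω·μ_z(δ,ν). Tolerances: `brentq`
`xtol ≤ 1e-13`; round-trip DP→CP→DP errors are ~1e-12 in practice. A
(γ₁, γ₂) pair within 1e-6 (relative) of the attainable boundary is
projected onto the boundary with a warning rather than rejected, because
sample moments of simulated data land epsilon-outside routinely; pairs
clearly outside raise `FeasibilityError` naming the nearest attainable
value. |γ₁| below 1e-12 is treated as exactly symmetric. ν ≥ 1e8 is
evaluated with the exact skew-normal formulas: beyond that the finite-ν
corrections (O(1/ν)) fall below the double precision of the `gammaln`
difference in the ν-dependent constant.

A practical caveat, surfaced honestly by the error path: small-sample
moment estimates (n ≈ 50) of genuinely heavy-tailed data frequently fall
outside the skew-t attainable region, because sample kurtosis is biased
down and extremely variable. The parametric exceedance then raises
`FeasibilityError`; the empirical and kernel methods below always work, and
pipeline drivers report them alongside.

## Exceedance (yield-performance) probability

P(yield ≥ threshold), threshold default 10 ng, boundary *inclusive*, three
ways:

* `empirical_ecdf` — the fraction of sessions at or above the threshold
  (the mass the empirical CDF assigns to [threshold, ∞));
* `parametric_skew_t` — upper tail of the moment-matched skew-t;
* `kernel_density_auc` — tail mass of a Gaussian-kernel density estimate,
  computed exactly as the average of normal tail probabilities; bandwidth
  is Silverman's rule in the `bw.nrd0` convention,
  0.9·min(sd, IQR/1.34)·n^{−1/5}, floored at 1e-6·max(1, |mean|).

All three are reported because summary-based workflows do not pin down
which one a given published probability came from; they agree within ~0.05
at n = 10⁴ (a tested property). Yields are analysed on the total-per-session
scale; the per-sheet scale is used only by the effort estimator.

Two-sampler comparisons use the two-sided two-sample t-test; the pooled
("Student's") variant is the default, Welch is available, and the variant is
recorded in the output.

## Minimal filter-sheet estimator

Inputs: training sessions with per-sheet yields, a target (10 ng), a
one-tailed confidence level (0.90), the simulated sample size per sheet
count (100), the t-quantile degrees of freedom (default n_train − 1, e.g.
40 for a 41-session training set), and a sheet grid (1..200).

1. λ̂ = mean per-sheet yield (ng/sheet); dispersion = per-sheet sd.
2. For each sheet count k: simulate `n_sim` session totals. The default
   family discretises the continuous ng scale at `poisson_scale` counts per
   ng (default 100, i.e. 0.01 ng resolution) and draws
   Poisson(poisson_scale·k·λ̂)/poisson_scale. A `gamma` family matches the
   mean k·λ̂ and empirical variance k·dispersion², and a `bootstrap` family
   sums k resampled observed per-sheet yields — both kept because the pure
   Poisson family ties the variance to the mean by fiat. Observed
   dispersion exactly 0 is treated as the noiseless limit in *every*
   family (all totals equal k·λ̂), so a deterministic rate c yields exactly
   ceil(target/c) sheets; dispersions below 1e-12·max(1, λ̂) are snapped to
   0 to keep that limit robust to float noise.
3. The one-tailed lower confidence bound of the simulated totals at each k:
   `mean_sd` (default): mean − t_{conf, df}·sd — a per-observation-style
   bound; `mean_se`: mean − t·sd/√n_sim; `empirical_quantile`: the
   (1−conf) sample quantile. All three are exposed because "the lower bound
   of a one-tailed confidence interval of simulated values" admits each
   reading; the mode is echoed in the output.
4. OLS of lower bound on k; the estimate is the smallest integer at or
   above the line's crossing with the target (ceiling with a 1e-9 slack so
   exact crossings are not pushed up by rounding), with the exact crossing
   abscissa reported. Slope ≤ 0 raises a non-informative-regression error;
   a crossing beyond the grid raises a grid-exceeded error naming the
   extrapolated k.

Randomness: one base seed; the per-k stream is keyed to the sheet count
itself (`SeedSequence(seed, spawn_key=(k,))`), so results are independent
of grid order and identical seeds give bitwise-identical runs.

## Air-quality LDA and variable importance

Sessions are labelled sufficient when yield ≥ threshold (inclusive — the
same 10 ng convention as the exceedance). The ten covariates (PM0.3, PM0.5,
PM1.0, PM2.5, PM5.0, PM10, AT, RH, DP, WB) are standardized to zero mean
and unit sd (n−1 denominator), and the Fisher discriminant
w ∝ S_pooled⁻¹(μ₁ − μ₀) is solved directly; an exactly singular pooled
covariance gets a 1e-8 ridge on the diagonal with a warning. Priors are
equal by default and the decision threshold is the midpoint of the
projected class means; neither affects the reported ROC AUC, which is
threshold-free. Scores are oriented so the sufficient class scores higher,
making cross-validated folds consistent.

Variable importance is the model-free filter convention (what caret falls
back to for `lda`): each covariate's own ROC AUC against the label, folded
as max(AUC, 1−AUC), then rescaled 0–100 across variables (min → 0,
max → 100). ROC AUC uses the Mann-Whitney formulation with ties counted
half; the implementation delegates to scikit-learn and is verified in the
tests against a brute-force pair-enumeration oracle and against
`caret::filterVarImp` run through Rscript.

Model AUC is reported three ways — resubstitution, seeded stratified 5-fold
CV, and leave-one-out — because resampling schemes behind published AUC
ranges often go unstated. Hour strata (H1/H2/H3) are fitted independently.
Rows with missing covariates are dropped with a warned count; no imputation.

## Gel densitometry

Band intensity is the arithmetic mean of pixels inside a rectangle mask;
coordinates are 0-based and half-open, and all rectangles in one comparison
must share the same size so means are comparable. No background subtraction
is applied by default (a rolling-minimum estimate exists but is off).
Group comparison is the pooled t-test on band means. Image I/O is limited
to plain CSV matrices and 8/16-bit PGM.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of their spec (seed included) and return
their ground truth, so every estimator is testable without field data.

* `gen_yields` draws sessions from a requested skew-t (via CP→DP),
  truncated below 0 by rejection with a 1000-round cap — rejection, not
  clamping, to avoid a point mass at zero.
* `gen_air_quality` draws the six PM bins, AT and RH from a correlated
  Gaussian (adjacent PM bins at 0.8^|i−j|, a positive-definite Toeplitz
  block), clips to physical ranges, and derives dew point (Lawrence
  approximation) and wet-bulb temperature from AT and RH with 0.2 °C
  instrument jitter, clipped so dp ≤ wb ≤ at always holds. Yield is
  log-linear in the standardized covariates:
  log y = log(base) + Σ βⱼ zⱼ + ε, ε ~ N(0, noise_sd²) — chosen because
  yields are positive and right-skewed; effects are specified on the log
  scale. Defaults plant the signal on the three finest PM bins
  (β = 0.8/0.7/0.6, noise 0.6, base 10 ng), the fraction carrying most
  bioaerosol surface area.
* `gen_gel` places flat-topped bands of known mean intensity at known
  rectangles over a uniform background with Gaussian camera noise, clipped
  at zero.

Presets (`sheetA-like` … `sheetE-like`) reproduce the *structure* of a
realistic pilot campaign — 6+6 one-sheet comparison sessions, a 41-session
single-sheet training set (per-sheet mean 0.20 ng, sd 0.12), 48+48 indoor
sessions (27-sheet fan sampler, CP (18, 12, 1.5, 4)), 16+16 outdoor
sessions, 66 covariate sessions — with parameter values chosen once as
plausible for a low-biomass indoor environment. They are synthetic
stand-ins, explicitly not anyone's measurements; consequently the tests
show that the *estimators* recover known ground truth under realistic
shapes and sizes, not that any particular field result is correct.
Features of real campaigns the generators do not emulate: temporal
autocorrelation of consecutive sessions, instrument drift, extraction
batch effects, and non-Gaussian covariate marginals.

## Problem sizes

The default test and acceptance runs use the preset sample sizes above,
10⁴–10⁶ draws for Monte-Carlo checks, the full 1..200 sheet grid at 100
(up to 10⁴) simulations per count, and 50-replicate property checks —
sizes at which every stochastic tolerance in the suite holds with a wide
margin while a complete run stays in the tens of seconds.

## Known limitations

* Moment matching is not maximum likelihood: it is the documented bridge
  convention, but less efficient, and infeasible sample moments are a real
  (reported, not hidden) failure mode at small n.
* The Poisson effort model treats sheets as independent and identically
  productive; real multi-sheet holders may have positional airflow effects.
* LDA assumes shared class covariances; the importance filter is marginal
  and inherits confounding between correlated PM bins.
* The gel statistic is the mean within a fixed mask; volume (sum) is
  derivable as mean × area but band auto-detection is out of scope.
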