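# Methods

## The growth model

Otolith growth is modelled on the size–size (Walford) scale: the radius at
the current annulus, Z′ (mm), as an affine function of the radius at the
previous annulus, Z. The model suite, from simplest to fullest:

| label | model |
|-------|-------|
| lm1 | Z′ = β₁Z + α₀ + ε |
| lm2 | Z′ = β₁Z + β₂T + α₀ + ε |
| lm3 | Z = β₁T + α₀ + ε (radius at the first birthday) |
| lm4 | L = β₁Z + α₀ + ε (total length from otolith radius) |
| mod1 | lm1 + random year intercept αₖᵗ |
| mod2 | lm1 + crossed random year and fish intercepts αₖᵗ, αᵢᶠ |
| mod3–mod6 | mod2 + one of four summer-temperature covariates (open sea, all/shallow/deep lagoons) |

T is the mean summer (June–August) water temperature of the calendar year
in which the increment grew; summer is the period of maximal growth for a
warm-season Mediterranean ectotherm, which is why annual means are not
used. A growth pair is labelled with the formation year of its later
annulus, and the temperature join uses that year.

Mixed models are fitted by maximum likelihood (not REML): the suite is
compared across different fixed-effects structures, and REML likelihoods
are not comparable across such changes. Fitting goes through statsmodels
`MixedLM` with the two crossed intercepts expressed as variance components
on a single grouping; the likelihood surface near a variance boundary can
trap a single gradient optimizer, so each fit runs L-BFGS and Powell and
keeps the higher likelihood (spot-checked against lme4: identical log
likelihood, fixed effects and variance components to ~6 decimals).
Variance components estimated at (numerically) zero are returned with a
boundary flag rather than raised as errors. Marginal R² is
Nakagawa–Schielzeth: Var(Xβ̂) / (Var(Xβ̂) + Σ variance components +
residual variance). AIC counts fixed effects + variance components + 1.

The allometry offers two error models. Constant variance is OLS. The
exponential-variance option models Var(εᵢ) = σ² exp(γ·μᵢ) with μᵢ the
fitted mean, estimated by iterated re-weighted least squares (γ from the
regression of log squared residuals on the fitted mean). The published
form of this variance function is not usable as printed (an exponent
linear in length in mm overflows), so γ is always estimated from data and
the projection's length kernel defaults to constant variance.

## von Bertalanffy algebra

With Walford slope β₁ ∈ (0, 1): K = −ln β₁ (yr⁻¹); Z∞ = α₀/(1−β₁), the
fixed point Z′ = Z; L∞ = allometry(Z∞); Φ′ = ln K + 2 ln(L∞ in cm). The
centimetre convention for Φ′ is fixed and unit-checked: published values
of this index for comparable species are only consistent with lengths in
cm (mm would add 2·ln 10 ≈ 4.6).

## The cohort IPM

The projection advances a density of otolith radii one age class per
year:

    n(Z′, a+1) = ∫ g(Z′|Z; T) n(Z, a) dZ

with g Gaussian, mean β₁Z + β₂T + α₀ and SD equal to the residual SD of
the growth fit. The initial density (age 1, the first birthday) is
Gaussian from the lm3-type fit. Length densities come from a second
integral against s(L|Z), Gaussian with the allometry mean and a constant
SD. No mortality enters: every density is conditional on survival and is
renormalized to integrate to one.

Age convention: the initial distribution is age 1; one kernel application
gives age 2, and so on, to a default maximum age of 7. The default
reference temperature is 20.48 °C with scenario offsets {−1, 0, +1} °C.

**Discretization.** Midpoint rule on a uniform mesh, the canonical IPM
choice. Default 500 nodes; bounds span from the coldest-scenario initial
mean minus 8s to the warmest-scenario fixed point plus 8s, where s is the
larger of the initial SD and the stationary SD σ/√(1−β₁²) of the growth
recursion. Because all kernels are affine-Gaussian, the exact moment
recursions

    μ_{a+1} = β₁μ_a + β₂T + α₀,   s²_{a+1} = β₁²s²_a + σ²

are implemented as an independent oracle (`closed_form_moments`); the
numerical projection matches them to better than 1e-6 relative error at
500 nodes and agrees to ~1e-13 in practice (Gaussian sampling at a
spacing of ~0.1σ has exponentially small aliasing error). Densities whose
mesh would truncate more than 0.1 % of their mass trigger a warning.

## Bootstrap uncertainty

Parameter uncertainty is propagated by refitting lm2/lm3/lm4 on resampled
tables in each replicate and re-running the whole projection per
temperature scenario (the length step uses the exact affine-Gaussian form
of the constant-SD size kernel, identical to the midpoint-rule mapping).
Per scenario and age the summary holds: the bootstrap mean of projected
mean lengths; a 95 % CI of the mean; the SD of the pooled predictive
distribution; and a 95 % prediction interval from the equal-weight
mixture of per-replicate predictive Gaussians (so it combines parameter
and residual variability; its quantiles are found by bracketing the
mixture CDF). All replicate randomness derives from one seed through
per-replicate substreams; identical seeds give bit-identical results.
Replicates with singular resampled designs are discarded and counted;
more than 5 % discards is an error.

**Resampling unit.** `resample="rows"` (default) treats growth pairs as
exchangeable. `"fish"` resamples whole fish, respecting within-fish
correlation. `"year"` resamples whole formation years and is the
appropriate unit whenever growth carries shared year-level shocks: a
common year effect moves every increment formed that year, and pair-level
resampling then sees only about half of the true sampling SD of projected
mean lengths in this package's calibrated test world. With cluster resampling the CI is mean ± t₍G₋₁₎ × bootstrap SD
(G = number of clusters) — the standard few-clusters correction, since
percentile intervals undercover when G is a dozen or so; under row
resampling the percentile interval is used. The first-increment and fish
tables are always row-resampled: in this model their rows carry no shared
year term.

## The synthetic world

The generator inverts the fitted model. Defaults are the published point
estimates for Gulf of Lions gilthead seabream: β₁ = 0.7033, β₂ = −0.0631
mm/°C, α₀ = 2.120 mm; initial size 2.937 − 0.0718·T; allometry
L = 176.38·Z − 74.62; ~400 fish spawned 2002–2012; capture ages 1–7
weighted toward ages 1–3 (matching a lagoon-nursery sample dominated by
young fish); mean summer temperature 20.48 °C with SD 0.5 °C; year and
fish random-intercept SDs 0.05 and 0.04 mm. Residual SDs are not
published for this system; the defaults — growth 0.08 mm, initial size
0.20 mm, length 20 mm — are calibration choices that visually match the
scatter of published size-at-age data and are **not** published values.

Structural choices: year effects are crossed (shared by every fish
growing in a calendar year), not nested. Non-positive growth draws are
redrawn from the truncated Gaussian rather than dropped, keeping pair
counts predictable; at the default SDs the truncation point is ~5
residual SDs below the mean, so the induced bias is negligible (measured
at <0.3 mm on the projected age-2 length, versus a sampling SD of
~3.6 mm). All randomness flows from one seed with deterministic per-fish
substreams. Lagoon temperature sources are correlated offsets of the
open-sea series — structure, not asserted values.

What the generator does **not** emulate: measurement error on increment
widths, otolith–soma decoupling (growth effects on the allometry),
size-selective mortality, individual temperature exposure histories
(lagoon vs open sea), and missing annuli. Passing tests therefore
demonstrate statistical correctness of the estimators and projection
under the stated model, not robustness to these real-data features.

## Problem sizes in the test suite

The suite favours many small worlds over one large one: parameter
recovery uses 20 replicates of the 400-fish default world; bootstrap
coverage uses 100 worlds × 200 bootstrap replicates at a 120-node mesh
and age 2 only; the tallies for sign recovery and AIC ordering use 100
direct simulations of the regression layer. These sizes make the checks
sharp enough to fail under real defects while keeping the full suite in
a couple of minutes.

## Known limitations

- The cIPM has no mortality, recruitment or density dependence; it
  projects the size of survivors, not population structure.
- Temperature enters linearly; outside the observed ~2 °C range the
  linear extrapolation (and the negative slope itself) is untested.
- The heteroscedastic allometry is available for fitting but the
  projection's length kernel is constant-SD; prediction intervals for
  large fish may be slightly too narrow if the true error grows with
  length.
- Mixed-model AICs assume the ML fit found the global optimum; the
  two-optimizer strategy makes this reliable but not certain for
  pathological data.
- With only ~10–20 year clusters, even the t-corrected cluster bootstrap
  is approximate; its coverage was verified by simulation at the default
  calibration only.
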