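# otogrowth

Otolith-increment growth modelling and cohort integral projection of fish
size-at-age under temperature scenarios.

Fish otoliths (ear stones) lay down one opaque annulus per year, so the
radial widths between consecutive annuli record every year of an
individual's growth. `otogrowth` turns tables of such annual increments —
here calibrated to gilthead seabream (*Sparus aurata*) from the Gulf of
Lions, NW Mediterranean — into:

1. **Size–size (Walford) growth models.** The otolith radius in year *t*
   is regressed on the radius in year *t−1*, optionally with the mean
   summer (Jun–Aug) water temperature of the year of increment formation:

   Z′ = β₁Z + β₂T + α₀ + ε

   plus linear mixed variants with crossed random intercepts for formation
   year and individual fish (fitted by maximum likelihood, compared by AIC
   and marginal R²).

2. **von Bertalanffy parameters** from the Walford fit: growth coefficient
   K = −ln β₁, asymptotic otolith radius Z∞ = α₀/(1−β₁) (the fixed point
   of the Walford map), asymptotic total length L∞ through the linear
   otolith-radius → body-length allometry L = β₁Z + α₀ + ε, and the
   growth-performance index Φ′ = ln K + 2 ln(L∞ in cm).

3. **A cohort integral projection model (cIPM).** A Gaussian growth kernel
   g(Z′|Z; T) advances the full density of otolith sizes one age class at
   a time,

   n(Z′, a+1) = ∫ g(Z′|Z; T) n(Z, a) dZ,

   starting from the initial-size regression Z = β₁T + α₀ + ε at the first
   birthday, and a second kernel s(L|Z) maps otolith densities to
   total-length densities. There is no mortality: distributions are
   conditional on survival. A nonparametric bootstrap refits all three
   regressions per replicate and re-runs the projection to propagate
   parameter uncertainty into per-age confidence and prediction intervals
   under warming/cooling scenarios.

A synthetic-data generator (`otogrowth.synthetic`) produces increment,
fish and temperature tables with exactly this statistical structure
(crossed year/fish random intercepts, temperature-dependent growth,
right-truncated lifespans), so the whole pipeline is testable without any
field data.

## Worked example

Project cohort length-at-age from published coefficient estimates
(no raw data needed — "coefficient injection"):

```python
from otogrowth import CohortProjection, vb_transform

vb = vb_transform((0.7097, 0.8154), (176.1, -74.1))
print(f"K = {vb.K:.3f}/yr  Z_inf = {vb.Z_inf:.2f} mm  "
      f"L_inf = {vb.L_inf:.0f} mm  phi' = {vb.phi_prime:.2f}")

proj = CohortProjection.from_coefficients(
    growth={"beta1": 0.7033, "beta2": -0.0631, "alpha0": 2.120, "sigma": 0.08},
    initial={"intercept": 2.937, "slope": -0.0718, "sigma": 0.20},
    allometry={"slope": 176.38, "intercept": -74.62, "sigma": 20.0},
)
result = proj.scenarios(reference_T=20.48, offsets=[-1.0, 0.0, 1.0], max_age=5)
print(result.to_frame()[["scenario", "age", "mean", "percent_change"]]
      .round(1).to_string(index=False))
```

which prints

```
K = 0.343/yr  Z_inf = 2.81 mm  L_inf = 421 mm  phi' = 6.41
 scenario  age  mean  percent_change
   minus1    1 196.7            -6.9
   minus1    2 273.3            -7.9
   minus1    3 327.2            -8.4
   minus1    4 365.1            -8.6
   minus1    5 391.8            -8.7
reference    1 184.0             0.0
reference    2 253.3             0.0
reference    3 302.0             0.0
reference    4 336.2             0.0
reference    5 360.3             0.0
    plus1    1 171.4             6.9
    plus1    2 233.3             7.9
    plus1    3 276.8             8.4
    plus1    4 307.4             8.6
    plus1    5 328.9             8.7
```

Reading the table: at the reference mean summer temperature of 20.48 °C a
surviving two-year-old averages 253 mm total length; one degree of summer
warming shrinks that to 233 mm (−7.9 %), and a three-year-old from 302 mm
to 277 mm (−8.4 %). The von Bertalanffy line says the otolith approaches
an asymptotic radius of 2.81 mm, equivalent to a 421 mm fish.

## Command-line pipeline

The same stages are scriptable end to end with a YAML config:

```sh
otogrowth simulate --config config.yaml   # synthetic world -> CSVs + truth.json
otogrowth fit      --config config.yaml   # lm1-lm4, mod1-mod6, AIC table, VB params
otogrowth project  --config config.yaml   # bootstrap scenario projection
otogrowth report   --config config.yaml   # one-page summary
```

`otogrowth project --coefficients coefs.json` bypasses fitting and
projects directly from a JSON file of coefficients. All outputs carry the
config hash and seed.

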