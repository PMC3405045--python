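# Methods

## Scope and model

`billheat` estimates region-resolved *dry* heat loss (radiation plus
forced convection) for small passerines observed by thermal imaging in a
temperature-controlled chamber, and asks whether two subspecies differ in
the heat shed through the bill.  Evaporative and respiratory heat loss,
free convection, and solar gain are outside the model: the chamber had no
radiative load and essentially still air (bulk velocity taken as
V = 0.1 m/s, the residual circulation of such rooms).

For each region r with surface area A_r (m²), surface temperature T_s and
ambient T_a:

    Q_r   = ε σ A_r (T_s,K⁴ − T_a,K⁴)          radiative
    Q_c   = h_c A_r (T_s − T_a)                 convective
    h_c   = Nu k / D,  Nu = c Re^n,  Re = V D / ν

with ε = 0.96, σ = 5.6703×10⁻⁸ W m⁻² K⁻⁴, and per-region constants:
bill and legs (cylinder-in-crossflow) c = 0.174, n = 0.618; body
(blunt body) c = 0.34, n = 0.6.  Characteristic dimensions: half the bill
depth at its base, the tarsus length, and the cube root of body volume
(mass / 0.913 g cm⁻³).  Temperatures enter the radiative term in kelvin;
the convective difference is identical in °C and K.  A surface colder
than the air yields a negative Q (heat gain), deliberately not clamped;
the bill's percent share of total loss is reported as missing when the
total is non-positive.

### Surface areas

Bill areas use the lateral surface of a nearly circular elliptical cone,
((W+D)/4)·L·π, evaluated at the nares (exposed cone) or at the bill base
(full bill); the printed length is used directly without slant-height
correction, matching how the field measures and reports these areas.
Both tarsi together are elliptical cylinders,
π·sqrt(2((w/2)² + (d/2)²) − 0.5(w − d)²)·l·2; toes are excluded and the
feathered tibia is counted as body.  Body area is the classic passerine
allometry A = 8.11 m^0.67 cm².  Cohort summaries always average per-bird
areas, never evaluate the allometry at the mean mass (Jensen's inequality
makes these differ by a few tenths of a percent).

All linear inputs are millimetres and areas mm²; conversion to m² happens
at exactly one documented point inside the heat-budget module, so mm²
values cannot silently enter a wattage.

### Air properties

The analysis needs k(T) and ν(T) for dry air.  We use the power-law
conductivity k = 0.02624 (T/300 K)^0.8646 W m⁻¹ K⁻¹ and Sutherland's
dynamic viscosity μ = 1.458×10⁻⁶ T^1.5/(T + 110.4) Pa s over ideal-gas
density at 101325 Pa; both sit within ~0.8% of standard 1-atm property
tables over 0–50 °C (shipped in `billheat/data/dry_air_properties.csv`
and asserted to 2% by the tests).  Humidity and pressure dependence are
negligible at this accuracy and are not modelled.  ν is evaluated at the
ambient temperature; k defaults to the film temperature (T_s + T_a)/2 —
the standard boundary-layer convention — and can be switched to ambient
(`AirPropertyConfig`).  The choice moves per-region Q by well under 1%.

### Water equivalence

A heat-loss difference ΔQ (W) sustained for an hour spares
ΔQ·3600/λ grams of evaporation at λ = 2418 J/g, i.e. 6.5 mW ≈ 9.7 mg/h.
This is an equivalence, not a claim that the bird would otherwise have
evaporated exactly that much.

## Synthetic experiment

The generator reproduces the chamber design: 9 birds per subspecies,
ambient stepped 15→37 °C in 2 °C increments (12 levels), 15 min per step
with five analysed frames, i.e. 1080 frame records.  What it emulates,
and the defaults:

* **Morphometrics** — per-subspecies truncated normals (±3 SD) at the
  chamber cohorts' means/SDs (e.g. full-bill area 127.46 ± 10.41 mm²
  eastern vs 148.70 ± 12.12 mm² Atlantic).  Linear bill and tarsus
  dimensions are back-derived from the sampled areas by uniformly scaling
  a nominal shape, so derived areas reproduce the draws exactly and the
  base ≥ nares invariant holds by construction; when the independently
  drawn cone would exceed the base envelope its dimensions are clipped to
  it, slightly truncating the (widely dispersed) Atlantic cone
  distribution.  Bill depth at the base, needed only as the convective
  length scale, is not part of the published comparison; it defaults to
  6.0 ± 0.3 mm, a stated assumption.
* **Bill temperature** — elevation above ambient interpolating linearly
  from 9.8 °C at 15 °C to 4.7 °C at 37 °C (the reported model-averaged
  span; the relationship is reported as close to linear), plus a small
  Atlantic offset of 0.3 °C reflecting the weakly supported subspecies
  term (evidence ratio ≈ 1.5); set it to 0 for null simulations.
* **Bill base** — hotter than the whole bill (10.5→5.0 °C elevation) with
  a subspecies×T_a interaction: Atlantic bases +1.5 °C at 15 °C declining
  linearly to 0 at 37 °C, the "higher particularly at lower temperatures"
  structure.
* **Body** — 4.4→2.6 °C elevation, no subspecies term.
* **Legs** — logistic vasodilation threshold: 1 °C elevation when cold,
  5 °C when warm, centred at 29 °C with 2 °C width; only "non-linear" is
  reported for the real tarsi, so the logistic shape (and every endpoint)
  is configurable.
* **Activity** — hops/min quadratic in T_a (vertex 26 °C at 5 hops/min,
  curvature 0.165 hops/min/°C², noise SD 2, floored at 0), identical in
  both subspecies.  **Humidity** — 70% at 15 °C falling ~1.8%/°C, noise
  SD 3; only its anticorrelation with T_a matters downstream.
* **Variance components** — per-bird, per-response random intercepts
  (SD 0.5 °C) and frame noise (SD 0.4 °C).  These are not published
  values; they are stated assumptions chosen to give realistic
  within/between-individual spread.

What the generator does *not* emulate: radiometric images of real birds
(ROI extraction is exercised on abstract temperature grids), posture and
feather-ptiloerection effects, camera calibration error, any dependence
of surface temperature on activity, and within-step temporal drift.
Passing tests therefore demonstrate that the pipeline recovers structure
from data *of this statistical form*, not that the biological effect sizes
are correct for real sparrows.

## Mixed-model inference

The candidate set for every response runs from the null (√activity only)
to the saturated SSP*T_a + SSP*T_a² + SSP*T_a³ model (11 models),
respecting marginality; every model carries the √activity fixed effect
and a per-individual random intercept (same slopes across individuals —
no random slopes).  Fits use full ML rather than REML because the
candidates differ in fixed effects, the standard multimodel-inference
choice; `statsmodels` MixedLM does the optimisation (L-BFGS with BFGS and
Powell fallbacks), and one test cross-checks log-likelihood and
coefficients against lme4's ML fit.  K counts fixed coefficients plus the
two variance parameters (so "SSP + T_a" → K = 6).  AICc uses n = rows
entering the fit; the default analysis unit is the per-(bird × step) mean
of the five frames (n = 216 at the default design) — frame-level analysis
is available by flag, and heat budgets are always computed per frame then
averaged.  T_a is internally centred and scaled ((T_a − 26)/11) for
conditioning of the cubic designs; this reparametrises within the same
column span, leaving likelihoods, K and predictions unchanged.

Model-averaged predictions use Akaike weights over the *full* set (the
ΔAICc < 5 truncation is display-only), with unconditional standard errors
Σ w_i sqrt(se_i² + (ŷ_i − ŷ̄)²).  Prediction SEs are fixed-effects-only,
conditional on random effects at zero.  Residual correlograms pool
within-individual residual products by lag in step order after absorbing
each individual's mean residual; with 12 steps per series the estimator
carries the usual ≈ −1/(n−1) small-sample bias, so the ±1.96/√n_pairs
bounds are a one-sided guard against *positive* temporal autocorrelation.
The morphometric comparison helper uses pooled-variance two-sample
t-tests with Bonferroni correction across the table's rows.

## Numerical and design choices

* Air-property functions refuse extrapolation outside −20–60 °C unless
  explicitly overridden.
* Surface temperatures outside [T_a − 5, 45] °C warn but do not fail
  (real ROIs occasionally graze implausible values).
* Frame selection takes the last frame of each minute, replacing a
  flagged frame by the temporally closest good frame within that minute
  (earlier frame on a distance tie); a minute with no usable frame yields
  a missing marker.
* Degenerate inputs raise named errors: non-positive measurements, a
  non-positive elliptical-cylinder radicand, singular fixed-effect
  designs (reported with the collinear columns), AICc with n ≤ K + 1.
* All randomness flows from a single named seed per run; identical seeds
  give byte-identical outputs.

## Problem sizes

Tests and the acceptance script run the default design (18 birds ×
12 steps × 5 frames; n = 216 step means).  Structure-recovery rates use
50 replicate experiments per condition in the test suite and 25 in the
acceptance script; these sizes give Monte-Carlo standard errors of a few
percent on a recovery rate, adequate for the ≥80%/plurality questions
asked of them.

## Known limitations

* The convection correlations are steady-state engineering fits for
  smooth cylinders and spheres; feathers, posture, and flow disturbance
  by the cage are not represented.
* The single-cohort subspecies contrast inherits the sampling noise of
  9 birds per group: across generator seeds the Atlantic bill heat-loss
  excess ranges roughly 15–37% around a ≈22% centre.
* The published cone-area formula is implemented literally (L rather
  than slant height); for these aspect ratios the difference is ~1%.
* Bill-base temperature informs the subspecies interaction analysis but
  not the heat budget, which uses the whole-bill mean temperature over
  the full bill area.
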