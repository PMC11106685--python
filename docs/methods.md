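# Methods

This note documents the models, conversions, defaults and numerical
choices behind `floralwastage`, and what the synthetic-data validation
does and does not demonstrate.

## The measurement chain

**Nectar.**  A flower's standing crop is drained into a 1 µL capillary;
volume is the column length as a fraction of tube length times nominal
tube volume.  Sugar concentration is refractometer % Brix, treated as %
mass/mass sucrose equivalents with no temperature correction.  Sugar mass
per µL of nectar is (Brix/100) × solution density, with density linearly
interpolated in a packaged handbook table of aqueous sucrose densities at
20 °C (0–70 % in 2 % steps).  Linear interpolation at these increments
introduces negligible error relative to field measurement error; the
conversion refuses to extrapolate outside the table.  Rates are quantity
× 60 / interval (minutes).  Rows recorded with zero volume ("no
detectable nectar") carry missing Brix and contribute zero sugar.

**Pollen.**  One anther is suspended in 15 µL of 70 % ethanol and a 10 µL
aliquot loaded on a haemocytometer; the response variable for the wastage
analysis is the raw sum of the four corner-square counts, whose magnitude
matches marginal means reported on that scale.  An absolute per-anther
estimate is provided as a convenience: mean count per corner square ÷
corner-square volume × suspension volume, with Neubauer defaults
(1 mm² × 0.1 mm) since chamber geometry varies between instruments.  The
aliquot volume cancels under the well-mixed assumption.

**Weather.**  Vapour pressure deficit uses the Tetens saturation formula
es = 0.6108·exp(17.27 T/(T+237.3)) kPa, VPD = es·(1 − RH/100), averaged
arithmetically over hourly readings.  Tetens is one of several
near-equivalent saturation formulas in agrometeorology; the constants are
function arguments in effect (the formula is isolated in one function)
and the choice is documented here because sources rarely print theirs.

## Statistical models

**Aggregation.**  The Gaussian analysis is fitted to cell means — the
mean sugar accumulation rate per (study day, period, location, treatment)
— rather than raw flowers.  Cell means enter the model unweighted; cell
sizes are retained for diagnostics.  This aggregation step is part of the
analysis definition, not a convenience.

**Gaussian mixed model.**  y ~ treatment (+ location + interaction), with
random intercepts for year and site-within-year.  The fit is the
package's own REML: for fixed variance ratios γ_g = σ²_g/σ²_resid the GLS
estimate of β and the profiled σ² are closed-form; the restricted
likelihood is maximised over γ ≥ 0 by a coarse grid followed by
Nelder-Mead polish (xatol 1e-12).  Boundary estimates (γ = 0) are
legitimate outcomes and are reported as zero variance components — with
only two years the year component is weakly identified and often sits at
the boundary.  Setting all γ to zero reproduces OLS exactly, which the
tests assert to 1e-8.  Estimated marginal means are model-predicted cell
means on the full factor grid averaged with equal weights over the
off-target factors, with SEs from the GLS covariance.

**Count models.**  Pollen counts: log-link negative-binomial (NB2)
regression, IRLS for the coefficients with the dispersion α estimated by
profile maximum likelihood (bounded search on log α; α → 0 recovers the
Poisson limit).  Insect transect counts: Poisson quasi-likelihood with
Pearson-dispersion–scaled covariance ("quasi-Poisson").  Neither count
model carries random intercepts: with a balanced two-level factor the
EMM ratio is unchanged by balanced multiplicative cluster effects, and
uncertainty is instead carried by the cluster bootstrap.  This is a
deliberate divergence from a Laplace-approximate GLMM, which would be out
of proportion to a two-level fixed-effect contrast; the point estimates
agree, the interval construction differs.

**Wastage statistic.**  100 × EMM(accessible)/EMM(inaccessible) for
nectar sugar, 100 × EMM(end)/EMM(begin of anthesis) for pollen, computed
from the raw (response-scale) marginal means and rounded to the nearest
integer only at reporting time.  The statistic is scale-invariant and
undefined for non-positive reference means.

**Inference.**  Likelihood-ratio tests compare nested ML fits (REML
likelihoods are rejected: they are not comparable across fixed-effect
structures); the stepwise order drops the treatment×location interaction
first, then location, at α = 0.05.  Confidence intervals are percentile
cluster-bootstrap intervals resampling whole study days with replacement
(the study day is the natural exchangeable unit: one field visit), with
failed replicates dropped and counted.  Bootstrap statistics inside the
pipeline use equal-weight marginal means of the aggregated cell means —
identical to the model EMMs under balance and orders of magnitude faster
than refitting REML per replicate.

## Resource budget

Per study day: flower density = mean racemes m⁻² × mean open flowers per
raceme; insect density = mean transect count / transect area (default
50 m × 1 m = 50 m²).  Supply per m² h uses the *bagged*-flower secretion
rate (the potential maximum — sampling intervals under 3 h leave no time
for reabsorption); uncollected sugar uses the *accessible*-flower
accumulation rate (what visitors left).  Unit chain: µg flower⁻¹ h⁻¹ ×
flowers m⁻² × 10⁻⁵ = kg ha⁻¹ h⁻¹, exact by construction.  Colony
equivalents divide the per-hectare sugar flux by 1186 g, the lifetime
sugar intake of one *Bombus terrestris* colony.  Pooling across study
days is the unweighted mean of per-day metrics.  Note the mean of per-day
per-insect ratios is not the ratio of grand means: with the study-scale
grand means the ratio-of-means is ≈1460 µL insect⁻¹ h⁻¹ while the
mean-of-ratios across heterogeneous days is substantially larger;
pooled output reports the mean of per-day values and flags days where
zero insects make the ratio undefined (no imputation).

## Phenology

Month-resolution only: each crop's planted area is divided by its number
of bloom months and assigned to each month in its inclusive, non-wrapping
window, so contributions sum exactly to planted area (asserted to 1e-12).
Seasons must partition the twelve months; defaults are UK meteorological
seasons with winter wrapping December–February.  Crop areas and bloom
windows are user inputs — the packaged defaults are illustrative, not a
published dataset.

## The synthetic study

`generate_study` emulates the sampling design: 2 years × 4 sites × 2–3
days (20 study days), 10 flower pairs per day (5 edge / 5 interior), both
treatments on the same plant, up to 3 periods per day ~142 ± 26 min
apart, 6 anthers per stage per day, 10 transects per period, ~31 quadrats
and ~24 raceme counts per day, and hourly weather.  Defaults are the
study-scale summary statistics: bagged secretion 0.10 ± 0.08 µL flower⁻¹
h⁻¹ (lognormal, moment-matched — SDs of the order of the means imply
strong right skew), Brix 42 ± 15 truncated to (0, 70], true
uncollected-nectar ratio ρ_nectar = 0.69, begin-stage pollen mean 167
with end/begin ratio ρ_pollen = 0.19 (NB, size 2), interior insect mean
0.71 per transect with edge multiplier 1.31/0.71 (NB, size 0.8), racemes
46 ± 25 m⁻², flowers per raceme 7 ± 5.  Year, site-within-year,
day-within-site and plant effects are mean-one lognormal multipliers with
log-scale SDs 0.10 / 0.15 / 0.15 / 0.20 — the magnitudes of these
variance components are not reported anywhere, so these are conventions
chosen to give 10–20 % between-cluster CV, and they are configurable.
Brix is drawn independently of volume (no concentration–volume trade-off
is modelled), and pair correlation comes from the shared plant effect.

What the generator does **not** emulate: weather-driven secretion
dynamics, within-day depletion beyond the static treatment ratio, nectar
reabsorption, spatial field geometry, or taxon-specific foraging.  A
passing parameter-recovery suite therefore shows the estimators are
consistent and the intervals honest *under this generating process*; it
does not validate the gauze-bag exclusion itself or transport to data
with, e.g., secretion–weather interactions.

## Validation suite and problem sizes

The end-to-end suites use 100 independently seeded default studies with
B = 300 bootstrap replicates for the coverage check (the 95 % CI of each
wastage percentage must cover the generating value in ≥ 90 of 100
replicates), 500 null simulations of n = 100 for likelihood-ratio-test
calibration (empirical size within 0.03 of 0.05), balanced 4 × 5 layouts
for the REML–ANOVA closed-form oracle (agreement to 1e-6) and 8 × 6
layouts for the cross-check against an established mixed-model reference
(3 significant figures).  These sizes were chosen to make Monte-Carlo
error small relative to the assertions while keeping the suite fast to
run routinely.

## Known limitations

* Count-model CIs come from the day bootstrap, not an integrated GLMM;
  with strong unbalanced cluster effects the EMM point estimates of the
  count models could shift slightly relative to a full GLMM.
* With two years, the year variance component is frequently estimated at
  the zero boundary; its uncertainty is not propagated into EMM SEs
  (the bootstrap covers this for the wastage ratios).
* The sucrose density table is for pure sucrose at 20 °C; real nectar
  contains hexoses whose density differs at the third decimal, and no
  refractometer temperature correction is applied.
* Phenology ignores within-month bloom curves and regional variation.
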