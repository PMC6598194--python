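# Methods

This note documents the models, conventions and design choices behind
`amuquant`, in the spirit of a statistical-software methods appendix.

## Dose derivation

A product's **daily dose** is the mass of product needed to medicate 1 kg
of live chicken for one day. For water-soluble products it is
`mix rate (g/l) × water intake (l/kg/day)`; for in-feed products
`mix rate (g/kg feed) × feed intake (g feed/kg/day)`. The default intake
constants are 0.225 l and 63.4 g per kg of live chicken per day — published
figures for meat-type pullets at tropical ambient temperature and for
native layer pullets respectively. Both are treated as age-constant; the
`IntakeModel` makes them overridable but the package deliberately does not
age-adjust them, since weekly record books cannot resolve within-week
intake changes. Per-AAI daily doses scale the product dose by the labelled
concentration (mg per g or per ml; liquids follow the identical arithmetic
with a 1 g/ml convention).

Doses are always derived from the **therapeutic** label instruction.
Labels typically also carry a prophylactic instruction at roughly half
strength; that rate is retained on the `Product` only so the synthetic
generator can model under-dosing, never for dose derivation.

Injectable products and human medicines raise a dedicated
"excluded-from-quantification" signal distinct from a validation error:
they are real, well-formed records whose flock-level dose is unknowable
from a label. They appear in descriptive summaries and in the binary
use/no-use timing analyses, are tallied per flock as `excluded_events`,
and contribute to none of the three quantitative metrics.

The per-AAI daily-dose table averages over all quantifiable products
containing the AAI. The coefficient of variation uses the population
(n-denominator) standard deviation by default because the product set is
treated as fixed, not sampled; `cv_ddof=1` switches to the sample
convention.

## Metric definitions and conventions

- **mg/kg at treatment** divides each week's administered AAI mass by the
  flock biomass *in that administration week* (not averaged over a
  multi-week course): biomass is birds present × mean bird weight from the
  growth curve, looked up exactly by week with no interpolation.
- **mg/kg sold** divides the cycle-total AAI mass by birds sold × weight
  at the final week. Flocks selling nothing (100% mortality) have the
  metric undefined and are omitted from that metric's cohort statistics
  only.
- **Treatment incidence** counts dose-days per event as
  `amount / (daily product dose × biomass at administration)`, splits them
  equally among the product's 1, 2 or 4 ingredients, and normalises by
  7 × cycle weeks × (1/1000). Normalising dose-days by flock biomass makes
  a dose-day "one day of the whole flock treated", so TI = 1000 is exactly
  daily dosing and values above 1000 indicate over-dosing relative to the
  label. The stated phrase "dose-days divided by cycle duration" needs a
  per-day convention to be dimensionally a per-1,000-days rate; this
  normalisation is the one that reproduces the interpretation "days per
  1,000 days on which one chicken is treated". A `per-bird` denominator
  variant (single-bird dose-days over realised chicken-days,
  Σ birds × 7) is exposed as a sensitivity switch; the two coincide in the
  absence of mortality.
- Cohort summaries report mean, SEM (sample sd / √n), median and IQR
  (linear, type-7 quantiles). The top-quartile share sorts flocks
  descending and sums the highest ⌈n/4⌉ — no interpolation rule is assumed.
- Per-AAI and per-class cohort means include zero for flocks that never
  used the AAI, so per-AAI means are additive to the cohort mean.

## Timing analyses

A flock-week is "used" when at least one antimicrobial-containing product
of any kind was given; descriptive timing deliberately has wider scope
than dose quantification (injectables and human medicines count here).
The Lexis surface indexes use probability by production week × continuous
study-week; unobserved cells are missing, never zero, and pooling cells
with their observation counts reproduces the weekly probability curve
exactly (a tested invariant).

The seasonal model is a binomial GLM of weekly use on production week plus
one annual harmonic pair (sin, cos with a fixed 52-week period), with
sandwich standard errors clustered on flock identity — the assumption-light
reading of "flock as the clustering variable"; a random-intercept model
would add a distributional assumption the weekly panel cannot easily
check. The harmonic pair is tested jointly (2-df Wald). Single-class
outcomes, single clusters and separation raise a `FittingError` with a
diagnostic rather than returning garbage coefficients. All observed
production weeks enter the model, including the sparse late-cycle tail.

## Metric comparison

Pearson correlations are computed pairwise on the largest available n
(total-loss flocks drop out of mg/kg-sold pairs only) with the standard
t-based two-sided p-value; zero-variance inputs yield an explicitly
flagged undefined correlation. Mortality stratification cross-classifies
flocks by strictly-above-mean AMU × at-or-above-cut mortality (default
cut: cohort median mortality) and uses the Pearson chi-square without
continuity correction by default (switchable). Per-AAI concordance joins
cohort-level TI with the weight-based summaries and reports base-10
log-scale correlations over AAIs with positive use.

## The synthetic cohort

The generator emulates a cohort of small-scale flocks of slow-growing
meat chickens with the structure used throughout the tests:

| quantity | model | default calibration |
| --- | --- | --- |
| restock size | LogNormal truncated to [100, 1530] | truncated median 300, IQR ≈ 199–461 |
| cycle length | round(Normal), clamped [10, 22] wk | median 18, IQR 16–20 |
| weekly mortality hazard | Beta(1, 82), shared within flock | cumulative mortality median ≈ 0.14 |
| flock extinction | Bernoulli per flock | 4% lose every bird |
| weekly use probability | logit-interpolated anchors | 0.76 (wk 1), 0.41 (wk 2), 0.02 (wk 21) |
| products per medicated week | 1 + Bernoulli(0.5) | ~5 products per cycle |
| treated days per event | uniform {3, 4, 5} | typical label courses |
| dosing-error multiplier | 0.5 w.p. 0.2, else LogNormal(mean 1) | under- and over-dosing |
| catalog | 236 products, 60% two-AAI, ~9% excluded routes | label-like mix rates/concentrations |

The restock location parameter is solved so the *truncated* median is 300
(truncating at 100 birds shifts a LogNormal(ln 300) median up); the hazard
Beta(1, 82) is chosen so that 1 − (1 − h)⁵⁰ᵗʰ over an 18-week cycle gives
≈ 0.141 cumulative mortality with an IQR ratio near the target. Event
amounts are constructed as `multiplier × daily product dose × biomass ×
treated days`, which makes a flock's true dose-days `Σ multiplier × days`
— the closed-form identity the parameter-recovery tests assert (TI =
1000 × medicated-day fraction exactly under a unit multiplier). Restock
dates spread uniformly over an 80-week window to exercise the Lexis
machinery. The bundled EU-style daily-dose reference table is synthetic
(per-AAI means log-jittered), as is the Gompertz growth curve reaching
≈ 1.4 kg at week 18; users analysing real data supply measured weighings
and a real reference.

What the generator does *not* emulate: disease processes (deaths are a
flock-level hazard, not outbreaks), correlation between mortality and
medication intensity, farmer-specific product preferences, seasonality of
restocking, or price effects. Passing tests therefore demonstrate that the
pipeline computes its metrics correctly and that its statistics are
calibrated — not that any particular real cohort will show the same
cohort-level means.

A separate grid-only simulator draws weekly use directly from the
logit-linear age + harmonic model. It exists because calibration studies
of the seasonal test need data generated from the *fitted model's own*
process; the full cohort generator's piecewise age curve would confound a
type-I-error check with age-trend misspecification.

## Problem sizes and numerical choices

The test suite simulates cohorts of up to ~500 flocks and calibration
studies of 100–200 model replicates at 200 flocks each — sizes at which
binomial sampling bands on the checked quantities are a few percentage
points wide and the whole suite runs in well under a minute. Calibration
bands in the tests are pre-set from sampling theory (± roughly two
standard errors of the sample quantile at n = 500). Quantile computations
use numpy's default linear interpolation; exact identities are asserted to
relative tolerances of 1e-9–1e-12 to allow float summation order effects.
Growth-curve lookups past the table raise rather than extrapolate;
decreasing (measured) curves must be explicitly flagged empirical.

## Known limitations

- In-feed antimicrobials premixed into purchased commercial feed are out
  of scope: record books capture products the farmer adds, not feed-mill
  formulations.
- Mid-cycle partial sales are not modelled; ledgers with non-monotone
  populations fail validation.
- The actual dilution a farmer used is unobservable from records; doses
  assume the therapeutic label rate, and the synthetic dosing-error
  multiplier exists precisely to probe that assumption's consequences.
- The per-AAI "total grams" view ignores the population treated and is
  reported only for concordance analysis, not as a consumption metric.
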