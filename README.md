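# amuquant

Quantifying antimicrobial use (AMU) in small-scale chicken flocks from
farmer record books and product labels.

Surveillance of on-farm antimicrobial use in low- and middle-income
production systems rarely has access to sales data or prescription
registers: what exists is the farmer's weekly record book (birds present,
deaths, products given) and the labels of the commercial products
themselves. `amuquant` turns those two sources into comparable,
flock-level consumption metrics, and ships a calibrated synthetic-cohort
generator so every stage of the pipeline can be exercised and tested with
known ground truth.

It is written for veterinary epidemiologists and AMU-surveillance teams
working with longitudinal flock data.

## The metrics

For each antimicrobial active ingredient (AAI) in an oral veterinary
product, the **animal daily dose** (ADDvetVN) is the mass of that AAI
delivered to 1 kg of live chicken in one day of therapeutic treatment,
derived from the label mixing instruction and standardised intake rates:

    ADD (mg/kg/day) = mix rate × daily carrier intake × concentration / 1000

with water intake 0.225 l/kg/day and feed intake 63.4 g/kg/day by default.
Injectable products and human medicines are modelled and counted but
excluded from dose derivation — the number of birds they reach cannot be
inferred from a label.

Three flock-level metrics summarise one production cycle (restocking of
day-old chicks to sale):

- **mg/kg at treatment** — Σ over medicated weeks of (AAI mg administered ÷
  flock biomass that week). Sensitive to *when* treatment happens: early
  treatments hit a small biomass.
- **mg/kg sold** — total AAI mg over the cycle ÷ live weight sold.
  Sensitive to mortality, which shrinks the denominator; undefined for
  flocks that lose every bird.
- **treatment incidence (TI)** — animal-daily-dose days per 1,000
  chicken-days: each event contributes `amount / (daily product dose ×
  biomass)` dose-days, split equally among the product's 1, 2 or 4 AAIs;
  TI = 1000 × dose-days / (7 × cycle weeks). TI = 1000 means therapeutic
  dosing every day of the cycle.

Timing analyses (weekly use probability, age × calendar Lexis surface, a
cluster-robust logistic model with one annual harmonic) and
metric-agreement analyses (pairwise Pearson correlations, mortality
stratification with a chi-square test, per-AAI dose/weight concordance)
complete the pipeline.

## Worked example

Simulate a cohort and run the analyses (the numbered scripts under
`analysis/` are thin drivers over the `amuquant` library):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/03_flock_metrics.py
```

which prints, for the default calibrated scenario:

```
cohort: 215 flocks on 102 farms
  median restock 301 birds, median cycle 18 weeks
  median cumulative mortality 13.3%, 3.7% of flocks lost every bird
mg_per_kg_at_treatment: mean 1224.3 (SEM 59.9), median 1084.9 [IQR 592.4-1666.1], n=215
mg_per_kg_sold: mean 340.4 (SEM 23.0), median 248.0 [IQR 99.3-439.5], n=207
treatment_incidence: mean 161.1 (SEM 5.9), median 149.7 [IQR 98.4-214.5], n=215
top-quartile flocks account for 50.3% of total use (mg/kg at treatment)
8/215 flocks sold no birds and are excluded from the mg/kg-sold statistics
```

Reading this: the weight-based metric referenced to biomass at treatment is
several times the sold-weight metric (treatments cluster in the early weeks
when birds are small), the TI of ~161 says an average bird is dosed on
roughly 16% of its days, use is concentrated in a heavy-using minority of
flocks, and the 8 total-loss flocks drop out of the mg/kg-sold statistics
because nothing was sold.

The same computations are available programmatically
(`amuquant.compute_flock_metrics`, `amuquant.cohort_summary`, …) and
through the CLI (`amuquant simulate`, `amuquant run-all --records … --events
… --catalog … --growth …`), which validates all inputs before writing any
output.

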