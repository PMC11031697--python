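# Methods

## The estimand and the indirect estimator

The quantity of interest is the number of drug overdose deaths in a state
and year in which the implicated drug was injected. No US vital-statistics
field records route of administration, so the estimator borrows it from
treatment admissions: within a demographic stratum (sex × age 18–39/≥40 ×
race/ethnicity; 16 cells) and drug type, the probability that a person
who died of an overdose involving drug *d* injected it is taken to equal
the fraction of treatment admissions in the same stratum reporting drug
*d* whose usual route is injection.

The estimator is a stratified product:

```
N̂(s,t) = Σ_d Σ_g  p̂(s,t,d,g) · D(s,t,d,g)
```

with `p̂ = x/n` over route-known admissions and `D` the allocated overdose
death count. Both the transportability assumption (treatment admissions ≈
decedents within stratum × drug) and its direction of bias matter: if
injection makes any of these drugs more lethal than other routes, the
estimate is conservative (an undercount).

### Death identification and categorization

Overdose deaths are those with underlying cause X40–X44, X60–X64, X85, or
Y10–Y14, restricted to adults (age ≥ 18). Drug involvement comes from
multiple-cause T-codes: T40.1/T40.4 (heroin and synthetic opioids other
than methadone), T40.2/T40.3 (natural/semisynthetic opioids and
methadone), T40.5 (cocaine), T43.6 (psychostimulants), T42.3/T42.4
(sedatives); any other code in T36–T59.0 falls in a residual OTHER_T
category. Both dotted and undotted ICD-10 spellings are accepted and
compared on a canonical dotted form, because vital-statistics files are
undotted while user-prepared CSVs are usually dotted. Range membership is
decided on the numeric value, so T51–T59.0 are OTHER_T and codes above
T59.0 are not drug poisonings (they are ignored with a warning).

A death listing several specific drugs is assigned to the listed drug
with the highest **national, year-specific** pooled injection percentage.
The interpretation: the target is "any drug was injected", so the most
plausibly injected listed drug carries the probability. A national (not
state-specific) ranking keeps categorization consistent across states; a
pooled-over-years mode exists as configuration. Ties break on a fixed
canonical drug order so results never depend on dictionary ordering.

Deaths whose only T-code is T50.9 ("other and unspecified drugs") carry
no usable drug information and are redistributed across the six
categories proportionally to the non-missing distribution at
(state, year, stratum) — the finest faithful reading of redistribution
"within year and demographic strata" — falling back to the national
(year, stratum) distribution when a cell has only unspecified deaths, and
to OTHER_T (probability zero) if no distribution exists anywhere. This is
a missing-at-random assumption within stratum. Redistributed counts are
fractional and stay fractional through estimation; rounding happens only
in report formatting, so per-cell totals are conserved exactly (checked
to 1e-9).

### Probabilities, intervals, and the fallback ladder

`p̂` cells use only admissions with a known route (missing routes are
excluded from numerator and denominator). Intervals are exact equal-tailed
Clopper–Pearson limits in the Beta-quantile form,
`lo = B(α/2; x, n−x+1)`, `hi = B(1−α/2; x+1, n−x)`, with the x=0 and x=n
edge cases pinned to 0 and 1; α defaults to 0.05. The test suite verifies
the endpoints against an independent bisection on binomial tail
probabilities for every n ≤ 60.

A death cell can have no admissions. Rather than dropping such deaths,
probabilities fall back through a pooling ladder — (1) state-year-drug
pooled over strata, (2) national year-drug-stratum, (3) national
year-drug — and the level used is recorded per cell, so reports can
quantify (`fallback_share`) or exclude pooled-probability contributions.
Pooling is the least-assumption default; a cell that misses every level
contributes zero with a logged warning.

### CI propagation

Death counts are treated as fixed constants (no Poisson variance); the
only modeled uncertainty is binomial sampling of the injection
probabilities. The default interval for a state-year sums interval
endpoints, `[Σ p_lo·D, Σ p_hi·D]`. This ignores the independence of cell
errors and is therefore deliberately conservative (wider than a variance
composition); it is also transparent and reproducible. A Monte-Carlo mode
(`ci_mode="mc"`) draws each cell's probability from Beta(x+1, n−x+1) — a
uniform-prior posterior — and takes percentile intervals of the totals,
for sensitivity analysis. OTHER_T deaths always contribute probability
zero, since injection probabilities exist only for the five treatment
drug groups; this too is conservative and is surfaced in the reports.

### Suppression and the national aggregate

A state-year is suppressed when (a) fewer than 50 admissions reported any
of the five drugs, (b) the missing-route fraction among drug reports
exceeds 15% (strictly greater — the threshold sits on "more than 15%",
and 15.0% exactly is kept), or (c) the state reported no treatment data
at all. Suppression withholds publication, not computation: suppressed
state-years still enter the national numerator and denominators, which is
the only way the national count, percentage, and rate stay mutually
consistent. Non-reporting states are excluded from the national
population and overdose-death denominators entirely. The national
estimate therefore equals the sum of reporting-state estimates exactly
(tested to 1e-6).

### Trends

Relative percent change between two years is `(r1 − r0)/r0 × 100`,
undefined when the start rate is zero or either endpoint is suppressed.
Its CI is a delta-method normal approximation on `log(r1/r0)`: each
rate's SE is back-computed as CI half-width / 1.96, converted to the log
scale by dividing by the rate, and the two years are treated as
independent. Degenerate zero-width inputs collapse to the point change;
a non-positive end rate falls back to the endpoint-combination interval
`[(lo1/hi0 − 1), (hi1/lo0 − 1)]` with a warning. State-vs-national
classification calls a state "faster"/"slower" only when its whole trend
CI lies above/below the national point change (a point-vs-point mode is
available); this CI-vs-point rule was an open design choice, made
because it avoids labeling noisy states.

## Synthetic data: what it emulates, and what it does not

The generator produces the three input files plus latent truth. Structure
emulated: 16 strata with realistic treatment-population weights
(male-skewed, younger-skewed, majority NH-White); 1–3 substances per
admission with sub-substance names (crack, fentanyl, benzodiazepine, …)
to exercise the grouping; per-(drug, age band) true injection
probabilities; route missingness applied after route assignment; overdose
underlying causes sampled across the full qualifying code list; polydrug
death records with a second specific T-code; a T50.9-only fraction; and
Poisson death counts from state-year rates.

Default conditions describe a 2020-era drug landscape at desk scale:

| parameter | default | rationale |
| --- | --- | --- |
| states / years | 6 states, 2010–2020 | enough geography and time for trends at desk scale |
| admissions per state-year | 5,000 | populates most stratum cells while staying fast |
| base injection probabilities | heroin/synth 0.60, opioid/methadone 0.18, cocaine 0.12, psychostimulant 0.30, sedative 0.04 | heroin near the reported ~58–69% national range; others ordered as treatment data order them |
| young-age shift | +0.06 | injection skews younger |
| death mixture | heroin/synth 0.45, opioid/methadone 0.15, psychostim 0.15, cocaine 0.12, other 0.08, sedative 0.05 | opioid-dominant 2020-like mixture |
| death rate | 12 → 35 per 100,000 (linear 2010→2020) | matches the scale of the adult overdose-rate rise |
| polydrug probability | 0.40 | polysubstance involvement is common in recent years |
| unspecified (T50.9-only) fraction | 0.08 | completeness of T-codes is high and improving |
| route missingness | 0.008 | route completeness ≈ 99.2% |

Latent injection flags are drawn from the probability of the category the
estimator will assign (the highest-ranked listed drug), so recovery tests
isolate estimator correctness from the polydrug assumption itself;
OTHER_T deaths get latent flag 0, mirroring the estimator's zero
probability. A `latent_mode="misspecified"` draws instead from the
least-injected listed drug, which quantifies the overestimation incurred
when polydrug use is less likely to involve injection.

Not emulated: geographic correlation, time-series autocorrelation beyond
the linear rate trend, differential treatment-system coverage by state,
stratum-specific death mixtures, and any dependence between injection
and death (the transportability assumption is true by construction).
Passing recovery tests therefore demonstrates that the pipeline's
arithmetic and bookkeeping are correct under the model's assumptions —
not that the assumptions hold in real surveillance data.

## Problem sizes used in checks

The large recovery check uses one year, six states with populations
scaled to yield ~50,000 overdose deaths in expectation, and 20,000
admissions per state-year (well-populated probability cells); the
pipeline estimate is required to sit within 3 Monte-Carlo standard errors
of the latent count and within 5% relative error. Interval coverage is
measured over 2,000 binomial replicates per true probability at n = 200.
Smaller fixtures (two states, two years, 1,500 admissions) back the unit
and property tests.

## Published-table arithmetic

Because the original microdata are restricted, headline published numbers
cannot be recomputed from raw inputs. The package instead ships the
published 2020 state summary table and national summary rates
(`injod/data/*.csv`) and re-derives everything that is a function of
them: the national rate over the reporting-state population (excluding
the five non-reporting states' populations), the percentage of overdose
deaths estimated injection-involved, the share of overdose deaths
occurring in reporting states, the median/min/max of the 39 published
state rates, the 8-largest-state share of the national estimate, and the
2010→2020 percent change with its delta-method CI. The published trend CI
was computed with a multiyear-change formula that is not public; the
delta-method interval documented above reproduces its scale (within a few
percentage points at each end) but is not expected to match digit-for-digit.

## Numerical and degenerate-input choices

- Age band cut is closed-open at 40 (39 → 18–39, 40 → ≥40); minors are
  excluded before stratification.
- Records with invalid demographic or route vocabulary are rejected
  row-wise at read time and collected with line numbers; a malformed
  header is a hard error.
- Duplicate drug reports within one admission deduplicate keeping
  injection over other over missing, so a record never contributes twice
  to one drug's denominator.
- Drug-ranking ties and drugs absent from a year's admissions fall back
  to the fixed canonical order, with absent drugs ranked last.
- All randomness (simulation, Monte-Carlo intervals) flows from
  numpy Generators seeded by a single configured seed.

## Known limitations

- The transportability assumption is untestable from these data; SUDORS-
  style toxicology systems would be the natural external validation.
- Endpoint-summed CIs overstate width when many independent cells
  contribute; the Monte-Carlo mode gives a tighter alternative but adds a
  prior assumption.
- The fallback ladder borrows probabilities across strata or states for
  sparse cells; `fallback_share` should be inspected before trusting
  small-state estimates.
- OTHER_T deaths contribute zero injection probability, so states with
  unusual residual-category shares are underestimated.
- Suppression thresholds are step functions; estimates just above the
  thresholds are published at full width despite being barely better
  measured than suppressed ones.
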