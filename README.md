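# injod — injection-involved overdose death estimation

`injod` estimates the annual number and rate of **injection-involved drug
overdose deaths** by US state, for public-health analysts who need
subnational injection-mortality burden when no surveillance system records
the route of administration on death certificates.

The method is indirect: it links two systems that each observe half of the
question. Substance-use **treatment admissions** (TEDS-A-style records)
report, per substance, whether the usual route of administration is
injection; **vital-statistics death records** carry ICD-10 underlying-cause
and multiple-cause codes identifying overdose deaths and the drugs
involved. The estimator assumes that, within a demographic stratum and drug
type, people admitted to treatment and people who died of an overdose
inject at the same rate.

## Model

For state *s*, year *t*, drug type *d* ∈ {heroin/synthetic opioids,
natural/semisynthetic opioids & methadone, cocaine, psychostimulants,
sedatives}, and demographic stratum *g* (sex × age band 18–39/≥40 ×
race/ethnicity, 16 strata):

- p̂(s,t,d,g) = x/n, the share of route-known treatment admissions
  reporting that drug whose usual route is injection, with exact
  Clopper–Pearson 95% limits [p_lo, p_hi] from the Beta-quantile form;
- D(s,t,d,g), overdose deaths (underlying cause X40–X44, X60–X64, X85,
  Y10–Y14, adults only) allocated to one drug category each: polydrug
  deaths take the listed drug with the highest national injection
  percentage, and deaths whose only T-code is T50.9 are redistributed
  proportionally to the non-missing category distribution within
  (state, year, stratum);
- the estimate collapses the product over drugs and strata:

  **N̂(s,t) = Σ_d Σ_g p̂(s,t,d,g) · D(s,t,d,g)**,

  with interval endpoints Σ p_lo·D and Σ p_hi·D, rates per 100,000 from
  population denominators, and a national aggregate over reporting states.

State-years with fewer than 50 drug-of-interest admissions, or with more
than 15% of drug reports missing the route, are suppressed. Multiyear
trends are relative percent changes in rates, with a delta-method CI on
the log rate ratio, and each state is classified as rising faster than,
slower than, or similarly to the national trend.

A first-class synthetic-data generator produces admission, death, and
population files with known per-death ground truth, so the whole pipeline
is testable without restricted microdata.

## Worked example

Simulate a two-state system, then estimate:

```sh
cat > sim_small.yaml <<'EOF'
states: [AL, CA]
year_start: 2019
year_end: 2020
state_population: {AL: 3800000, CA: 10000000}
admissions_per_state_year: 3000
EOF
injod simulate --config sim_small.yaml --out demo/data --seed 7
injod estimate --admissions demo/data/admissions.csv \
    --deaths demo/data/deaths.csv --population demo/data/population.csv \
    --out demo/results --seed 7
```

which prints

```
wrote 12000 admissions, 6479 deaths to demo/data
2020 national: 2022 (1611-2502) injection-involved deaths, rate 14.65 per 100,000
```

and writes per-year tables (`demo/results/estimates_2020.csv`):

```
state,population,overdose_deaths,injection_deaths_95ci,pct_of_overdose_deaths_95ci,rate_per_100000_95ci
AL,3800000,1289,541 (431-669),42.0 (33.5-51.9),14.23 (11.35-17.61)
CA,10000000,3579,1481 (1180-1833),41.4 (33.0-51.2),14.81 (11.80-18.33)
US,13800000,4868,2022 (1611-2502),41.5 (33.1-51.4),14.65 (11.67-18.13)
```

Of the 4,868 simulated overdose deaths in 2020, an estimated 2,022 (41.5%)
involved injection — a rate of 14.65 per 100,000 adults — with the 95%
interval propagated from the exact binomial limits of every
(drug × stratum) injection probability. The trend subcommand compares
states to the national percent change:

```sh
injod trend --admissions demo/data/admissions.csv --deaths demo/data/deaths.csv \
    --population demo/data/population.csv --start 2019 --end 2020 \
    --out demo/trends.csv --seed 7
# national 2019->2020: +197% (118% to 306%)
```

In Python, the same pipeline is one call
(`injod.run_pipeline(admissions, deaths, population, RunConfig())`), and
`injod.synthetic_data.generate_all(SimulationConfig(...))` returns the
input frames together with the latent ground truth.

## Layout

| module | contents |
| --- | --- |
| `injod.coding` | ICD-10 handling, overdose filter, drug grouping, strata |
| `injod.injection_probability` | Clopper–Pearson intervals, probability cells, fallback ladder, drug ranking, missingness |
| `injod.death_allocation` | polydrug assignment, T50.9 redistribution |
| `injod.estimation` | product estimator, rates, suppression, national aggregate |
| `injod.trends` | percent change, trend CIs, state-vs-national classification |
| `injod.synthetic_data` | generator with latent ground truth |
| `injod.io` / `injod.cli` | CSV schemas, report tables, `injod` command |

See `docs/methods.md` for assumptions, parameter defaults, and known
limitations.
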