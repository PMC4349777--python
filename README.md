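# nephrospan

Life expectancy by kidney-function stratum. The package classifies
person-level records by eGFR (2009 CKD-EPI creatinine equation), albuminuria
(ACR or urine dipstick) and the KDIGO 2012 risk matrix, splits follow-up into
5-year age bands on an age time scale (left-truncated at 40, open at 80+),
accumulates deaths and person-years per sex × stratum, and builds Chiang
abridged life tables with variances, 95% CIs on expectancy and on expectancy
differences between strata.

Because registry data of this kind are not redistributable, the package
ships a first-class synthetic-cohort generator with known piecewise-constant
hazards per stratum and an exact closed-form expectancy oracle, so the whole
estimation chain is validated by parameter recovery.

## Modules

| module | what it does |
|---|---|
| `nephrospan.kidney_classify` | CKD-EPI eGFR, eGFR/albuminuria categories, KDIGO risk, cohort exclusions |
| `nephrospan.persontime` | age-band scheme, exposure splitting, deaths/person-years aggregation |
| `nephrospan.lifetable` | Chiang abridged life table, expectancy CIs, expectancy differences |
| `nephrospan.synthetic_cohort` | hazard specs, exact death-time simulation, analytic expectancy oracle |
| `nephrospan.report_cli` | pipeline orchestration, report bundle, CLI |

## CLI

```bash
# simulate a cohort (config may carry a `simulate:` section; hazards
# default to a plausibility-calibrated age-increasing profile)
nephrospan simulate --config config.yaml --seed 1 --out persons.csv

# classify persons (creatinine in mg/dL or umol/L)
nephrospan classify --in persons.csv --out profiles.csv \
    --creatinine-units mg/dL --ethnicity-factor off

# life tables from an aggregated counts CSV
nephrospan lifetable --counts counts.csv --radix 100000 --out tables.csv

# full pipeline: simulate/read -> classify -> counts -> life tables ->
# expectancy + difference CSVs (and, with --grouping kdigo, the risk-class
# matrix plus losses vs the low-risk reference), plus manifest.json
nephrospan report --config config.yaml --seed 1 --out report/ [--sensitivity]
```

Example `config.yaml`:

```yaml
simulate:
  n_per_stratum: 2000
  admin_followup_years: 7
  index_age_range: [30, 90]
  hazards: default          # or a {"male|GE60|NORMAL": [9 rates], ...} map
grouping: egfr_x_albuminuria   # or kdigo
sexes: [male, female]
sensitivity: false
output_dir: report
```

`--sensitivity` re-runs the analysis excluding persons with diabetes,
hypertension or cardiovascular disease. Every input person is accounted for
exactly once in `manifest.json` (included, excluded with a reason, or
pre-40); strata failing life-table preconditions (a band with no exposure,
no terminal-band deaths) are skipped with a logged reason. Identical config
and seed produce a byte-identical bundle.

## Conventions worth knowing

- ACR boundary values 30 and 300 mg/g are "mild" (inclusive range); dipstick
  readings above 2+ map to "heavy"; ACR wins when both measurements exist.
- Even-count medians: arithmetic midpoint for ACR, lower-middle value for
  the ordinal dipstick scale.
- Death at an exact band boundary belongs to the higher band ([a, b)
  intervals); ages are continuous, never rounded.
- Life tables use a = 0.5 in all bands and close the 80+ interval with
  e = 1/m; the expectancy variance includes a delta-method term
  1/(m²·D) for the open interval so CIs exist at age 80.
- In very-high-mortality strata the Chiang conversion can drive q to 1
  before the terminal band; downstream rows are then undefined and reported
  as empty cells.
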