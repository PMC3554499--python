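# rxcomorbid

Medication-based chronic comorbidity analysis from pharmacy dispensing
claims. The package implements a full pharmacoepidemiology pipeline:

- **`rxcomorbid.catalog`** — the RxRiskV (mod) catalog: 42 chronic-condition
  categories defined by ATC inclusion/exclusion patterns (truncated codes
  match as prefixes, 7-character codes exactly), an all-of rule for chronic
  heart failure (loop diuretic *and* ACE inhibitor), and a total priority
  order used to attribute multi-indication drugs to a single category.
  Shipped as package data (`rxriskv_mod_2010`); custom catalogs load from
  YAML. A linter reports ambiguous patterns, dead excludes and printed
  literals that violate the ATC grammar.
- **`rxcomorbid.claims`** — claims/demographics CSV I/O and the month
  calendar (default 16-month window 2009-11…2011-02, costing year 2010).
- **`rxcomorbid.scoring`** — chronicity rule (a condition requires
  dispensings covering ≥3 consecutive calendar months, codes pooled within
  a category), treated-T2DM proxy flag (chronic oral anti-hyperglycaemic
  use, A10B, alone or with insulin), and cohort scoring with a capped
  comorbidity band (`0`…`9`, `>=10`).
- **`rxcomorbid.stats`** — stratified prevalence, median/IQR tables
  (type-1 integer quartiles), capped-band χ² distribution test,
  low-vs-high comorbidity split at the T2DM-group median, and per-condition
  odds ratios adjusted for age band (ref 65-69) and sex (ref female) with
  Wald 95% CIs.
- **`rxcomorbid.costs`** — annual ingredient-cost aggregation restricted to
  each patient's assigned condition categories, seeded percentile-bootstrap
  means with 95% CIs per stratum, and T2DM/non-T2DM cost ratios.
- **`rxcomorbid.simulate`** — a seed-deterministic synthetic claims
  generator with planted per-condition prevalences and T2DM odds ratios,
  sub-chronic emissions to exercise the chronicity filter, right-skewed
  gamma costs, and exact implied ground truth (Poisson-binomial count
  distributions) for plant-and-recover testing.

## CLI

```sh
rxcomorbid simulate --n-patients 10000 --seed 1 --out-dir sim/
rxcomorbid claims validate sim/claims.csv
rxcomorbid score --claims sim/claims.csv --demographics sim/demographics.csv \
    --out profiles.csv
rxcomorbid tables --profiles profiles.csv --out-dir results/
rxcomorbid costs --claims sim/claims.csv --profiles profiles.csv \
    --replicates 2000 --seed 17 --out table3.csv
rxcomorbid catalog lint
rxcomorbid catalog match C10AA05
rxcomorbid catalog show Hyperlipidemia
```

File formats are plain CSV: claims (`patient_id,month,atc_code,
ingredient_cost`, month as `YYYY-MM`), demographics (`patient_id,sex,
age_band` with bands `65-69`, `70-74`, `75+`).

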