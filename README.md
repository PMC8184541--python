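# fracrisk

Country-specific 10-year fracture probability models built from
age/sex-specific hip-fracture incidence and national mortality.

Given hip-fracture incidence rates (per 100,000 person-years), an age/sex
MOF:hip ratio schedule and mortality rates, `fracrisk`:

- derives a surrogate **major osteoporotic fracture** (MOF) incidence
  schedule by multiplying hip incidence by the ratio schedule;
- converts rate schedules to piecewise-constant continuous-time hazards
  (log-linear interpolation in age, clamped extrapolation) and integrates
  the **10-year first-fracture probability under the competing risk of
  death** with an exact per-interval closed form;
- adjusts the fracture hazard (never the death hazard) multiplicatively for
  clinical risk factors: prior fracture, femoral-neck T-score via a
  gradient of risk per SD, and arbitrary user-supplied relative risks;
- age-standardises summary probabilities to a user-supplied standard
  population and computes cross-population comparison statistics
  (age ratios, max/min spreads, per-population ranges, age-specific
  intervention thresholds);
- generates fully synthetic countries (Gompertz–Makeham rates, Poisson
  event counts, exact Garwood rate intervals) so every stage is testable
  without external data.

A published comparison grid (10-year MOF and hip probabilities for women
with a prior fracture, BMI 25, six populations, ages 50–90) ships as a
packaged fixture for the comparison statistics.

The bundled prior-fracture relative risk (1.8) and gradients of risk
(hip 3.7, MOF 1.6 per SD) are literature-typical placeholders, not
calibrated coefficients: supply your own values for substantive use.

## CLI

```sh
# write a complete synthetic input set (CSVs + generating-parameter manifest)
fracrisk simulate --preset low-incidence --seed 42 --out sim/

# build a serialisable country model from rate CSVs
fracrisk build --hip-incidence sim/hip_incidence_female.csv \
               --ratios sim/mof_hip_ratios_female.csv \
               --mortality sim/mortality_female.csv \
               --sex F --population demo --out model.json

# 10-year probabilities for one risk profile
fracrisk predict --model model.json --age 70 --sex F \
                 --prior-fracture --t-score -2.5 --rr smoking=1.3

# comparison statistics on the packaged grid
fracrisk compare --fixture table1

# age-standardised summary probabilities
fracrisk standardise --model model.json --std-pop std_pop.csv
```

CSV schemas: rate files are `age,rate` (per 100,000 person-years), ratio
files `age,ratio`, standard populations `age_lower,age_upper,weight`.

## Layout

| module | contents |
| --- | --- |
| `fracrisk.rate_tables` | schedule/grid types, CSV I/O, packaged fixture |
| `fracrisk.hazard_engine` | rate→hazard conversion, competing-risk integral |
| `fracrisk.risk_adjustment` | relative-risk machinery, per-profile probabilities |
| `fracrisk.surrogate_mof` | MOF incidence from hip incidence × ratios |
| `fracrisk.standardisation` | age-standardisation, comparison statistics |
| `fracrisk.synthetic` | Gompertz schedules, Poisson counts, synthetic countries |
| `fracrisk.model` | the serialisable country-model bundle |
| `fracrisk.cli` | `fracrisk` command-line entry point |
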