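# regionforce

Integrated, multi-professional, needs-based primary-care workforce planning
at the regional scale.

Regional health authorities need to know whether the neighbourhoods where
care is *needed* have a workforce able to *deliver* it. `regionforce` is a
simulator for that question, built for planners and health-services
researchers: it estimates neighbourhood-level service requirements,
projects profession-specific service capacity, assesses the gap between
them, optimizes task-shifting allocation across professions with
overlapping scopes of practice, and runs baseline-vs-scenario comparisons —
all on fully synthetic but internally consistent planning regions, so every
stage is testable without access-controlled health data.

## The model

For each neighbourhood *x*, annual service requirements combine resident
needs relocated by care-seeking flows, external inflow, and unmet need:

```
V_TOT_x = V_RES_x · P[x,x] + Σ_{n≠x} V_RES_n · P[n,x] + E_x + UMN_x
```

where `V_RES_x = Σ_s count(x,s) · rate(s)` aggregates stratified population
counts against expected visit rates per stratum (age × sex × morbidity),
`P` is a row-stochastic origin–destination flow matrix, `E_x` is visits by
patients residing outside the region, and `UMN_x` is a visit-equivalent
unmet-need composite built from low-urgency ED visits, ambulatory-care-
sensitive hospitalizations and survey-reported unmet need. Because `P` is
row-stochastic, `Σ V_TOT = Σ V_RES + Σ E + Σ UMN` holds exactly.

Capacity per profession follows a stock-flow projection (cohorts by age
band under inflow, outflow, retirement and death, discrete annual steps)
and a multiplicative adjustment chain:

```
capacity = headcount × base_output × activity × participation
           × scope_share × practice_pattern × productivity [× visits/hour]
```

with physicians denominated in visits/year and other professions in
hours/year. The requirements–capacity gap (`requirement − capacity`,
positive = shortfall) is then minimized by an exact linear program that
shifts services among professions wherever regulated scopes overlap, with
optional in-person/virtual shifting. See `docs/methods.md` for the full
account of the model, defaults and limitations.

## Worked example

Run the default synthetic city (140 neighbourhoods, 5 sub-regions, ~2.7 M
residents, three professions), then a scenario raising productivity 10%:

```sh
$ regionforce run --out demo_base
requirements 9,012,512 visits/yr; capacity 9,032,802 visits/yr; post-allocation unmet 174,740 visits/yr -> demo_base

$ cat scen.yaml
name: productivity_up
overrides:
  - decision_point: productivity
    path: workforce.productivity_factor
    value: 1.1

$ regionforce run --scenario scen.yaml --out demo_scen
requirements 9,012,512 visits/yr; capacity 9,936,082 visits/yr; post-allocation unmet 0 visits/yr -> demo_scen

$ regionforce compare demo_base demo_scen --out report.csv
wrote comparison (150 rows) to report.csv
```

Reading the baseline: residents of the synthetic city need about 9.0 M
primary-care visits/yr once flows, external patients and unmet need are
counted, and the projected workforce could deliver about 9.0 M — but
capacity is in the wrong places and professions, so 174,740 visits/yr
remain unmet after optimal task shifting at the sub-region level. The
scenario's 10% productivity lever lifts capacity to 9.9 M (requirements
unchanged — the override is local to the workforce stage) and the residual
unmet falls to zero; `report.csv` shows the per-geography differences, e.g.
`post_allocation_gap` dropping to 0 in every sub-region.

The same workflow is available as a library:

```python
import regionforce as rf

bundle = rf.run_pipeline({"seed": 0})
scen = rf.Scenario("prod", [rf.Override("productivity",
                                        "workforce.productivity_factor", 1.1)])
report = rf.compare(bundle, rf.run_pipeline({"seed": 0}, scen))
```

`regionforce generate --seed 7 --out region_dir` writes a complete synthetic
region (populations, needs rates, flows, workforce, indicators, scope
matrix) as plain CSV tables for inspection or external use.

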