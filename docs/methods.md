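# Methods

`regionforce` implements an integrated, multi-professional, needs-based
planning model for primary care at a regional scale. The model answers one
question in five steps: do the places where care is needed have a workforce
able to deliver it, and if not, how far can reallocation close the gap?

## 1. Service requirements

Service requirements are the total annual primary-care visits to be
*delivered* in each neighbourhood, assembled from four additive terms:

```
V_TOT_x = V_RES_x · P[x,x]  +  Σ_{n≠x} V_RES_n · P[n,x]  +  E_x  +  UMN_x
```

* **Resident needs** `V_RES_x`: expected annual family-physician visits by
  residents of neighbourhood *x*, the exact linear aggregation
  `Σ_s count(x,s) · rate(s)` over population strata *s*. Strata are (age
  band × sex × morbidity level) cells — a transparent, coarse stand-in for an
  individual-level case-mix grouper. The rate table is a pluggable input so
  aggregated output from a real grouper can be substituted without code
  changes; the package makes no attempt to reproduce any proprietary
  grouper's clinical logic.
* **Care-seeking flows** `P`: a row-stochastic origin–destination matrix;
  `P[i,j]` is the share of resident-*i* visits received in *j*. Row sums are
  validated to 1 (drift ≤ 1e-6 is renormalized, anything larger is rejected
  naming the offending row), which is what makes the conservation identity
  `Σ V_TOT = Σ V_RES + Σ E + Σ UMN` hold to 1e-9. The matrix can be
  estimated from (origin, destination) visit records by direct share
  counting; origins with no observed visits default to self-care
  (`P[i,i] = 1`) so the empty-input limit is the identity matrix.
* **External inflow** `E_x`: visits delivered in *x* to patients residing
  outside the region — an exogenous observed vector, not a modelled demand
  process, and deliberately held fixed under closer-to-home scenarios.
* **Unmet need** `UMN_x`: a subjective visit-equivalent composite,
  `adj_x · (w_ed·ED_x + w_acsc·ACSC_x + w_survey·share_x·V_RES_x)`, built
  from low-urgency emergency-department visits, ambulatory-care-sensitive
  hospitalizations, and a survey-reported unmet share of resident needs,
  scaled by a locally elicited consultation multiplier (default 1; setting
  it to 0 removes a neighbourhood's UMN — a scenario lever). The linear form
  is this package's concretization of a deliberately subjective quantity;
  any callable mapping the same inputs to a UMN series can replace it. UMN
  is attributed to the service location, since it enters the total of the
  neighbourhood where the visits would be delivered. Default weights
  (1 visit per low-urgency ED visit, 5 per ACSC hospitalization, survey
  weight 1) are stated conventions, not estimates.

Growth compounds resident needs forward as `V_RES_x(t) = V_RES_x(0) · g_x^h`
with a per-neighbourhood annual factor `g_x` and horizon `h` years. Because
`g_x` is uniform across a neighbourhood's strata, growing stratified counts
and re-applying rates gives the identical result; both modes exist
(regression-tested equal) so stratum-specific growth can be slotted in
later. Whether unmet need should itself grow is not resolved here: growth
applies to `V_RES` only, and UMN's survey term inherits growth only through
`V_RES`. Neighbourhoods with `g_x ≥ 1.02/yr` (configurable) are flagged as
growth hot-spots.

The requirements equation ships in two forms: a vectorized matrix product
used by the pipeline and the literal per-neighbourhood loop kept as a
readable reference; the acceptance suite checks their equivalence to 1e-9
relative on a thousand randomized regions.

## 2. Workforce capacity

Each profession is projected and adjusted independently, then harmonized to
visits/year:

* **Stock-flow projection.** Headcounts by provider age band and practice
  neighbourhood evolve in discrete annual steps (the planning cadence — no
  continuous hazards): each cohort loses `retirement(band) + death(band) +
  outflow` shares, a `1/band_years` fraction of survivors ages into the next
  band (band width 10 years by default), and inflow — `inflow_rate ×`
  current stock, distributed across neighbourhoods in proportion to existing
  stock — enters the youngest band (configurable; the data say nothing about
  where entrants land). Aggressive scenario rates that would drive a cohort
  negative floor at zero with a warning rather than an error, so scenario
  exploration never crashes. A single cohort under constant rates therefore
  decays exactly as `h₀(1−r)^t`, which the acceptance suite checks for
  horizons 0–30.
* **Adjustment chain.** Capacity = `headcount × base_output × activity ×
  participation × scope_share × practice_pattern × productivity`, times a
  visits-per-hour conversion (default 3.0) for hour-denominated professions.
  Physician capacity must be denominated in visits/year; other regulated
  professions use hours/year; nurse practitioners may use either. Every
  factor is recorded in an audit trail whose product reproduces the headline
  to 1e-9 relative, and the chain is exactly multiplicative: scaling any one
  factor by *k* scales capacity by exactly *k*. Practice-pattern and
  productivity adjustments apply at profession level, not cohort level —
  cohort-level pattern data are rarely available and the choice keeps the
  audit trail flat. Productivity is a subjective scenario lever, default 1.

Providers are attributed to a single practice neighbourhood; multi-site
practice and any training-pipeline constraint on supply are out of scope
(the model assumes the workforce is not limited by the training pathway).

## 3–5. Gap, allocation, final alignment

The gap is `requirement − capacity` (positive = shortfall) throughout.
Allocation formalizes task shifting as a linear program per geography:
total requirements split into service categories by a share vector
(default: routine/acute 0.35, chronic disease 0.30, preventive 0.20, mental
health 0.15 — stated conventions); a service × profession boolean scope
matrix says who may deliver what (shifting is only possible where regulated
scopes overlap); an efficiency matrix (default 1) prices capacity
consumption per delivered visit. The LP maximizes delivered visits subject
to eligibility, per-profession capacity and per-service requirements —
exactly the iterative "allocate until optimally aligned" procedure, solved
exactly. The published plasticity-matrix machinery this generalizes is not
reproduced internally; the LP is this package's formalization of its stated
semantics. A second LP phase fixes total delivery at its optimum and
prefers professions earlier in the configured order, so ties break
deterministically. With unit efficiencies the constraint matrix is totally
unimodular, so the LP optimum is also the integer optimum — the property the
brute-force oracle suite exploits. Manual (descriptive) plans are accepted
as data and validated against the same constraints. Allocation can run per
neighbourhood, per sub-region, or citywide; sub-region is the default
planning geography (neighbourhood-level allocation assumes no within-city
travel for shifted services, citywide assumes free travel; sub-regions are
the compromise the geography exists for).

Virtual-care shifting re-expresses a requirement in capacity-consumption
units: with share *s* of visits virtual at relative cost *e*, consumption is
`(1−s) + s·e` of baseline — conserving totals when `e = 1`.

Final alignment classifies each geography as shortfall (unmet remains after
allocation), surplus (spare capacity that could be diverted), or aligned
(|residual| ≤ 1e-6 visits).

## Scenario engine

Scenarios are declarative YAML override files — never code — naming a
decision point (`population_profile`, `growth`, `flows`, `unmet_need`,
`workforce_profile`, `adjustments`, `productivity`, `model_of_care/scope`,
`virtual_care`) and a dotted config path each override may touch; paths
outside a decision point's stage are rejected up front. All randomness flows
from the single configured seed through fixed per-component substreams
(`SeedSequence(seed, spawn_key=(component,))`), so baseline and scenario
runs share inputs exactly and differences isolate the override; an override
at one stage provably leaves all upstream outputs bit-identical, and adding
a new generator never perturbs existing ones.

## Synthetic regions: what they emulate and what they do not

The generator fabricates the inputs a regional planner would assemble:
140 neighbourhoods in 5 sub-regions (configurable), neighbourhood
populations log-normal around 19,000 (σ = 0.35 on the log scale) so the
default city holds roughly 2.7 million residents; 9 age bands × 2 sexes ×
3 morbidity levels = 54 strata, with a stylized age pyramid and morbidity
concentrating in older bands; visit rates U-shaped in age (3.0/yr under 10,
2.0 for young adults, 6.0 at 80+) scaled by morbidity (×0.6/×1.2/×2.6) and
sex (×1.08 F / ×0.92 M) with 5% log-normal jitter, giving ≈2.9
visits/resident/yr citywide; flows with diagonal mass `locality` (default
0.6) and Dirichlet off-diagonal mass; external inflow sized at 5% of
nominal resident volume; growth factors log-normal around 1.01/yr;
unmet-need indicators at plausible per-capita rates (low-urgency ED
0.03/person/yr, ACSC 0.004/person/yr, survey share Beta(2,38), mean 5%);
and three default professions — family physicians (0.75/1,000 residents,
4,200 visits/yr base), nurse practitioners (0.15/1,000, 3,000 visits/yr),
registered nurses (0.50/1,000, 1,600 hours/yr).

These distributions are stated conventions on the right scale, not
calibrations: nothing matches real neighbourhood profiles, there is no
spatial correlation between adjacent neighbourhoods, no gravity structure
in the flows, and no correlation between deprivation, unmet need and
workforce density of the kind real cities exhibit. Passing tests therefore
demonstrate that the *machinery* — equations, conservation, projection,
optimization, scenario isolation — is correct, not that any particular
city's gap estimate is right; with real inputs substituted through the same
CSV interfaces, correctness of the machinery is what carries over.

## Numerical choices

* Flow rows: renormalize drift ≤ 1e-6, reject beyond; conservation then
  holds to 1e-9.
* Requirements decomposition must reproduce `V_TOT` to 1e-6 relative, or
  the estimate is rejected as inconsistent.
* Capacity audit product reproduces the headline to 1e-9 relative.
* LP: HiGHS, exact for these instance sizes; allocation ties broken by
  profession order via a second phase; post-allocation residuals below
  1e-6 visits classify as aligned.
* Zero-visit flow origins default to self-care rather than uniform spread,
  keeping the identity limit clean.
* Degenerate inputs: empty record lists give the identity matrix and zero
  inflow; horizon 0 is the identity everywhere; all-zero weights give zero
  UMN.

## Problem sizes

The default end-to-end run (140 neighbourhoods, 54 strata, 3 professions,
5-year horizons, sub-region allocation) completes in about a second on one
CPU. The test suite's randomized-instance counts (1,000 regions for
equation equivalence, 500 integer instances for LP-vs-enumeration, 100
seeds for generator invariants) were chosen to exercise the full parameter
ranges while keeping a complete run around ten seconds.

## Known limitations

* Needs cover family-physician-type visits only; the needs model has no
  per-profession demand structure — multi-professional structure enters
  through capacity and scopes.
* No uncertainty quantification: the model is a point simulator; scenario
  runs are the intended sensitivity instrument.
* No costing, no training pipeline, no individual-provider microsimulation,
  no geographic coordinates or travel costs.
* External inflow does not respond to flow scenarios; whether it should is
  a modelling question the data cannot answer here.
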