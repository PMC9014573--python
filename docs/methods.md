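# Methods

This note documents the models implemented in `hrhplan`, the assumptions
and numerical conventions behind them, what the synthetic-data generator
does and does not emulate, and the design choices made where the published
methodology left the question open.

## Vacancy analysis

The vacancy stage is bookkeeping, but the bookkeeping conventions matter
because the outputs are compared against published integer percentages.

- **Rounding.** Fill percentages are `round-half-up(100·filled/established)`
  as integers. Python's built-in banker's rounding would turn 99.5 into
  100 but 112.5 into 112; half-up reproduces every published cell we check
  (e.g. 676/679 = 99.56 → 100, 94/83 = 113.25 → 113). Rates above 100%
  (over-established cadres) are reported as-is, never capped.
- **Undefined rates.** A rate against zero established posts is a flagged
  undefined value, not a number: silently emitting 0 or ∞ would hide either
  phantom staff or a missing establishment row.
- **Region aggregation.** Two estimators are computed. The *unweighted
  mean* of district integer percentages is the convention used in published
  district tables (it weights a 640-post district equally with a 2560-post
  one); the *pooled* rate `Σfilled/Σestablished` is the statistically
  conventional alternative. They differ materially (Central region: 62% vs
  66%), so both are always reported and neither silently stands in for the
  other. Central hospitals and headquarters are excluded from region
  aggregates but kept as their own rows and in the grand total.
- **Frontline scope.** Tables default to sub-cadres flagged frontline
  (direct service-delivery groups); support staff can be included with a
  flag. The default cadre registry carries the 20 frontline sub-cadres in
  nine groups used in the Malawi exercise and is user-extensible.
- **Density ratios.** Staff per 1000 population are reported to two
  decimals. Central-hospital staff serve whole regions, so they never enter
  a district's numerator (they still count nationally). Title
  standardization is case- and whitespace-insensitive; unresolved titles
  are retained and reported, never dropped, since resolved+unresolved must
  equal the register row count (a conservation property the tests enforce).

## Training-pipeline projection

Annual per-sub-cadre recurrence
`W(t+1) = W(t) + inflow(t+1) − outflow(t+1)` with

- `inflow = enrollment(t+1−duration) · graduation_rate · pass_rate ·
  absorption(t+1) + hired_abroad(t+1)`;
- `outflow = W(t) · (retirement + involuntary + voluntary(t+1) + study_leave)`,
  baseline components 1/2/3/1% (7% total).

**Update order.** The published equation is annual and silent on whether
the year's graduates are exposed to attrition in their hire year. The
default applies outflow to start-of-year stock only (new hires attrite from
their first full year); `attrit_new_hires=True` switches to the
alternative. The choice shifts each year's stock by at most
`rate × inflow` (≲0.5% here) and does not affect any ordering property.

**Fractional workers** are carried exactly through the recurrence and
rounded only for display; this is what makes conservation
(`ΔW = inflow − outflow`) testable to machine precision and the constant-
rate case equal to the geometric closed form
`W0(1−r)^t + I(1−(1−r)^t)/r` within 1e-9.

**Scenarios** are parameter-path overrides:

- *Reduced attrition*: voluntary rate ramps linearly 3% → 1% between 2017
  and 2022 (path 3.0, 2.6, 2.2, 1.8, 1.4, 1.0%), constant after.
  "Incrementally" is read as linear annual interpolation; a step variant
  is available through the override's `mode`.
- *Increased absorption*: step from 50% to 75% from 2018 onward.
- *Increased enrollment*: a multiplier ramping linearly to 2× at 2020 and
  4× at 2030, constant after.
- *Combined*: the composition of the three; because the overrides touch
  disjoint parameters, composition equals elementwise application (tested).

The community health worker cadre (DCSA) is exempt from the absorption and
enrollment overrides: these workers are recruited directly against vacant
community posts, so their absorption is fixed at 100% and their enrollment
follows its own (rising) path.

**Targets.** The establishment total is constant over time; the WHO
density target is 4.45 workers per 1000 population, growing with the
population projection. Which cadres count toward the WHO comparison is
caller-controlled (the projection sums whatever cadres it was given), since
published practice varies on including community health workers.

**Dominance and ordering.** Given the parameter directions above, each
single intervention weakly dominates baseline every year and the combined
scenario weakly dominates each single one; first-crossing years are
correspondingly ordered. These orderings — not any specific national
trajectory — are the pipeline's checkable behaviour, because the real
baseline enrollment inputs per cadre were never published in the main
text; the acceptance checks therefore exercise them on synthetic systems.

**Identifiability.** Under constant rate and inflow the recurrence is
affine, so `(1−r, I)` is recoverable from a trajectory by least squares —
provided the series is not at its steady state `I/r`, where the regressor
is constant. `recover_constant_flows` exists as a consistency check on
generated projections, not as an estimator for real data.

## Demand-based optimization (WFOM)

`requirement(c) = Σ_a volume(a) · minutes(a, facility_type) · share(a, c) /
available_minutes(c)` per facility, summed upward. Conventions:

- **Shares** for each (activity, facility type) must sum to 1; inputs off
  by more than 1e-6 are renormalized with a warning (beyond rescue they are
  a data error worth surfacing, within fuzz they are float noise). This
  guarantees the share matrix conserves service minutes exactly, a tested
  invariant.
- **Availability** is global with an optional per-cadre maternity override
  (days per year 365, defaults of 11 public holidays, 21 vacation, 5 sick,
  5 study days at 6 patient-facing hours/day, i.e. 116 280 min/worker-year).
- **Requirements are fractional FTE**; integer post recommendations apply a
  ceiling at the chosen aggregation level, since a published rounding rule
  does not exist. Ceiling at facility level then summing would overstate
  national need, so the level is explicit.
- **Facility screening.** Facilities reporting fewer than a configurable
  number of distinct activities are excluded and counted, mirroring the
  completeness screens real service-data registries need.
- **Missing inputs** (an activity-time or share entry for a facility type
  that has volumes) are errors naming the pair — defaulting minutes or
  shares would silently bias requirements.
- **Gap netting.** Two conventions are provided and labelled: national
  netting (surpluses offset shortfalls) and positive-part summation per
  district (a surplus in one district cannot staff another). Published
  national figures are consistent with netting at national level but the
  per-district convention is what recruitment planning needs.

Cadres without modelled services (dental, nutrition, radiography, mental
health) simply have no share entries and receive no requirement; community
health workers are out of the model's scope entirely, since it describes
facility-based care.

## Synthetic-data generator

The generator emulates the administrative inputs of a multi-district
public health system: a staff-return register (one row per worker, with
realistic raw-title noise — case, spacing, slash variants), an
establishment list, training programs, flow parameters, district
populations, a facility registry, and service volumes/times/shares.

Defaults are the study conditions of the planning exercise the package is
modelled on: district fill rates drawn uniformly on 0.33–1.00 (the
published district spread), attrition 1/2/3/1%, graduation rates 0.75–1.00,
licensing pass rates 0.70–1.00 for exam cadres (1.0 otherwise), 50%
absorption (100% for community health workers), 27 districts with a small
set of facility types each, Poisson service volumes with per-facility-type
intensity multipliers, and ~2.7% annual population growth. Establishment
cells are `1 + Poisson` draws scaled from the published national post
totals per sub-cadre, so every (cadre, district) cell keeps at least one
sanctioned post and fill rates are defined everywhere; filled posts are
binomial in the district's fill rate.

Every draw flows through one `numpy` generator stream seeded by a single
integer: the same seed and config reproduce the bundle byte-for-byte, and
partial regeneration is impossible by design. The exact drawn quantities
(filled counts, establishment, populations, demand-model requirements
computed by an independent plain triple loop at generation time, and a
plain-loop baseline projection) are retained as `GroundTruth` for test
assertions. A `dirty` mode injects the pathologies real staff returns
exhibit — unknown titles, missing duty stations, facilities with no usable
service data — at configurable rates.

What passing on synthetic data does **not** show: the generator's volumes
are independent Poisson draws (no seasonality, no spatial correlation, no
under-reporting structure), titles are perturbations of a known dictionary
rather than free text, and establishment lists are internally consistent
by construction. Results on real registers depend on standardization and
completeness work the generator only caricatures.

A separate fixture encodes the published 2017 Malawi national totals
(sub-cadre and district/central-hospital marginals — the full cross-
tabulation was never published, so it is carried as two snapshot/
establishment pairs sharing one grand total) plus the published demand-
model anchors. This is real published data, not synthetic, and is the
basis of the exact-reproduction checks.

## Problem sizes and checks

The test suite and `scripts/acceptance.py` run entirely on the fixture and
on generated systems: vacancy reproduction is exact arithmetic on the
printed totals; pipeline properties use 24-year horizons over the full
default cadre set across several seeds; optimization-model oracle checks
use 100 random systems of up to 5 facilities × 6 activities × 4 cadres
against an independent brute-force recomputation, plus full-bundle
ground-truth agreement at 1e-9. These sizes make the whole suite run in a
few seconds while exercising every code path the larger national-scale
configuration uses.

## Known limitations

- Specialist cadres, task-shifting/productivity scenarios, intervention
  costing, and facility-level vacancy analysis (duty stations are usually
  missing from staff returns) are out of scope.
- The published national projection trajectories cannot be reproduced
  without the unpublished per-cadre enrollment inputs; the package checks
  the model's structural properties instead.
- The published national density figure (1.49 workers per 1000) depends on
  a population denominator that was never printed; density code is
  validated against generator ground truth instead.
- Two published aggregate nurse-technician gap figures exceed the
  table-derived differences by a small unexplained offset; both netting
  conventions are implemented and labelled rather than tuned to match.
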