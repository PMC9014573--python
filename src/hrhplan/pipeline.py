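"""Training-pipeline stock-and-flow projection with intervention scenarios.

The future available workforce is projected annually per sub-cadre as

    W(t+1) = W(t) + inflow(t+1) - outflow(t+1)

where inflow is the graduating training cohort (enrollment lagged by program
duration, thinned by graduation rate, licensing pass rate, and absorption
into employment) plus workers hired from abroad, and outflow is the
start-of-year stock times the attrition rates (retirement + involuntary +
voluntary + study leave; baseline 1/2/3/1% = 7% total).

Intervention scenarios override flow parameters over time: linear ramps
(e.g. voluntary attrition 3% -> 1%), step changes (absorption 50% -> 75%),
and enrollment multipliers (doubling by a target year), with per-cadre
exemptions (community health workers keep their own recruitment path).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._util import StepSeries, round_half_up
from .core_data import PopulationProjection, WorkforceSnapshot

log = logging.getLogger("hrhplan")

WHO_SDG_THRESHOLD_PER_1000 = 4.45

YearValue = Union[float, Mapping[int, float]]


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingProgram:
    """Pre-service training pipeline for one sub-cadre."""

    subcadre: str
    enrollment_by_year: Mapping[int, float]
    graduation_rate: float
    pass_rate: float = 1.0  # 1.0 for cadres without a licensing exam
    duration_years: int = 3

    def __post_init__(self) -> None:
        _check_fraction("graduation_rate", self.graduation_rate)
        _check_fraction("pass_rate", self.pass_rate)
        if self.duration_years < 1:
            raise ValueError("duration_years must be >= 1")
        if any(e < 0 for e in self.enrollment_by_year.values()):
            raise ValueError("enrollment must be non-negative")

    def enrollment_start(self) -> int:
        return min(self.enrollment_by_year)


@dataclass(frozen=True)
class FlowParameters:
    """Recruitment and attrition rates governing one sub-cadre's flows.

    Scalar values apply to every year; a ``{year: value}`` mapping is a step
    function (value at the latest year <= the query year).
    """

    absorption_by_year: YearValue = 0.50
    hired_abroad_by_year: YearValue = 0.0
    retirement_rate: float = 0.01
    involuntary_rate: float = 0.02
    voluntary_rate_by_year: YearValue = 0.03
    study_leave_rate: float = 0.01

    def __post_init__(self) -> None:
        _check_fraction("retirement_rate", self.retirement_rate)
        _check_fraction("involuntary_rate", self.involuntary_rate)
        _check_fraction("study_leave_rate", self.study_leave_rate)
        for name, v in (("absorption", self.absorption_by_year),
                        ("voluntary_rate", self.voluntary_rate_by_year)):
            vals = v.values() if isinstance(v, Mapping) else [v]
            for x in vals:
                _check_fraction(name, x)

    def absorption_at(self, year: int) -> float:
        return StepSeries(dict(self.absorption_by_year)
                          if isinstance(self.absorption_by_year, Mapping)
                          else self.absorption_by_year).at(year)

    def hired_abroad_at(self, year: int) -> float:
        return StepSeries(dict(self.hired_abroad_by_year)
                          if isinstance(self.hired_abroad_by_year, Mapping)
                          else self.hired_abroad_by_year).at(year)

    def voluntary_at(self, year: int) -> float:
        return StepSeries(dict(self.voluntary_rate_by_year)
                          if isinstance(self.voluntary_rate_by_year, Mapping)
                          else self.voluntary_rate_by_year).at(year)

    def total_outflow_rate(self, year: int) -> float:
        return (self.retirement_rate + self.involuntary_rate
                + self.voluntary_at(year) + self.study_leave_rate)


@dataclass
class ParameterBundle:
    """Per-sub-cadre training programs and flow parameters for a projection."""

    programs: dict[str, TrainingProgram]
    flows: dict[str, FlowParameters]

    @classmethod
    def uniform(cls, programs: Iterable[TrainingProgram],
                flows: FlowParameters) -> "ParameterBundle":
        progs = {p.subcadre: p for p in programs}
        return cls(progs, {c: flows for c in progs})

    def cadres(self) -> list[str]:
        return sorted(self.programs)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Override:
    """One time-varying parameter override.

    ``mode='ramp'`` interpolates linearly in annual steps between the points
    and holds constant outside them; ``mode='step'`` holds each point's value
    from its year onward (baseline before the first point).  ``parameter`` is
    one of ``voluntary_rate``, ``absorption``, ``enrollment_multiplier``.
    """

    parameter: str
    points: tuple[tuple[int, float], ...]
    mode: str = "ramp"
    exempt: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.parameter not in ("voluntary_rate", "absorption",
                                  "enrollment_multiplier"):
            raise ValueError(f"unknown override parameter {self.parameter!r}")
        if self.mode not in ("ramp", "step"):
            raise ValueError(f"unknown override mode {self.mode!r}")
        years = [y for y, _ in self.points]
        if years != sorted(set(years)):
            raise ValueError("override points must be strictly time-ordered")

    def value_at(self, year: int) -> Optional[float]:
        """Override value for ``year``; None if the baseline applies."""
        if not self.points:
            return None
        years = [y for y, _ in self.points]
        vals = [v for _, v in self.points]
        if self.mode == "step":
            if year < years[0]:
                return None
            return StepSeries(dict(self.points)).at(year)
        if year <= years[0]:
            return vals[0]
        if year >= years[-1]:
            return vals[-1]
        return float(np.interp(year, years, vals))


@dataclass(frozen=True)
class ScenarioSpec:
    """A named bundle of parameter overrides."""

    name: str
    overrides: tuple[Override, ...] = ()


DCSA_CODE = "DCSA"


def baseline_scenario() -> ScenarioSpec:
    return ScenarioSpec("baseline")


def reduced_attrition(start_year: int = 2017, end_year: int = 2022,
                      start_rate: float = 0.03, end_rate: float = 0.01
                      ) -> ScenarioSpec:
    """Voluntary attrition ramped down linearly (3% -> 1% by 2022)."""
    return ScenarioSpec("reduced_attrition", (
        Override("voluntary_rate",
                 ((start_year, start_rate), (end_year, end_rate)), "ramp"),
    ))


def increased_absorption(year: int = 2018, rate: float = 0.75,
                         exempt: Iterable[str] = (DCSA_CODE,)) -> ScenarioSpec:
    """Graduate absorption stepped up (50% -> 75% from 2018); community
    health workers are hired against their own posts and stay exempt."""
    return ScenarioSpec("increased_absorption", (
        Override("absorption", ((year, rate),), "step", frozenset(exempt)),
    ))


def increased_enrollment(base_year: int = 2017, first_double: int = 2020,
                         second_double: int = 2030,
                         exempt: Iterable[str] = (DCSA_CODE,)) -> ScenarioSpec:
    """Training enrollment doubled by one year and doubled again by a later
    one, ramping linearly in between."""
    return ScenarioSpec("increased_enrollment", (
        Override("enrollment_multiplier",
                 ((base_year, 1.0), (first_double, 2.0), (second_double, 4.0)),
                 "ramp", frozenset(exempt)),
    ))


def combined_scenario(**kwargs) -> ScenarioSpec:
    """Composition of the three single interventions."""
    parts = (reduced_attrition(), increased_absorption(),
             increased_enrollment())
    return ScenarioSpec("combined",
                        tuple(o for s in parts for o in s.overrides))


SCENARIOS = {
    "baseline": baseline_scenario,
    "reduced_attrition": reduced_attrition,
    "increased_absorption": increased_absorption,
    "increased_enrollment": increased_enrollment,
    "combined": combined_scenario,
}


def apply_scenario(base: ParameterBundle, scenario: ScenarioSpec,
                   horizon: Sequence[int]) -> ParameterBundle:
    """Materialize a scenario's overrides into a new parameter bundle.

    Overridden paths are expanded to dense per-year values over ``horizon``
    (plus the enrollment years feeding it); exempted sub-cadres keep their
    baseline paths.  The input bundle is never mutated.
    """
    years = list(horizon)
    if not years:
        raise ValueError("empty horizon")
    programs = dict(base.programs)
    flows = dict(base.flows)
    known = set(base.programs) | set(base.flows)
    for ov in scenario.overrides:
        unknown = ov.exempt - known
        if unknown:
            raise KeyError(f"override exempts unknown sub-cadres {sorted(unknown)}")
        for cadre in sorted(known):
            if cadre in ov.exempt:
                continue
            if ov.parameter == "voluntary_rate":
                fl = flows[cadre]
                dense = {y: (ov.value_at(y) if ov.value_at(y) is not None
                             else fl.voluntary_at(y)) for y in years}
                flows[cadre] = replace(fl, voluntary_rate_by_year=dense)
            elif ov.parameter == "absorption":
                fl = flows[cadre]
                dense = {y: (ov.value_at(y) if ov.value_at(y) is not None
                             else fl.absorption_at(y)) for y in years}
                flows[cadre] = replace(fl, absorption_by_year=dense)
            else:  # enrollment_multiplier
                prog = programs.get(cadre)
                if prog is None:
                    continue
                scaled = {y: e * (ov.value_at(y) if ov.value_at(y) is not None
                                  else 1.0)
                          for y, e in prog.enrollment_by_year.items()}
                programs[cadre] = replace(prog, enrollment_by_year=scaled)
    return ParameterBundle(programs, flows)


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

@dataclass
class OutflowComponents:
    retired: float
    involuntary: float
    voluntary: float
    study_leave: float

    @property
    def total(self) -> float:
        return self.retired + self.involuntary + self.voluntary + self.study_leave


def project_inflow(programs: Mapping[str, TrainingProgram],
                   flows: Mapping[str, FlowParameters],
                   year: int) -> dict[str, float]:
    """Per-sub-cadre inflow for one year.

    inflow = enrollment(year - duration) * graduation_rate * pass_rate
             * absorption(year) + hired_abroad(year).
    Cohort years before the enrollment series contribute zero (warned).
    """
    out: dict[str, float] = {}
    for cadre, prog in programs.items():
        fl = flows[cadre]
        cohort_year = year - prog.duration_years
        enrollment = prog.enrollment_by_year.get(cohort_year)
        if enrollment is None:
            if cohort_year < prog.enrollment_start():
                log.warning("%s: cohort year %d precedes enrollment series; "
                            "graduate inflow set to 0", cadre, cohort_year)
            enrollment = 0.0
        grads_hired = (enrollment * prog.graduation_rate * prog.pass_rate
                       * fl.absorption_at(year))
        out[cadre] = grads_hired + fl.hired_abroad_at(year)
    return out


def project_outflow(workforce_at_start: Mapping[str, float],
                    flows: Mapping[str, FlowParameters],
                    year: int) -> dict[str, OutflowComponents]:
    """Per-sub-cadre outflow for one year, applied to start-of-year stock,
    decomposed into retirement / involuntary / voluntary / study leave."""
    out: dict[str, OutflowComponents] = {}
    for cadre, stock in workforce_at_start.items():
        fl = flows[cadre]
        if fl.total_outflow_rate(year) >= 1.0:
            raise ValueError(
                f"{cadre}: combined outflow rate >= 1 in {year}")
        out[cadre] = OutflowComponents(
            retired=stock * fl.retirement_rate,
            involuntary=stock * fl.involuntary_rate,
            voluntary=stock * fl.voluntary_at(year),
            study_leave=stock * fl.study_leave_rate,
        )
    return out


@dataclass
class ProjectionSeries:
    """Projected available workforce per sub-cadre per year, with its
    inflow/outflow decomposition.  Fractional workers are retained; rounding
    happens only at reporting."""

    years: list[int]
    workforce: dict[tuple[str, int], float]
    inflow: dict[tuple[str, int], float]
    outflow: dict[tuple[str, int], float]
    scenario: str = "baseline"

    def cadres(self) -> list[str]:
        return sorted({c for (c, _y) in self.workforce})

    def total(self, year: int) -> float:
        return sum(v for (_c, y), v in self.workforce.items() if y == year)

    def totals(self) -> dict[int, float]:
        out = {y: 0.0 for y in self.years}
        for (_c, y), v in self.workforce.items():
            out[y] += v
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.scenario, c, y, self.workforce[(c, y)],
                 self.inflow[(c, y)], self.outflow[(c, y)])
                for c in self.cadres() for y in self.years]
        return pd.DataFrame(rows, columns=["scenario", "subcadre", "year",
                                           "workforce", "inflow", "outflow"])


def project_workforce(snapshot: Union[WorkforceSnapshot, Mapping[str, float]],
                      programs: Mapping[str, TrainingProgram],
                      flows: Union[FlowParameters, Mapping[str, FlowParameters]],
                      scenario: Optional[ScenarioSpec] = None,
                      horizon: Sequence[int] = range(2017, 2041),
                      attrit_new_hires: bool = False) -> ProjectionSeries:
    """Run the annual stock-and-flow recurrence over ``horizon``.

    The first horizon year is the snapshot year (no flows applied).  By
    default outflow is computed on start-of-year stock, so the year's new
    graduates are not attrited in their hire year; ``attrit_new_hires=True``
    applies the rates to stock plus the year's inflow instead.
    """
    years = list(horizon)
    if len(years) < 1:
        raise ValueError("horizon must contain at least one year")
    initial = (snapshot.by_subcadre() if isinstance(snapshot, WorkforceSnapshot)
               else dict(snapshot))
    cadres = sorted(set(initial) | set(programs))
    progs = dict(programs)
    flow_map = (dict(flows) if isinstance(flows, Mapping)
                else {c: flows for c in cadres})
    for c in cadres:
        flow_map.setdefault(c, FlowParameters())
        progs.setdefault(c, TrainingProgram(c, {years[0]: 0.0}, 1.0, 1.0, 1))
    bundle = ParameterBundle(progs, flow_map)
    if scenario is not None and scenario.overrides:
        bundle = apply_scenario(bundle, scenario, years)

    wf: dict[tuple[str, int], float] = {}
    infl: dict[tuple[str, int], float] = {}
    outf: dict[tuple[str, int], float] = {}
    stock = {c: float(initial.get(c, 0.0)) for c in cadres}
    for c in cadres:
        wf[(c, years[0])] = stock[c]
        infl[(c, years[0])] = 0.0
        outf[(c, years[0])] = 0.0
    for year in years[1:]:
        year_in = project_inflow(bundle.programs, bundle.flows, year)
        if attrit_new_hires:
            base = {c: stock[c] + year_in.get(c, 0.0) for c in cadres}
        else:
            base = stock
        year_out = project_outflow(base, bundle.flows, year)
        for c in cadres:
            i = year_in.get(c, 0.0)
            o = year_out[c].total
            nxt = stock[c] + i - o
            if nxt < 0:
                log.warning("%s: projected stock negative in %d; floored at 0 "
                            "(check parameters)", c, year)
                o = stock[c] + i  # keep conservation exact at the floor
                nxt = 0.0
            wf[(c, year)] = nxt
            infl[(c, year)] = i
            outf[(c, year)] = o
            stock[c] = nxt
    name = scenario.name if scenario is not None else "baseline"
    return ProjectionSeries(years, wf, infl, outf, scenario=name)


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------

@dataclass
class TargetSeries:
    """Workforce targets per year: the (constant) establishment total and
    the WHO density threshold of 4.45 workers per 1000 population."""

    establishment_total: float
    who_total: dict[int, float]

    @classmethod
    def from_population(cls, establishment_total: float,
                        pop: PopulationProjection,
                        years: Iterable[int],
                        per_1000: float = WHO_SDG_THRESHOLD_PER_1000,
                        location: str = "national") -> "TargetSeries":
        who = {y: per_1000 * pop.get(location, y) / 1000.0 for y in years}
        return cls(float(establishment_total), who)

    def at(self, year: int) -> dict[str, float]:
        return {"establishment": self.establishment_total,
                "who": self.who_total[year]}


def crossing_year(series: ProjectionSeries,
                  targets: TargetSeries) -> dict[str, Optional[int]]:
    """First year the total projected workforce meets each target, or None
    if the target is never reached within the horizon."""
    totals = series.totals()
    out: dict[str, Optional[int]] = {}
    for name in ("establishment", "who"):
        out[name] = None
        for y in series.years:
            target = (targets.establishment_total if name == "establishment"
                      else targets.who_total[y])
            if totals[y] >= target:
                out[name] = y
                break
    return out


@dataclass
class TargetGap:
    gap: float
    pct_of_target: int


def gap_at_year(series: ProjectionSeries, targets: TargetSeries,
                year: int) -> dict[str, TargetGap]:
    """Shortfall against each target in a given year: gap = max(target -
    workforce, 0) and the percent of the target met (rounded half-up)."""
    if year not in series.years:
        raise ValueError(f"year {year} outside projection horizon")
    total = series.total(year)
    out = {}
    for name, target in targets.at(year).items():
        out[name] = TargetGap(max(target - total, 0.0),
                              round_half_up(100.0 * total / target))
    return out


def read_training_programs(path) -> dict[str, TrainingProgram]:
    """Read training programs from long-format CSV with columns (subcadre,
    year, enrollment, graduation_rate, pass_rate, duration_years); rates and
    duration are per-sub-cadre constants, enrollment varies by year."""
    df = pd.read_csv(path)
    needed = {"subcadre", "year", "enrollment", "graduation_rate",
              "pass_rate", "duration_years"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"training-program file lacks columns {sorted(missing)}")
    out: dict[str, TrainingProgram] = {}
    for cadre, grp in df.groupby("subcadre"):
        out[str(cadre)] = TrainingProgram(
            str(cadre),
            {int(r.year): float(r.enrollment) for r in grp.itertuples(index=False)},
            graduation_rate=float(grp["graduation_rate"].iloc[0]),
            pass_rate=float(grp["pass_rate"].iloc[0]),
            duration_years=int(grp["duration_years"].iloc[0]))
    return out


def flows_from_config(cfg: Mapping, cadres: Iterable[str]
                      ) -> dict[str, FlowParameters]:
    """Build per-sub-cadre flow parameters from a config mapping.

    Top-level keys set the shared rates (``absorption``, ``hired_abroad``,
    ``retirement_rate``, ``involuntary_rate``, ``voluntary_rate``,
    ``study_leave_rate``); an optional ``per_cadre`` mapping overrides any
    of them for specific sub-cadres (e.g. 100% absorption for community
    health workers).
    """
    def build(over: Mapping) -> FlowParameters:
        get = lambda k, d: over.get(k, cfg.get(k, d))  # noqa: E731
        return FlowParameters(
            absorption_by_year=get("absorption", 0.50),
            hired_abroad_by_year=get("hired_abroad", 0.0),
            retirement_rate=get("retirement_rate", 0.01),
            involuntary_rate=get("involuntary_rate", 0.02),
            voluntary_rate_by_year=get("voluntary_rate", 0.03),
            study_leave_rate=get("study_leave_rate", 0.01))

    per_cadre = cfg.get("per_cadre", {}) or {}
    return {c: build(per_cadre.get(c, {})) for c in cadres}


def recover_constant_flows(workforce: Sequence[float]) -> tuple[float, float]:
    """Invert the recurrence W(t+1) = (1 - r) W(t) + I by least squares,
    recovering the constant attrition rate r and constant inflow I from a
    projected total series.  Useful as a consistency check on generated
    projections."""
    w = np.asarray(workforce, dtype=float)
    if len(w) < 3:
        raise ValueError("need at least 3 points to identify rate and inflow")
    A = np.column_stack([w[:-1], np.ones(len(w) - 1)])
    coef, *_ = np.linalg.lstsq(A, w[1:], rcond=None)
    slope, intercept = coef
    return 1.0 - slope, float(intercept)
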