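"""Seeded synthetic health-system data and the published-totals fixture.

Two kinds of test data live here:

* :func:`generate_system` / :func:`generate_projection_inputs` — a seeded
  generator of complete, internally consistent input bundles (staff
  returns, establishments, training programs, service volumes, activity
  times, cadre shares, populations) for a multi-district health system,
  with the exact ground-truth quantities retained for assertions.

* :func:`malawi_fixture` — the published 2017 Malawi MoH/CHAM national
  vacancy totals by sub-cadre and by district/central hospital, plus the
  published demand-model anchors, encoded as in-memory tables so the
  analyses can be checked against real printed numbers with no download.

All randomness flows through one ``numpy`` generator stream seeded from a
single integer, so a seed plus a config identifies a bundle exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core_data import (CadreAliasMap, CadreRegistry, EstablishmentTable,
                        Location, LocationRegistry, PopulationProjection,
                        StaffRecord, WorkforceSnapshot)
from .pipeline import DCSA_CODE, FlowParameters, TrainingProgram
from .wfom import Availability, available_minutes_by_cadre

REFERENCE_DATE = date(2017, 12, 31)


# ---------------------------------------------------------------------------
# Published-totals fixture (Malawi MoH/CHAM, 2017)
# ---------------------------------------------------------------------------

# National filled and established posts per frontline sub-cadre, 2017.
_TABLE2 = (
    # code, current staff, established posts, printed % filled
    ("MO", 564, 784, 72),
    ("CO", 1311, 3956, 33),
    ("MA", 1213, 1739, 70),
    ("NMO", 992, 1498, 66),
    ("NMT", 4467, 12701, 35),
    ("CMA", 209, 208, 100),
    ("PHO", 66, 98, 67),
    ("PHT", 159, 832, 19),
    ("PHA", 81, 472, 17),
    ("LO", 94, 83, 113),
    ("LT", 351, 821, 43),
    ("LA", 116, 610, 19),
    ("EHO", 591, 1081, 55),
    ("DCSA", 10085, 10099, 100),
    ("DO", 31, 104, 30),
    ("DT", 123, 681, 18),
    ("NO", 36, 63, 57),
    ("HCW", 470, 1922, 24),
    ("RAD", 75, 137, 55),
    ("RT", 94, 204, 46),
)

# Filled and established posts per district / central hospital / HQ, 2017.
_TABLE3 = (
    # region, name, kind, current, established, printed %
    ("Central", "Dedza", "district", 782, 1234, 63),
    ("Central", "Dowa", "district", 766, 1161, 66),
    ("Central", "Kasungu", "district", 767, 1317, 58),
    ("Central", "Lilongwe", "district", 2227, 2560, 87),
    ("Central", "Mchinji", "district", 681, 1103, 62),
    ("Central", "Nkhotakota", "district", 493, 1095, 45),
    ("Central", "Ntcheu", "district", 793, 1239, 64),
    ("Central", "Ntchisi", "district", 366, 859, 43),
    ("Central", "Salima", "district", 669, 943, 71),
    ("North", "Chitipa", "district", 303, 830, 37),
    ("North", "Karonga", "district", 420, 1028, 41),
    ("North", "Mzimba", "district", 1346, 2054, 66),
    ("North", "Nkhata Bay", "district", 418, 1213, 34),
    ("North", "Rumphi", "district", 474, 1116, 42),
    ("South", "Balaka", "district", 596, 911, 65),
    ("South", "Blantyre", "district", 1058, 1293, 82),
    ("South", "Chikwawa", "district", 525, 1081, 49),
    ("South", "Chiradzulu", "district", 606, 987, 61),
    ("South", "Machinga", "district", 617, 962, 64),
    ("South", "Mangochi", "district", 1038, 1492, 70),
    ("South", "Mulanje", "district", 799, 1403, 57),
    ("South", "Mwanza", "district", 210, 640, 33),
    ("South", "Neno", "district", 282, 795, 35),
    ("South", "Nsanje", "district", 391, 1068, 37),
    ("South", "Phalombe", "district", 455, 958, 47),
    ("South", "Thyolo", "district", 803, 1159, 69),
    ("South", "Zomba", "district", 1186, 1424, 83),
    ("Central", "Headquarters", "headquarters", 174, 3536, 5),
    ("Central", "Kamuzu Central Hospital", "central_hospital", 610, 653, 93),
    ("North", "Mzuzu Central Hospital", "central_hospital", 313, 650, 48),
    ("Southwest", "Queen Elizabeth Central Hospital", "central_hospital",
     676, 679, 100),
    ("Southeast", "Zomba Central Hospital", "central_hospital", 284, 650, 44),
)

#: Demand-model result anchors from the same 2017 exercise.
NMT_REQUIRED_BY_FACILITY_TYPE = {
    "urban_health_centre": 320,
    "rural_health_centre": 3077,
    "district_hospital": 1092,
    "community_hospital": 1061,
    "central_hospital": 430,
}


@dataclass
class WfomAnchors:
    """Published demand-model results used as cross-checks."""

    nmt_required_by_facility_type: dict[str, int]
    pharmacist_filled: int = 66
    pharmacist_required: int = 545
    nursing_officer_filled: int = 992
    nursing_officer_additional: int = 1603

    @property
    def nmt_required_total(self) -> int:
        return sum(self.nmt_required_by_facility_type.values())

    @property
    def nursing_officer_required(self) -> int:
        return self.nursing_officer_filled + self.nursing_officer_additional


@dataclass
class MalawiFixture:
    """The printed 2017 national workforce totals as analysis-ready objects.

    Sub-cadre and location totals are two marginals of the same workforce
    (the full sub-cadre-by-location cross-tabulation was never published),
    so they are carried as two snapshot/establishment pairs sharing one
    grand total.
    """

    table2: pd.DataFrame
    table3: pd.DataFrame
    subcadre_snapshot: WorkforceSnapshot
    subcadre_establishment: EstablishmentTable
    location_snapshot: WorkforceSnapshot
    location_establishment: EstablishmentTable
    locations: LocationRegistry
    registry: CadreRegistry
    wfom: WfomAnchors
    total_staff_all_cadres: int = 37926
    establishment_total_all_cadres: int = 62269


def _slug(name: str) -> str:
    return name.lower().replace(" ", "_")


def malawi_fixture() -> MalawiFixture:
    """Build the published-totals fixture (Malawi MoH/CHAM, 2017)."""
    registry = CadreRegistry.default()
    table2 = pd.DataFrame(_TABLE2, columns=["subcadre", "current",
                                            "establishment", "pct_printed"])
    table2.insert(1, "cadre_group",
                  [registry.group_of(c) for c in table2["subcadre"]])
    table3 = pd.DataFrame(_TABLE3, columns=["region", "name", "kind",
                                            "current", "establishment",
                                            "pct_printed"])
    table3.insert(0, "location", [_slug(n) for n in table3["name"]])

    sc_snapshot = WorkforceSnapshot(
        REFERENCE_DATE,
        {(r.subcadre, "national"): int(r.current)
         for r in table2.itertuples(index=False)})
    sc_establishment = EstablishmentTable(
        {(r.subcadre, "national"): int(r.establishment)
         for r in table2.itertuples(index=False)},
        vintage="MoH 2014/15 + CHAM 2017")

    loc_snapshot = WorkforceSnapshot(
        REFERENCE_DATE,
        {("ALL", r.location): int(r.current)
         for r in table3.itertuples(index=False)})
    loc_establishment = EstablishmentTable(
        {("ALL", r.location): int(r.establishment)
         for r in table3.itertuples(index=False)},
        vintage="MoH 2014/15 + CHAM 2017")

    locations = LocationRegistry(
        Location(r.location, r.name, r.kind, r.region)
        for r in table3.itertuples(index=False))

    return MalawiFixture(
        table2=table2, table3=table3,
        subcadre_snapshot=sc_snapshot,
        subcadre_establishment=sc_establishment,
        location_snapshot=loc_snapshot,
        location_establishment=loc_establishment,
        locations=locations, registry=registry,
        wfom=WfomAnchors(dict(NMT_REQUIRED_BY_FACILITY_TYPE)),
    )


# ---------------------------------------------------------------------------
# Synthetic system generator
# ---------------------------------------------------------------------------

#: Essential-service activities modelled by the generator, with the cadres
#: that may perform each and the normative minutes per encounter.
ACTIVITY_DEFS = {
    "opd_consultation": (("CO", "MA", "NMT"), 10.0),
    "antenatal_visit": (("NMT", "NMO", "CMA"), 20.0),
    "delivery": (("NMO", "NMT"), 240.0),
    "immunization": (("NMT", "MA"), 5.0),
    "hiv_test": (("LT", "LA", "NMT"), 15.0),
    "lab_panel": (("LO", "LT", "LA"), 20.0),
    "dispensing": (("PHO", "PHT", "PHA"), 5.0),
    "minor_surgery": (("MO", "CO"), 60.0),
}

#: Annual encounter intensity (Poisson mean) per activity at a reference
#: rural health centre; other facility types scale these.
DEFAULT_VOLUME_MEANS = {
    "opd_consultation": 15000.0,
    "antenatal_visit": 2000.0,
    "delivery": 800.0,
    "immunization": 4000.0,
    "hiv_test": 3000.0,
    "lab_panel": 2500.0,
    "dispensing": 12000.0,
    "minor_surgery": 300.0,
}

FACILITY_TYPE_VOLUME_SCALE = {
    "urban_health_centre": 1.5,
    "rural_health_centre": 1.0,
    "community_hospital": 2.0,
    "district_hospital": 4.0,
    "central_hospital": 8.0,
}

DEFAULT_FACILITIES_PER_DISTRICT = {
    "urban_health_centre": 1,
    "rural_health_centre": 3,
    "community_hospital": 1,
    "district_hospital": 1,
}

#: Program duration (years) by cadre group; community health workers train
#: for a single year.
DEFAULT_DURATION_BY_GROUP = {
    "Clinical": 4,
    "Nursing/Midwifery": 3,
    "Pharmacy": 3,
    "Laboratory": 3,
    "Education and Environmental Health": 3,
    "Dental": 3,
    "Nutrition": 3,
    "Radiography": 3,
    "Other": 3,
}

#: Cadre groups whose graduates sit a licensing exam.
EXAM_GROUPS = ("Clinical", "Nursing/Midwifery", "Pharmacy", "Laboratory")


@dataclass
class DirtConfig:
    """Rates of the data pathologies seen in real staff returns."""

    unknown_title_rate: float = 0.0
    missing_facility_rate: float = 0.0
    sparse_facility_rate: float = 0.0  # facilities reporting no services


@dataclass
class SystemConfig:
    """Parameters of a synthetic multi-district health system.

    Defaults mirror the planning exercise's stated study conditions:
    district fill rates spanning 33-100%, annual attrition 7% decomposed as
    1% retirement + 2% involuntary + 3% voluntary + 1% study leave, cohort
    graduation rates of 75-100%, a 50% graduate-absorption rate, and
    Poisson-distributed facility service volumes.
    """

    seed: int = 0
    n_districts: int = 27
    n_central_hospitals: int = 4
    n_facilities_per_type: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FACILITIES_PER_DISTRICT))
    registry: CadreRegistry = field(default_factory=CadreRegistry.default)
    fill_rate_range: tuple[float, float] = (0.33, 1.00)
    attrition: tuple[float, float, float, float] = (0.01, 0.02, 0.03, 0.01)
    graduation_rate_range: tuple[float, float] = (0.75, 1.00)
    pass_rate_range: tuple[float, float] = (0.70, 1.00)
    absorption: float = 0.50
    volume_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VOLUME_MEANS))
    district_population_range: tuple[float, float] = (200_000, 900_000)
    population_growth: float = 0.027
    availability: Availability = field(default_factory=Availability)
    dirt: DirtConfig = field(default_factory=DirtConfig)

    def __post_init__(self) -> None:
        if self.n_districts < 1:
            raise ValueError("need at least one district")
        if not all(n >= 0 for n in self.n_facilities_per_type.values()):
            raise ValueError("facility counts must be non-negative")
        if sum(self.n_facilities_per_type.values()) == 0 \
                and self.n_central_hospitals == 0:
            raise ValueError("system must contain at least one facility")
        lo, hi = self.fill_rate_range
        if not (0.0 <= lo <= hi <= 1.5):
            raise ValueError("invalid fill_rate_range")
        for r in self.attrition:
            if not 0.0 <= r < 1.0:
                raise ValueError("attrition components must be in [0, 1)")
        if sum(self.attrition) >= 1.0:
            raise ValueError("total attrition must be below 100%")


@dataclass
class GroundTruth:
    """The exact quantities the generator drew, kept for assertions."""

    filled: dict[tuple[str, str], int]
    establishment: dict[tuple[str, str], int]
    district_fill_rates: dict[str, float]
    population: dict[tuple[str, int], float]
    staff_per_1000: dict[str, float]
    wfom_required: dict[tuple[str, str], float]  # (facility, subcadre)
    wfom_required_by_cadre: dict[str, float]
    n_unknown_titles: int = 0


@dataclass
class SyntheticBundle:
    """A complete, internally consistent set of planning inputs."""

    config: SystemConfig
    registry: CadreRegistry
    locations: LocationRegistry
    alias_map: CadreAliasMap
    staff_records: list[StaffRecord]
    establishment: EstablishmentTable
    population: PopulationProjection
    facilities: pd.DataFrame
    volumes: pd.DataFrame
    times: pd.DataFrame
    shares: pd.DataFrame
    availability: Availability
    ground_truth: GroundTruth


# Per-district establishment weights per sub-cadre, scaled from national
# frontline post totals spread over 27 districts.
def _establishment_weights(registry: CadreRegistry) -> dict[str, float]:
    national = {code: est for code, _cur, est, _pct in _TABLE2}
    return {sc.code: national.get(sc.code, 200) / 27.0 for sc in registry}


def _title_variant(rng: np.random.Generator, title: str) -> str:
    forms = (title, title.upper(), title.lower(), title + "  ", " " + title,
             title.replace("/", " / "))
    return forms[rng.integers(len(forms))]


def generate_system(config: SystemConfig) -> SyntheticBundle:
    """Generate a full input bundle plus its ground truth.

    The same seed and config always reproduce the identical bundle: every
    draw comes from one generator stream, so partial regeneration (and the
    silent fixture drift it invites) is impossible by design.
    """
    rng = np.random.default_rng(config.seed)
    registry = config.registry
    weights = _establishment_weights(registry)

    # --- locations -------------------------------------------------------
    regions = ("North", "Central", "South")
    locations = []
    for d in range(config.n_districts):
        locations.append(Location(f"d{d:02d}", f"District {d:02d}",
                                  "district", regions[d % 3]))
    for h in range(config.n_central_hospitals):
        locations.append(Location(f"ch{h}", f"Central Hospital {h}",
                                  "central_hospital", regions[h % 3]))
    loc_registry = LocationRegistry(locations)
    districts = [l.id for l in locations if l.kind == "district"]
    hospitals = [l.id for l in locations if l.kind == "central_hospital"]

    # --- establishment and filled posts ---------------------------------
    establishment: dict[tuple[str, str], int] = {}
    filled: dict[tuple[str, str], int] = {}
    district_fill: dict[str, float] = {}
    lo, hi = config.fill_rate_range
    for loc in districts + hospitals:
        rate = float(rng.uniform(lo, hi))
        district_fill[loc] = rate
        scale = 1.0 if loc in districts else 0.5
        for sc in registry:
            lam = max(weights[sc.code] * scale, 0.2)
            est = int(rng.poisson(lam)) + 1  # every cell keeps >=1 post
            establishment[(sc.code, loc)] = est
            filled[(sc.code, loc)] = int(rng.binomial(est, min(rate, 1.0)))

    # --- staff records ---------------------------------------------------
    alias_map = CadreAliasMap.identity(registry)
    facilities_by_district: dict[str, list[str]] = {}
    fac_rows = []
    for d in districts:
        fac_list = []
        for ftype, n in config.n_facilities_per_type.items():
            for i in range(n):
                fid = f"{d}_{ftype}_{i}"
                fac_rows.append((fid, ftype, d))
                fac_list.append(fid)
        facilities_by_district[d] = fac_list
    for h in hospitals:
        fac_rows.append((f"{h}_central_hospital_0", "central_hospital", h))
        facilities_by_district[h] = [f"{h}_central_hospital_0"]
    facilities = pd.DataFrame(fac_rows,
                              columns=["facility", "facility_type", "district"])

    records: list[StaffRecord] = []
    n_unknown = 0
    for (code, loc), n in sorted(filled.items()):
        display = registry[code].display_name
        for _ in range(n):
            if rng.random() < config.dirt.unknown_title_rate:
                raw = f"Unclassified Post {int(rng.integers(1000))}"
                n_unknown += 1
            else:
                raw = _title_variant(rng, display)
            fac = None
            fac_pool = facilities_by_district.get(loc, [])
            if fac_pool and rng.random() >= config.dirt.missing_facility_rate:
                fac = fac_pool[rng.integers(len(fac_pool))]
            records.append(StaffRecord(
                raw_title=raw, location=loc,
                employer="CHAM" if rng.random() < 0.29 else "MoH",
                subcadre=alias_map.resolve(raw),
                duty_facility=fac))

    # --- population ------------------------------------------------------
    years = list(range(REFERENCE_DATE.year, REFERENCE_DATE.year + 24))
    pop_lo, pop_hi = config.district_population_range
    base_pop = {d: float(rng.uniform(pop_lo, pop_hi)) for d in districts}
    population: dict[tuple[str, int], float] = {}
    for t, year in enumerate(years):
        growth = (1.0 + config.population_growth) ** t
        for d in districts:
            population[(d, year)] = round(base_pop[d] * growth)
        population[("national", year)] = sum(
            population[(d, year)] for d in districts)

    staff_by_loc: dict[str, int] = {}
    for (code, loc), n in filled.items():
        staff_by_loc[loc] = staff_by_loc.get(loc, 0) + n
    y0 = years[0]
    ratios = {d: round(1000.0 * staff_by_loc.get(d, 0) / population[(d, y0)], 2)
              for d in districts}

    # --- service volumes, times, shares ---------------------------------
    sparse = set()
    for fid in facilities["facility"]:
        if rng.random() < config.dirt.sparse_facility_rate:
            sparse.add(fid)
    vol_rows = []
    for row in facilities.itertuples(index=False):
        if row.facility in sparse:
            continue
        scale = FACILITY_TYPE_VOLUME_SCALE[row.facility_type]
        for act, lam in config.volume_means.items():
            vol_rows.append((row.facility, act,
                             int(rng.poisson(lam * scale))))
    volumes = pd.DataFrame(vol_rows,
                           columns=["facility", "activity", "annual_count"])

    time_rows = []
    share_rows = []
    for act, (cadres, base_min) in ACTIVITY_DEFS.items():
        if act not in config.volume_means:
            continue
        for ftype in FACILITY_TYPE_VOLUME_SCALE:
            minutes = round(float(base_min * rng.uniform(0.8, 1.2)), 2)
            time_rows.append((act, ftype, minutes))
            share = rng.dirichlet(np.ones(len(cadres)) * 4.0)
            share = np.round(share, 6)
            share[-1] = round(1.0 - share[:-1].sum(), 6)  # sums to exactly 1
            for cadre, s in zip(cadres, share):
                share_rows.append((act, ftype, cadre, float(s)))
    times = pd.DataFrame(time_rows,
                         columns=["activity", "facility_type", "minutes"])
    shares = pd.DataFrame(share_rows, columns=["activity", "facility_type",
                                               "subcadre", "share"])

    # --- ground-truth demand-model requirements (plain triple loop) ------
    wfom_cadres = sorted({c for cs, _m in ACTIVITY_DEFS.values() for c in cs})
    avail = available_minutes_by_cadre(config.availability, wfom_cadres)
    time_lut = {(r.activity, r.facility_type): r.minutes
                for r in times.itertuples(index=False)}
    share_lut: dict[tuple[str, str, str], float] = {
        (r.activity, r.facility_type, r.subcadre): r.share
        for r in shares.itertuples(index=False)}
    ftype_of = dict(zip(facilities["facility"], facilities["facility_type"]))
    wfom_required: dict[tuple[str, str], float] = {}
    for r in volumes.itertuples(index=False):
        ftype = ftype_of[r.facility]
        for cadre in wfom_cadres:
            s = share_lut.get((r.activity, ftype, cadre), 0.0)
            if s == 0.0:
                continue
            fte = r.annual_count * time_lut[(r.activity, ftype)] * s / avail[cadre]
            key = (r.facility, cadre)
            wfom_required[key] = wfom_required.get(key, 0.0) + fte
    by_cadre: dict[str, float] = {}
    for (_f, cadre), v in wfom_required.items():
        by_cadre[cadre] = by_cadre.get(cadre, 0.0) + v

    ground_truth = GroundTruth(
        filled=filled, establishment=establishment,
        district_fill_rates=district_fill,
        population=population, staff_per_1000=ratios,
        wfom_required=wfom_required, wfom_required_by_cadre=by_cadre,
        n_unknown_titles=n_unknown)

    return SyntheticBundle(
        config=config, registry=registry, locations=loc_registry,
        alias_map=alias_map, staff_records=records,
        establishment=EstablishmentTable(establishment, vintage="synthetic"),
        population=PopulationProjection(population),
        facilities=facilities, volumes=volumes, times=times, shares=shares,
        availability=config.availability, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# Projection inputs
# ---------------------------------------------------------------------------

@dataclass
class ProjectionInputs:
    """Training programs and flow parameters for a synthetic system, with
    the baseline projection recomputed by an independent plain-loop
    recurrence for assertions."""

    programs: dict[str, TrainingProgram]
    flows: dict[str, FlowParameters]
    initial_workforce: dict[str, float]
    horizon: list[int]
    ground_truth_workforce: dict[tuple[str, int], float]


def brute_force_projection(initial: Mapping[str, float],
                           programs: Mapping[str, TrainingProgram],
                           flows: Mapping[str, FlowParameters],
                           years: list[int]) -> dict[tuple[str, int], float]:
    """Reference stock-and-flow recurrence, written as the plainest possible
    loop: outflow on start-of-year stock, graduate inflow added at year end."""
    wf: dict[tuple[str, int], float] = {}
    stock = {c: float(v) for c, v in initial.items()}
    for c in stock:
        wf[(c, years[0])] = stock[c]
    for year in years[1:]:
        for c in stock:
            p, f = programs[c], flows[c]
            enrollment = p.enrollment_by_year.get(year - p.duration_years, 0.0)
            inflow = (enrollment * p.graduation_rate * p.pass_rate
                      * f.absorption_at(year)) + f.hired_abroad_at(year)
            outflow = stock[c] * (f.retirement_rate + f.involuntary_rate
                                  + f.voluntary_at(year) + f.study_leave_rate)
            stock[c] = stock[c] - outflow + inflow
            wf[(c, year)] = stock[c]
    return wf


def generate_projection_inputs(config: SystemConfig,
                               horizon: Optional[list[int]] = None,
                               initial_workforce: Optional[Mapping[str, float]]
                               = None) -> ProjectionInputs:
    """Draw per-cadre training programs and flow parameters.

    Enrollment is constant per cadre (scaled to the cadre's establishment
    weight); the community health worker cadre gets 100% absorption and a
    rising enrollment path, mirroring its recruit-to-post hiring.  Rates are
    drawn within the configured ranges; attrition components are the
    configured constants.
    """
    rng = np.random.default_rng(config.seed + 1)  # separate stream from bundle
    if horizon is None:
        horizon = list(range(REFERENCE_DATE.year, REFERENCE_DATE.year + 24))
    registry = config.registry
    weights = _establishment_weights(registry)
    ret, inv, vol, study = config.attrition
    g_lo, g_hi = config.graduation_rate_range
    p_lo, p_hi = config.pass_rate_range

    programs: dict[str, TrainingProgram] = {}
    flows: dict[str, FlowParameters] = {}
    initial: dict[str, float] = {}
    max_duration = max(DEFAULT_DURATION_BY_GROUP.values())
    enroll_years = list(range(horizon[0] - max_duration, horizon[-1] + 1))
    for sc in registry:
        group = sc.cadre_group
        duration = 1 if sc.code == DCSA_CODE \
            else DEFAULT_DURATION_BY_GROUP[group]
        grad = float(rng.uniform(g_lo, g_hi))
        pass_rate = float(rng.uniform(p_lo, p_hi)) \
            if group in EXAM_GROUPS else 1.0
        # scale cohort sizes and stocks with the number of districts
        size = config.n_districts
        base_enroll = max(float(rng.poisson(
            weights[sc.code] * 2.0 * size / 27.0)), 1.0)
        if sc.code == DCSA_CODE:
            # Community health workers: enrollment ramps up over five years
            # then holds, and every recruit is hired against a vacant post.
            enrollment = {y: base_enroll
                          * min(2.0, 1.0 + 0.2 * max(y - horizon[0], 0))
                          for y in enroll_years}
            absorption: float | dict[int, float] = 1.0
        else:
            enrollment = {y: base_enroll for y in enroll_years}
            absorption = config.absorption
        programs[sc.code] = TrainingProgram(sc.code, enrollment, grad,
                                            pass_rate, duration)
        flows[sc.code] = FlowParameters(
            absorption_by_year=absorption,
            hired_abroad_by_year=float(rng.poisson(0.5)),
            retirement_rate=ret, involuntary_rate=inv,
            voluntary_rate_by_year=vol, study_leave_rate=study)
        initial[sc.code] = float(rng.poisson(
            weights[sc.code] * config.n_districts * 0.6))

    if initial_workforce is not None:
        initial = {c: float(v) for c, v in initial_workforce.items()}
        for c in initial:
            if c not in programs:
                raise KeyError(f"no program drawn for cadre {c!r}")

    truth = brute_force_projection(initial, programs, flows, horizon)
    return ProjectionInputs(programs, flows, initial, list(horizon), truth)


# ---------------------------------------------------------------------------
# Bundle output
# ---------------------------------------------------------------------------

def staff_records_frame(bundle: SyntheticBundle) -> pd.DataFrame:
    """Staff records as a register table in the reader's default layout."""
    return pd.DataFrame(
        [(r.raw_title, r.location, r.employer, r.duty_facility or "")
         for r in bundle.staff_records],
        columns=["title", "location", "employer", "facility"])


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as the CSV files the other stages read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["staff_returns"] = outdir / "staff_returns.csv"
    staff_records_frame(bundle).to_csv(paths["staff_returns"], index=False)

    paths["establishment"] = outdir / "establishment.csv"
    bundle.establishment.to_csv(paths["establishment"])

    paths["alias_map"] = outdir / "alias_map.csv"
    pd.DataFrame([(sc.display_name, sc.code) for sc in bundle.registry],
                 columns=["alias", "target"]).to_csv(paths["alias_map"],
                                                     index=False)

    paths["population"] = outdir / "population.csv"
    pd.DataFrame([(loc, y, p) for (loc, y), p in
                  sorted(bundle.population.population.items())],
                 columns=["location", "year", "population"]) \
        .to_csv(paths["population"], index=False)

    for name in ("facilities", "volumes", "times", "shares"):
        paths[name] = outdir / f"{name}.csv"
        getattr(bundle, name).to_csv(paths[name], index=False)
    return paths
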