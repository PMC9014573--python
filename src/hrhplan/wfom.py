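"""Workforce Optimization Model: demand-based staffing requirements.

Converts observed service volumes and normative activity times into the
number of full-time workers each cadre would need to deliver the current
level of utilization with the right cadre taking the recommended time per
patient:

    requirement(cadre) = sum_activities volume * minutes * share(cadre)
                         / available_minutes(cadre)

where ``share`` splits each activity's minutes across the cadres that
perform it at that facility type, and ``available_minutes`` is the annual
patient-facing time per worker (working days net of holidays and leave,
times patient-facing hours per day).  Requirements are fractional FTE;
integer post recommendations use a ceiling at the chosen aggregation level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from ._util import round_half_up
from .core_data import EstablishmentTable, WorkforceSnapshot

log = logging.getLogger("hrhplan")

FACILITY_TYPES = (
    "urban_health_centre",
    "rural_health_centre",
    "community_hospital",
    "district_hospital",
    "central_hospital",
)

AGGREGATION_LEVELS = ("facility_type", "district", "national")


class MissingWfomInputError(KeyError):
    """A service volume has no matching activity time or cadre share."""


# ---------------------------------------------------------------------------
# Availability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Availability:
    """Annual patient-facing time budget per health worker.

    Defaults follow public-service entitlements: a calendar year minus
    public holidays, vacation, sick leave, study leave, and average
    maternity leave, at a stated number of patient-facing hours per day.
    """

    days_per_year: int = 365
    public_holidays: float = 11
    vacation_days: float = 21
    sick_days: float = 5
    study_leave_days: float = 5
    maternity_days_avg: float = 0
    patient_facing_hours_per_day: float = 6.0

    def working_days(self, maternity_days: Optional[float] = None) -> float:
        m = self.maternity_days_avg if maternity_days is None else maternity_days
        return (self.days_per_year - self.public_holidays - self.vacation_days
                - self.sick_days - self.study_leave_days - m)

    def __post_init__(self) -> None:
        if self.patient_facing_hours_per_day <= 0:
            raise ValueError("patient_facing_hours_per_day must be positive")
        if self.working_days() <= 0:
            raise ValueError("leave components exceed the calendar year")


def available_minutes(avail: Availability,
                      maternity_days: Optional[float] = None) -> float:
    """Patient-facing minutes per worker-year:
    (working days) * (hours per day) * 60."""
    days = avail.working_days(maternity_days)
    if days <= 0:
        raise ValueError("non-positive working days")
    return days * avail.patient_facing_hours_per_day * 60.0


def available_minutes_by_cadre(avail: Availability, cadres: Iterable[str],
                               maternity_override: Optional[Mapping[str, float]]
                               = None) -> dict[str, float]:
    """Per-cadre availability, applying any per-cadre maternity override
    (e.g. a predominantly female cadre with higher average maternity leave)."""
    maternity_override = maternity_override or {}
    return {c: available_minutes(avail, maternity_override.get(c))
            for c in cadres}


# ---------------------------------------------------------------------------
# Requirements
# ---------------------------------------------------------------------------

def _share_lookup(shares: pd.DataFrame) -> dict[tuple[str, str], dict[str, float]]:
    """Index shares by (activity, facility_type), validating that each
    group's shares sum to 1 (renormalized with a warning if off by >1e-6)."""
    out: dict[tuple[str, str], dict[str, float]] = {}
    for (act, ftype), grp in shares.groupby(["activity", "facility_type"]):
        s = dict(zip(grp["subcadre"], grp["share"].astype(float)))
        if any(v < 0 or v > 1 for v in s.values()):
            raise ValueError(f"share out of [0,1] for {(act, ftype)}")
        total = sum(s.values())
        if total <= 0:
            raise ValueError(f"zero total share for {(act, ftype)}")
        if abs(total - 1.0) > 1e-9:
            if abs(total - 1.0) > 1e-6:
                log.warning("shares for %s sum to %.8f; renormalizing",
                            (act, ftype), total)
            s = {c: v / total for c, v in s.items()}
        out[(act, ftype)] = s
    return out


def facility_requirement(volumes: Mapping[str, float],
                         times: Mapping[tuple[str, str], float],
                         shares: Mapping[tuple[str, str], Mapping[str, float]],
                         avail_minutes: Mapping[str, float],
                         facility_type: str) -> dict[str, float]:
    """FTE requirement per sub-cadre for one facility.

    ``volumes`` maps activity -> annual count; ``times`` maps
    (activity, facility_type) -> minutes per encounter; ``shares`` maps the
    same key to the cadre split of those minutes.  A volume whose activity
    lacks a time or share entry for this facility type is an error naming
    the pair.
    """
    req: dict[str, float] = {c: 0.0 for c in avail_minutes}
    for activity, count in volumes.items():
        if count < 0:
            raise ValueError(f"negative volume for activity {activity!r}")
        if count == 0:
            continue
        key = (activity, facility_type)
        if key not in times:
            raise MissingWfomInputError(f"no activity time for {key}")
        if key not in shares:
            raise MissingWfomInputError(f"no cadre shares for {key}")
        minutes = times[key]
        for cadre, share in shares[key].items():
            if share == 0:
                continue
            if cadre not in avail_minutes:
                raise MissingWfomInputError(
                    f"no availability for cadre {cadre!r}")
            req[cadre] = req.get(cadre, 0.0) + count * minutes * share \
                / avail_minutes[cadre]
    return req


@dataclass
class RequirementResult:
    """Per-(facility, sub-cadre) FTE requirements plus an account of the
    facilities excluded for insufficient service data."""

    table: pd.DataFrame  # columns: facility, subcadre, required
    excluded_facilities: list[str]

    def by_cadre(self) -> dict[str, float]:
        return self.table.groupby("subcadre")["required"].sum().to_dict()

    @property
    def total(self) -> float:
        return float(self.table["required"].sum())


def compute_requirements(volumes: pd.DataFrame,
                         times: pd.DataFrame,
                         shares: pd.DataFrame,
                         facilities: pd.DataFrame,
                         avail_minutes: Mapping[str, float],
                         min_activities: int = 1) -> RequirementResult:
    """Run the requirement computation across a facility registry.

    Input frames: ``volumes`` (facility, activity, annual_count); ``times``
    (activity, facility_type, minutes); ``shares`` (activity, facility_type,
    subcadre, share); ``facilities`` (facility, facility_type, district).
    Facilities reporting fewer than ``min_activities`` distinct activities
    are excluded and counted, mirroring registry completeness screens.
    """
    for col in ("facility", "activity", "annual_count"):
        if col not in volumes.columns:
            raise ValueError(f"volumes frame lacks column {col!r}")
    ftype_of = dict(zip(facilities["facility"], facilities["facility_type"]))
    time_lut = {(r.activity, r.facility_type): float(r.minutes)
                for r in times.itertuples(index=False)}
    share_lut = _share_lookup(shares)

    rows = []
    excluded: list[str] = []
    for fac, grp in volumes.groupby("facility"):
        if fac not in ftype_of:
            raise KeyError(f"facility {fac!r} missing from registry")
        reported = grp[grp["annual_count"] > 0]["activity"].nunique()
        if reported < min_activities:
            excluded.append(str(fac))
            continue
        vols = dict(zip(grp["activity"], grp["annual_count"].astype(float)))
        req = facility_requirement(vols, time_lut, share_lut, avail_minutes,
                                   ftype_of[fac])
        rows.extend((fac, c, v) for c, v in req.items())
    if excluded:
        log.warning("excluded %d facilities with fewer than %d reported "
                    "activities", len(excluded), min_activities)
    table = pd.DataFrame(rows, columns=["facility", "subcadre", "required"])
    return RequirementResult(table, excluded)


def aggregate_requirements(result: RequirementResult,
                           facilities: pd.DataFrame,
                           level: str = "national",
                           integer_posts: bool = False) -> pd.DataFrame:
    """Aggregate per-facility requirements to facility type, district, or
    national level.  Aggregates are exact sums of components; with
    ``integer_posts`` the summed FTE is ceiled to whole posts at this level.
    """
    if level not in AGGREGATION_LEVELS:
        raise ValueError(f"level must be one of {AGGREGATION_LEVELS}")
    table = result.table
    meta = facilities.set_index("facility")
    missing = set(table["facility"]) - set(meta.index)
    if missing:
        raise KeyError(f"facilities missing from registry: {sorted(missing)}")
    if level == "national":
        out = table.groupby("subcadre", as_index=False)["required"].sum()
        out.insert(0, "key", "national")
    else:
        col = "facility_type" if level == "facility_type" else "district"
        keyed = table.assign(key=table["facility"].map(meta[col]))
        out = keyed.groupby(["key", "subcadre"], as_index=False)["required"].sum()
    if integer_posts:
        out["posts"] = out["required"].map(math.ceil)
    return out


# ---------------------------------------------------------------------------
# Gap analysis
# ---------------------------------------------------------------------------

def gap_analysis(required_by_cadre: Mapping[str, float],
                 snapshot: WorkforceSnapshot,
                 establishment: Optional[EstablishmentTable] = None
                 ) -> pd.DataFrame:
    """Gaps between filled posts, demand-based requirements, and the
    establishment, per sub-cadre.

    gap_vs_optimal = max(required - filled, 0); pct_gap and
    pct_optimal_filled are integer percentages of the requirement (rounded
    half-up).  Cadres whose requirement exceeds their established posts are
    flagged: the demand-based need outstrips even the sanctioned ceiling.
    """
    filled = snapshot.by_subcadre()
    established = establishment.by_subcadre() if establishment else {}
    rows = []
    for cadre in sorted(required_by_cadre):
        req = float(required_by_cadre[cadre])
        f = filled.get(cadre, 0)
        est = established.get(cadre)
        gap = max(req - f, 0.0)
        if req > 0:
            pct_gap = round_half_up(100.0 * gap / req)
            pct_filled = round_half_up(100.0 * f / req)
        else:
            pct_gap = 0
            pct_filled = 100
        rows.append({
            "subcadre": cadre,
            "required": req,
            "filled": f,
            "established": est,
            "gap_vs_optimal": gap,
            "pct_gap": pct_gap,
            "pct_optimal_filled": pct_filled,
            "exceeds_establishment": est is not None and req > est,
        })
    return pd.DataFrame(rows)


def total_gap(requirements: pd.DataFrame, filled_by_key: Mapping[str, float],
              netting: str = "national") -> float:
    """Total workforce gap against demand-based requirements.

    ``netting='national'`` nets surpluses against shortfalls across keys;
    ``netting='positive_parts'`` sums only positive per-key gaps (surplus in
    one district cannot staff another).  ``requirements`` needs columns
    ``key`` and ``required``.
    """
    if netting not in ("national", "positive_parts"):
        raise ValueError("netting must be 'national' or 'positive_parts'")
    per_key = requirements.groupby("key")["required"].sum()
    gaps = {k: per_key[k] - float(filled_by_key.get(k, 0.0))
            for k in per_key.index}
    if netting == "national":
        return max(sum(gaps.values()), 0.0)
    return float(sum(max(g, 0.0) for g in gaps.values()))
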