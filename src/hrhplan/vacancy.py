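"""Vacancy analysis: filled posts versus establishment, and staffing ratios.

Compares a workforce snapshot against the establishment (sanctioned posts)
at national, sub-cadre, district/central-hospital, and region level, and
computes health-worker-to-population ratios.  Percentages are integer,
rounded half-up, which reproduces published vacancy tables cell-for-cell;
fill rates above 100% (over-established cadres) are reported as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from ._util import round_half_up
from .core_data import (CadreRegistry, EstablishmentTable, LocationRegistry,
                        PopulationProjection, WorkforceSnapshot)

log = logging.getLogger("hrhplan")

GROUP_BY_CHOICES = ("subcadre", "location", "total")
REGION_METHODS = ("unweighted_mean", "pooled")


class UndefinedFillRateError(ZeroDivisionError):
    """Fill rate requested against zero established posts."""


@dataclass
class VacancyRow:
    """One line of a vacancy table: filled vs established posts for a key."""

    key: str
    filled: int
    established: int
    pct_filled: Optional[int]
    region: Optional[str] = None
    flag: str = ""


@dataclass
class RatioRow:
    """Staff per 1000 population for one location (or 'national')."""

    key: str
    staff: int
    population: float
    per_1000: float


def fill_rate(filled: int, established: int) -> int:
    """Integer percentage of established posts filled, rounded half-up.

    Values above 100 are permitted (more staff than sanctioned posts).
    Raises :class:`UndefinedFillRateError` when ``established`` is zero —
    the rate is undefined, not a number.
    """
    if filled < 0 or established < 0:
        raise ValueError("counts must be non-negative")
    if established == 0:
        raise UndefinedFillRateError(
            f"fill rate undefined: {filled} filled against 0 established posts")
    return round_half_up(100.0 * filled / established)


def _safe_rate(filled: int, established: int) -> tuple[Optional[int], str]:
    if established == 0:
        return (None, "no_established_posts") if filled > 0 else (None, "empty")
    return fill_rate(filled, established), ""


def vacancy_table(snapshot: WorkforceSnapshot,
                  establishment: EstablishmentTable,
                  group_by: str = "subcadre",
                  registry: Optional[CadreRegistry] = None,
                  frontline_only: bool = True) -> list[VacancyRow]:
    """Filled vs established posts, grouped by sub-cadre or location.

    Emits one row per group plus a ``Total`` row whose filled/established
    counts are exact column sums.  Sub-cadres present in the snapshot but
    absent from the establishment get ``established=0`` and a warning flag.
    When ``registry`` is given and ``frontline_only`` is set, only sub-cadres
    flagged frontline are included (the scope of published vacancy tables);
    pass ``frontline_only=False`` to include support cadres.
    """
    if group_by not in GROUP_BY_CHOICES:
        raise ValueError(f"group_by must be one of {GROUP_BY_CHOICES}")

    keep = None
    if registry is not None and frontline_only:
        keep = set(registry.frontline_codes())

    def _filter(by_key: dict) -> dict:
        if keep is None:
            return by_key
        return {k: v for k, v in by_key.items() if k in keep}

    if group_by == "subcadre":
        filled = _filter(snapshot.by_subcadre())
        established = _filter(establishment.by_subcadre())
    elif group_by == "location":
        filled = snapshot.by_location()
        established = establishment.by_location()
    else:  # total
        filled = {"Total": snapshot.total}
        established = {"Total": establishment.total}

    rows: list[VacancyRow] = []
    keys = sorted(set(filled) | set(established))
    for key in keys:
        f = filled.get(key, 0)
        e = established.get(key, 0)
        pct, flag = _safe_rate(f, e)
        if flag == "no_established_posts":
            log.warning("%r has %d filled posts but no established posts", key, f)
        rows.append(VacancyRow(str(key), f, e, pct, flag=flag))

    if group_by != "total":
        tot_f = sum(r.filled for r in rows)
        tot_e = sum(r.established for r in rows)
        pct, flag = _safe_rate(tot_f, tot_e)
        rows.append(VacancyRow("Total", tot_f, tot_e, pct, flag=flag))
    return rows


def location_vacancy_table(snapshot: WorkforceSnapshot,
                           establishment: EstablishmentTable,
                           locations: LocationRegistry,
                           registry: Optional[CadreRegistry] = None,
                           frontline_only: bool = True) -> list[VacancyRow]:
    """Per-location vacancy table with region labels attached, suitable for
    region aggregation.  Headquarters and central hospitals are included as
    their own rows (and in the Total), as in published district tables."""
    rows = vacancy_table(snapshot, establishment, "location",
                         registry, frontline_only)
    for row in rows:
        if row.key in locations:
            row.region = locations[row.key].region
    return rows


def region_summary(district_rows: Iterable[VacancyRow],
                   method: str = "unweighted_mean",
                   locations: Optional[LocationRegistry] = None
                   ) -> list[VacancyRow]:
    """Aggregate district vacancy rows to regions.

    ``unweighted_mean`` averages the district integer fill percentages and
    rounds half-up — the rule that reproduces published region headers.
    ``pooled`` recomputes the rate from summed filled/established counts,
    the statistically conventional alternative.  Only rows for locations of
    kind ``district`` are aggregated; central hospitals and headquarters are
    excluded (when ``locations`` is given) or rows without a region label
    are skipped.
    """
    if method not in REGION_METHODS:
        raise ValueError(f"method must be one of {REGION_METHODS}")
    by_region: dict[str, list[VacancyRow]] = {}
    for row in district_rows:
        if row.key == "Total" or row.region is None:
            continue
        if locations is not None and row.key in locations \
                and locations[row.key].kind != "district":
            continue
        by_region.setdefault(row.region, []).append(row)

    out: list[VacancyRow] = []
    for region in sorted(by_region):
        rows = [r for r in by_region[region] if r.pct_filled is not None]
        if not rows:
            log.warning("region %r has no districts with a defined rate", region)
            continue
        f = sum(r.filled for r in rows)
        e = sum(r.established for r in rows)
        if method == "unweighted_mean":
            pct = round_half_up(sum(r.pct_filled for r in rows) / len(rows))
        else:
            pct = fill_rate(f, e)
        out.append(VacancyRow(region, f, e, pct, region=region))
    return out


def staff_per_1000(snapshot: WorkforceSnapshot,
                   pop: PopulationProjection,
                   year: int,
                   scope: Optional[Iterable[str]] = None,
                   locations: Optional[LocationRegistry] = None,
                   include_national: bool = True) -> list[RatioRow]:
    """Health workers per 1000 population, by location and nationally.

    District ratios count only staff posted to the district itself: central
    hospital staff serve whole regions and are excluded from any district's
    numerator (they still count nationally).  Ratios are reported to two
    decimal places.  A missing population projection raises ``KeyError``
    naming the location.
    """
    by_loc = snapshot.by_location()
    if scope is None:
        scope = sorted(by_loc)
    rows: list[RatioRow] = []
    for loc in scope:
        population = pop.get(loc, year)  # raises KeyError naming loc
        staff = by_loc.get(loc, 0)
        rows.append(RatioRow(loc, staff, population,
                             round(1000.0 * staff / population, 2)))
    if include_national:
        population = pop.get("national", year)
        staff = snapshot.total
        rows.append(RatioRow("national", staff, population,
                             round(1000.0 * staff / population, 2)))
    return rows


def rows_to_frame(rows: Iterable[VacancyRow]) -> pd.DataFrame:
    """Vacancy rows as a DataFrame with columns group/filled/established/
    pct_filled/flag (the CLI's CSV layout)."""
    return pd.DataFrame(
        [(r.key, r.filled, r.established,
          "" if r.pct_filled is None else r.pct_filled, r.flag)
         for r in rows],
        columns=["group", "filled", "established", "pct_filled", "flag"])
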