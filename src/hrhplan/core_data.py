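"""Domain types, cadre standardization, and tabular I/O.

The planning analyses all start from the same administrative inputs: "staff
return" registers (one row per employed health worker), establishment-post
lists (the sanctioned number of positions per sub-cadre and location), and
population projections.  This module defines the shared in-memory types,
the cadre-title standardization step, and CSV/XLSX readers and writers.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd
import yaml

from ._util import normalize_title

log = logging.getLogger("hrhplan")

EMPLOYERS = ("MoH", "CHAM")

CADRE_GROUPS = (
    "Clinical",
    "Nursing/Midwifery",
    "Pharmacy",
    "Laboratory",
    "Education and Environmental Health",
    "Dental",
    "Nutrition",
    "Radiography",
    "Other",
)

LOCATION_KINDS = ("district", "central_hospital", "headquarters")


class DataFormatError(ValueError):
    """An input file does not match the expected tabular layout."""


class UnknownSubCadreError(KeyError):
    """An alias or record references a sub-cadre code absent from the registry."""


# ---------------------------------------------------------------------------
# Cadres
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubCadre:
    """One occupational grade of health worker (e.g. Nurse Midwife Technician)."""

    code: str
    display_name: str
    cadre_group: str
    frontline: bool = True

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("SubCadre code must be non-empty")
        if not self.cadre_group:
            raise ValueError(f"SubCadre {self.code!r} needs a cadre_group")


#: The frontline sub-cadres of the Malawi MoH/CHAM workforce, grouped into
#: the nine broad cadre groups used throughout the analyses.
DEFAULT_SUBCADRES: tuple[SubCadre, ...] = (
    SubCadre("MO", "Medical Officer/Specialist", "Clinical"),
    SubCadre("CO", "Clinical Officer/Technician", "Clinical"),
    SubCadre("MA", "Medical Assistant", "Clinical"),
    SubCadre("NMO", "Nursing/Midwifery Officer", "Nursing/Midwifery"),
    SubCadre("NMT", "Nurse Midwife Technician", "Nursing/Midwifery"),
    SubCadre("CMA", "Community Midwifery Assistant", "Nursing/Midwifery"),
    SubCadre("PHO", "Pharmacy Officer", "Pharmacy"),
    SubCadre("PHT", "Pharmacy Technician", "Pharmacy"),
    SubCadre("PHA", "Pharmacy Assistant", "Pharmacy"),
    SubCadre("LO", "Laboratory Officer", "Laboratory"),
    SubCadre("LT", "Laboratory Technician", "Laboratory"),
    SubCadre("LA", "Laboratory Assistant", "Laboratory"),
    SubCadre("EHO", "Education/Environmental Health Officer",
             "Education and Environmental Health"),
    SubCadre("DCSA", "Disease Control and Surveillance Assistant",
             "Education and Environmental Health"),
    SubCadre("DO", "Dental Officer", "Dental"),
    SubCadre("DT", "Dental Therapist", "Dental"),
    SubCadre("NO", "Nutrition Officer", "Nutrition"),
    SubCadre("HCW", "Home Craft Worker", "Nutrition"),
    SubCadre("RAD", "Radiographer", "Radiography"),
    SubCadre("RT", "Radiography Technician", "Radiography"),
)


class CadreRegistry:
    """Registry of known sub-cadres, keyed by unique code."""

    def __init__(self, subcadres: Iterable[SubCadre]):
        self._by_code: dict[str, SubCadre] = {}
        for sc in subcadres:
            if sc.code in self._by_code:
                raise ValueError(f"duplicate sub-cadre code {sc.code!r}")
            self._by_code[sc.code] = sc
        if not self._by_code:
            raise ValueError("registry must contain at least one sub-cadre")

    @classmethod
    def default(cls) -> "CadreRegistry":
        return cls(DEFAULT_SUBCADRES)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> SubCadre:
        try:
            return self._by_code[code]
        except KeyError:
            raise UnknownSubCadreError(code) from None

    def __iter__(self) -> Iterator[SubCadre]:
        return iter(self._by_code.values())

    def __len__(self) -> int:
        return len(self._by_code)

    @property
    def codes(self) -> list[str]:
        return list(self._by_code)

    def frontline_codes(self) -> list[str]:
        return [sc.code for sc in self if sc.frontline]

    def group_of(self, code: str) -> str:
        return self[code].cadre_group


class CadreAliasMap:
    """Mapping from raw position titles to sub-cadre codes.

    Lookup is insensitive to case, repeated whitespace, and spacing around
    slashes.  Every alias maps to exactly one target; targets are validated
    against a registry when one is supplied.
    """

    def __init__(self, mapping: Mapping[str, str],
                 registry: Optional[CadreRegistry] = None):
        self._map: dict[str, str] = {}
        for alias, target in mapping.items():
            if registry is not None and target not in registry:
                raise UnknownSubCadreError(
                    f"alias {alias!r} maps to unknown sub-cadre {target!r}")
            key = normalize_title(alias)
            if key in self._map and self._map[key] != target:
                raise ValueError(
                    f"alias {alias!r} maps to both {self._map[key]!r} and {target!r}")
            self._map[key] = target

    @classmethod
    def identity(cls, registry: CadreRegistry) -> "CadreAliasMap":
        """Aliases every display name and code to its own code."""
        m = {sc.display_name: sc.code for sc in registry}
        m.update({sc.code: sc.code for sc in registry})
        return cls(m, registry)

    @classmethod
    def from_csv(cls, path: str | Path,
                 registry: Optional[CadreRegistry] = None) -> "CadreAliasMap":
        df = pd.read_csv(path, dtype=str)
        if df.shape[1] < 2:
            raise DataFormatError(
                f"alias map {path} must have two columns (alias, target)")
        alias_col, target_col = df.columns[:2]
        return cls(dict(zip(df[alias_col], df[target_col])), registry)

    def resolve(self, raw_title: str) -> Optional[str]:
        return self._map.get(normalize_title(raw_title))

    def __len__(self) -> int:
        return len(self._map)


# ---------------------------------------------------------------------------
# Locations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Location:
    """A workforce duty area: a district, a central hospital, or headquarters."""

    id: str
    name: str
    kind: str
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in LOCATION_KINDS:
            raise ValueError(f"unknown location kind {self.kind!r}")
        if self.kind == "district" and not self.region:
            raise ValueError(f"district {self.id!r} must carry a region label")


class LocationRegistry:
    """Registry of locations keyed by id."""

    def __init__(self, locations: Iterable[Location]):
        self._by_id: dict[str, Location] = {}
        for loc in locations:
            if loc.id in self._by_id:
                raise ValueError(f"duplicate location id {loc.id!r}")
            self._by_id[loc.id] = loc

    def __contains__(self, loc_id: str) -> bool:
        return loc_id in self._by_id

    def __getitem__(self, loc_id: str) -> Location:
        return self._by_id[loc_id]

    def __iter__(self) -> Iterator[Location]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def of_kind(self, *kinds: str) -> list[Location]:
        return [l for l in self if l.kind in kinds]


# ---------------------------------------------------------------------------
# Records and aggregates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaffRecord:
    """One row of a staff return: a single employed health worker."""

    raw_title: str
    location: str
    employer: str
    subcadre: Optional[str] = None
    duty_facility: Optional[str] = None

    def __post_init__(self) -> None:
        if self.employer not in EMPLOYERS:
            raise ValueError(
                f"employer must be one of {EMPLOYERS}, got {self.employer!r}")

    @property
    def resolved(self) -> bool:
        return self.subcadre is not None


@dataclass
class StandardizationResult:
    """Outcome of cadre standardization: the records, plus an explicit
    account of every title that could not be resolved."""

    records: list[StaffRecord]
    unresolved: list[StaffRecord] = field(default_factory=list)

    @property
    def n_resolved(self) -> int:
        return len(self.records) - len(self.unresolved)

    def unresolved_titles(self) -> Counter:
        return Counter(r.raw_title for r in self.unresolved)


@dataclass
class WorkforceSnapshot:
    """Counts of filled posts by (sub-cadre, location) at a reference date.

    ``employer_counts`` optionally retains the MoH/CHAM breakdown; ``counts``
    is the marginal over employers and is what the analyses consume.
    """

    reference_date: date
    counts: dict[tuple[str, str], int]
    employer_counts: Optional[dict[tuple[str, str, str], int]] = None
    n_unresolved: int = 0

    def __post_init__(self) -> None:
        for key, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {key}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def by_subcadre(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (sc, _loc), n in self.counts.items():
            out[sc] = out.get(sc, 0) + n
        return out

    def by_location(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (_sc, loc), n in self.counts.items():
            out[loc] = out.get(loc, 0) + n
        return out

    def to_frame(self) -> pd.DataFrame:
        if self.employer_counts:
            rows = [(sc, loc, emp, n)
                    for (sc, loc, emp), n in sorted(self.employer_counts.items())]
        else:
            rows = [(sc, loc, "all", n)
                    for (sc, loc), n in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["subcadre", "location", "employer", "count"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 reference_date: Optional[date] = None) -> "WorkforceSnapshot":
        df = pd.read_csv(path, dtype={"subcadre": str, "location": str,
                                      "employer": str, "count": int})
        for col in ("subcadre", "location", "employer", "count"):
            if col not in df.columns:
                raise DataFormatError(f"snapshot file {path} lacks column {col!r}")
        counts: dict[tuple[str, str], int] = {}
        employer_counts: dict[tuple[str, str, str], int] = {}
        keep_employers = not (df["employer"] == "all").all()
        for row in df.itertuples(index=False):
            key = (row.subcadre, row.location)
            counts[key] = counts.get(key, 0) + int(row.count)
            if keep_employers:
                ekey = (row.subcadre, row.location, row.employer)
                employer_counts[ekey] = employer_counts.get(ekey, 0) + int(row.count)
        return cls(reference_date or date.today(), counts,
                   employer_counts or None)


@dataclass
class EstablishmentTable:
    """Sanctioned (target) post counts by (sub-cadre, location)."""

    counts: dict[tuple[str, str], int]
    vintage: str = ""

    def __post_init__(self) -> None:
        for key, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative established posts for {key}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def by_subcadre(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (sc, _loc), n in self.counts.items():
            out[sc] = out.get(sc, 0) + n
        return out

    def by_location(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (_sc, loc), n in self.counts.items():
            out[loc] = out.get(loc, 0) + n
        return out

    def to_csv(self, path: str | Path) -> None:
        rows = [(sc, loc, n) for (sc, loc), n in sorted(self.counts.items())]
        pd.DataFrame(rows, columns=["subcadre", "location", "count"]) \
            .to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, vintage: str = "") -> "EstablishmentTable":
        df = pd.read_csv(path, dtype={"subcadre": str, "location": str, "count": int})
        for col in ("subcadre", "location", "count"):
            if col not in df.columns:
                raise DataFormatError(f"establishment file {path} lacks column {col!r}")
        counts: dict[tuple[str, str], int] = {}
        for row in df.itertuples(index=False):
            key = (row.subcadre, row.location)
            counts[key] = counts.get(key, 0) + int(row.count)
        return cls(counts, vintage)


@dataclass
class PopulationProjection:
    """Projected population per location (or 'national') per year."""

    population: dict[tuple[str, int], float]

    def __post_init__(self) -> None:
        years_by_loc: dict[str, list[int]] = {}
        for (loc, year), pop in self.population.items():
            if pop <= 0:
                raise ValueError(f"non-positive population for {(loc, year)}")
            years_by_loc.setdefault(loc, []).append(year)
        for loc, years in years_by_loc.items():
            ys = sorted(years)
            if ys != list(range(ys[0], ys[-1] + 1)):
                raise ValueError(f"population years for {loc!r} are not contiguous")

    def get(self, location: str, year: int) -> float:
        try:
            return self.population[(location, year)]
        except KeyError:
            raise KeyError(
                f"no population projection for {location!r} in {year}") from None

    def years(self, location: str = "national") -> list[int]:
        return sorted(y for (loc, y) in self.population if loc == location)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationProjection":
        df = pd.read_csv(path)
        for col in ("location", "year", "population"):
            if col not in df.columns:
                raise DataFormatError(f"population file {path} lacks column {col!r}")
        return cls({(str(r.location), int(r.year)): float(r.population)
                    for r in df.itertuples(index=False)})


# ---------------------------------------------------------------------------
# Readers and standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnMap:
    """Column names of a staff-return register; configurable because the
    register schema varies between HR offices."""

    title: str = "title"
    location: str = "location"
    employer: str = "employer"
    duty_facility: Optional[str] = "facility"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        return pd.read_excel(path, dtype=str)
    return pd.read_csv(path, dtype=str)


def read_staff_returns(path: str | Path, alias_map: CadreAliasMap,
                       columns: ColumnMap = ColumnMap()) -> list[StaffRecord]:
    """Read a staff-return register (CSV or XLSX) into StaffRecords.

    Titles are resolved through ``alias_map``; rows whose title is unknown
    are retained with ``subcadre=None`` and summarised in the log — they are
    never silently dropped.
    """
    df = _read_table(path)
    for col in (columns.title, columns.location, columns.employer):
        if col not in df.columns:
            raise DataFormatError(f"staff return {path} lacks column {col!r}")
    if len(df) == 0:
        raise DataFormatError(f"staff return {path} contains no data rows")
    has_facility = (columns.duty_facility is not None
                    and columns.duty_facility in df.columns)
    records = []
    for row in df.itertuples(index=False):
        rd = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        title = rd[columns.title]
        facility = rd.get(columns.duty_facility) if has_facility else None
        if facility is not None and pd.isna(facility):
            facility = None
        records.append(StaffRecord(
            raw_title=str(title),
            location=str(rd[columns.location]),
            employer=str(rd[columns.employer]),
            subcadre=alias_map.resolve(str(title)),
            duty_facility=facility,
        ))
    n_unresolved = sum(not r.resolved for r in records)
    if n_unresolved:
        titles = Counter(r.raw_title for r in records if not r.resolved)
        log.warning("%d of %d staff-return rows have unresolved titles: %s",
                    n_unresolved, len(records), dict(titles.most_common(10)))
    else:
        log.info("read %d staff-return rows, all titles resolved", len(records))
    return records


def standardize_cadres(records: Iterable[StaffRecord],
                       alias_map: CadreAliasMap,
                       registry: Optional[CadreRegistry] = None
                       ) -> StandardizationResult:
    """Resolve raw titles to sub-cadre codes.

    Deterministic and idempotent: re-applying to already-standardized
    records yields identical output.  Unresolved records are enumerated in
    the result's report, never dropped.
    """
    if len(alias_map) == 0:
        raise ValueError("alias map is empty")
    out: list[StaffRecord] = []
    unresolved: list[StaffRecord] = []
    for rec in records:
        code = alias_map.resolve(rec.raw_title)
        if code is None and rec.subcadre is not None:
            code = rec.subcadre  # already standardized upstream
        if code is not None and registry is not None and code not in registry:
            raise UnknownSubCadreError(code)
        new = replace(rec, subcadre=code)
        out.append(new)
        if code is None:
            unresolved.append(new)
    if unresolved:
        log.warning("standardization left %d of %d records unresolved",
                    len(unresolved), len(out))
    return StandardizationResult(out, unresolved)


def aggregate_snapshot(records: Iterable[StaffRecord],
                       reference_date: date) -> WorkforceSnapshot:
    """Aggregate standardized records into a workforce snapshot.

    Unresolved records are excluded from the counts and reported via the
    snapshot's ``n_unresolved``; resolved totals are conserved exactly.
    """
    counts: dict[tuple[str, str], int] = {}
    employer_counts: dict[tuple[str, str, str], int] = {}
    n_unresolved = 0
    for rec in records:
        if not rec.resolved:
            n_unresolved += 1
            continue
        key = (rec.subcadre, rec.location)
        counts[key] = counts.get(key, 0) + 1
        ekey = (rec.subcadre, rec.location, rec.employer)
        employer_counts[ekey] = employer_counts.get(ekey, 0) + 1
    if n_unresolved:
        log.warning("aggregate_snapshot excluded %d unresolved records", n_unresolved)
    return WorkforceSnapshot(reference_date, counts, employer_counts or None,
                             n_unresolved=n_unresolved)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load the structured run configuration (YAML mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DataFormatError(f"config {path} must be a mapping")
    return cfg
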