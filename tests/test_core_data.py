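"""Staff-return ingestion, cadre standardization, and snapshot aggregation."""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrhplan.core_data import (CadreAliasMap, CadreRegistry, ColumnMap,
                               DataFormatError, Location, PopulationProjection,
                               StaffRecord, SubCadre, UnknownSubCadreError,
                               WorkforceSnapshot, aggregate_snapshot,
                               read_staff_returns, standardize_cadres)
from hrhplan.synthetic import staff_records_frame

REF = date(2017, 12, 31)


@pytest.fixture(scope="module")
def registry():
    return CadreRegistry.default()


@pytest.fixture(scope="module")
def alias_map(registry):
    return CadreAliasMap.identity(registry)


def write_register(tmp_path, rows, columns=("title", "location", "employer")):
    path = tmp_path / "staff.csv"
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
    return path


class TestReadStaffReturns:
    def test_resolves_normalization_variants(self, tmp_path, alias_map):
        path = write_register(tmp_path, [
            ("Medical Officer/Specialist", "d1", "MoH"),
            ("medical officer/specialist ", "d1", "MoH"),
            ("NURSE MIDWIFE TECHNICIAN", "d2", "CHAM"),
        ])
        records = read_staff_returns(path, alias_map)
        assert len(records) == 3
        assert [r.subcadre for r in records] == ["MO", "MO", "NMT"]

    def test_unknown_title_flagged_not_dropped(self, tmp_path, alias_map):
        path = write_register(tmp_path, [
            ("Medical Officer/Specialist", "d1", "MoH"),
            ("Wizard of Accounts", "d1", "MoH"),
        ])
        records = read_staff_returns(path, alias_map)
        assert len(records) == 2
        assert sum(r.resolved for r in records) == 1
        assert records[1].subcadre is None

    def test_missing_column_names_it(self, tmp_path, alias_map):
        path = write_register(tmp_path, [("x", "d1")], ("title", "location"))
        with pytest.raises(DataFormatError, match="employer"):
            read_staff_returns(path, alias_map)

    def test_empty_file_is_error(self, tmp_path, alias_map):
        path = write_register(tmp_path, [])
        with pytest.raises(DataFormatError, match="no data rows"):
            read_staff_returns(path, alias_map)

    def test_xlsx_register_reads_like_csv(self, tmp_path, alias_map):
        path = tmp_path / "staff.xlsx"
        pd.DataFrame([("Pharmacy Officer", "d1", "MoH")],
                     columns=["title", "location", "employer"]).to_excel(
            path, index=False)
        (rec,) = read_staff_returns(path, alias_map)
        assert rec.subcadre == "PHO"

    def test_custom_column_mapping(self, tmp_path, alias_map):
        path = tmp_path / "staff.csv"
        pd.DataFrame([("Dental Officer", "d2", "CHAM")],
                     columns=["post", "duty", "org"]).to_csv(path, index=False)
        cols = ColumnMap(title="post", location="duty", employer="org",
                         duty_facility=None)
        (rec,) = read_staff_returns(path, alias_map, cols)
        assert (rec.subcadre, rec.location, rec.employer) == ("DO", "d2", "CHAM")

    def test_synthetic_register_counts_match_ground_truth(
            self, tmp_path, small_bundle):
        path = tmp_path / "register.csv"
        staff_records_frame(small_bundle).to_csv(path, index=False)
        records = read_staff_returns(path, small_bundle.alias_map)
        assert all(r.resolved for r in records)
        snap = aggregate_snapshot(records, REF)
        truth = {k: v for k, v in small_bundle.ground_truth.filled.items()
                 if v > 0}
        assert snap.counts == truth


class TestStandardizeCadres:
    def test_idempotent(self, alias_map, registry):
        records = [StaffRecord("nurse midwife technician", "d1", "MoH"),
                   StaffRecord("nobody knows", "d1", "MoH")]
        once = standardize_cadres(records, alias_map, registry)
        twice = standardize_cadres(once.records, alias_map, registry)
        assert once.records == twice.records
        assert len(once.unresolved) == len(twice.unresolved) == 1

    def test_aliases_merge_under_one_code(self, registry):
        amap = CadreAliasMap({"NURSE/MIDWIFERY OFFICER": "NMO",
                              "Nursing Officer": "NMO"}, registry)
        records = [StaffRecord("Nurse/Midwifery Officer", "d1", "MoH"),
                   StaffRecord("nursing officer", "d1", "CHAM")]
        result = standardize_cadres(records, amap, registry)
        assert {r.subcadre for r in result.records} == {"NMO"}

    def test_empty_alias_map_is_error(self, registry):
        with pytest.raises(ValueError, match="empty"):
            standardize_cadres([], CadreAliasMap({}), registry)

    def test_alias_to_unknown_code_is_error(self, registry):
        with pytest.raises(UnknownSubCadreError):
            CadreAliasMap({"Some Title": "NOPE"}, registry)

    @settings(derandomize=True, max_examples=100)
    @given(code=st.sampled_from([sc.code for sc in CadreRegistry.default()]),
           data=st.data())
    def test_casing_and_whitespace_perturbations_resolve(self, code, data,
                                                         registry, alias_map):
        """Any case flip / extra whitespace variant of a known title resolves
        to the same code as the clean title."""
        title = registry[code].display_name
        chars = []
        for ch in title:
            ch = data.draw(st.sampled_from([ch.upper(), ch.lower()]))
            chars.append(ch)
            if ch == " " and data.draw(st.booleans()):
                chars.append(" ")
        noisy = " " * data.draw(st.integers(0, 2)) + "".join(chars) + "  "
        assert alias_map.resolve(noisy) == code


class TestAggregateSnapshot:
    def test_empty_records_all_zero(self):
        snap = aggregate_snapshot([], REF)
        assert snap.counts == {} and snap.total == 0

    def test_conservation_with_unresolved(self, dirty_bundle):
        records = dirty_bundle.staff_records
        snap = aggregate_snapshot(records, REF)
        assert snap.total + snap.n_unresolved == len(records)
        assert snap.n_unresolved == dirty_bundle.ground_truth.n_unknown_titles
        assert snap.n_unresolved > 0

    def test_counts_match_generator_ground_truth(self, small_bundle):
        snap = aggregate_snapshot(small_bundle.staff_records, REF)
        truth = {k: v for k, v in small_bundle.ground_truth.filled.items()
                 if v > 0}
        assert snap.counts == truth
        assert snap.employer_counts is not None
        by_pair = {}
        for (sc, loc, _emp), n in snap.employer_counts.items():
            by_pair[(sc, loc)] = by_pair.get((sc, loc), 0) + n
        assert by_pair == truth

    def test_snapshot_csv_roundtrip(self, tmp_path, small_bundle):
        snap = aggregate_snapshot(small_bundle.staff_records, REF)
        path = tmp_path / "snapshot.csv"
        snap.to_csv(path)
        back = WorkforceSnapshot.from_csv(path, REF)
        assert back.counts == snap.counts
        assert back.employer_counts == snap.employer_counts

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            WorkforceSnapshot(REF, {("MO", "d1"): -1})


class TestDomainTypes:
    def test_district_requires_region(self):
        with pytest.raises(ValueError, match="region"):
            Location("d1", "D1", "district", None)

    def test_unknown_location_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            Location("x", "X", "clinic")

    def test_registry_rejects_duplicate_codes(self):
        with pytest.raises(ValueError, match="duplicate"):
            CadreRegistry([SubCadre("MO", "A", "Clinical"),
                           SubCadre("MO", "B", "Clinical")])

    def test_employer_restricted(self):
        with pytest.raises(ValueError, match="employer"):
            StaffRecord("t", "d1", "NGO")

    def test_population_years_must_be_contiguous(self):
        with pytest.raises(ValueError, match="contiguous"):
            PopulationProjection({("national", 2017): 1e6,
                                  ("national", 2019): 1e6})

    def test_population_missing_location_named(self):
        pop = PopulationProjection({("national", 2017): 1e6})
        with pytest.raises(KeyError, match="atlantis"):
            pop.get("atlantis", 2017)
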