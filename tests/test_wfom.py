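"""Demand-based staffing requirements: availability, requirements, gaps."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from hrhplan.core_data import EstablishmentTable, WorkforceSnapshot
from hrhplan.wfom import (Availability, MissingWfomInputError,
                          aggregate_requirements, available_minutes,
                          available_minutes_by_cadre, compute_requirements,
                          facility_requirement, gap_analysis, total_gap)

REF = date(2017, 12, 31)


class TestAvailability:
    def test_printed_formula(self):
        avail = Availability(public_holidays=11, vacation_days=21,
                             sick_days=5, study_leave_days=5,
                             maternity_days_avg=0,
                             patient_facing_hours_per_day=6)
        assert available_minutes(avail) == 323 * 360 == 116280

    def test_zero_leave_eight_hours(self):
        avail = Availability(public_holidays=0, vacation_days=0, sick_days=0,
                             study_leave_days=0, maternity_days_avg=0,
                             patient_facing_hours_per_day=8)
        assert available_minutes(avail) == 365 * 480 == 175200

    def test_per_cadre_maternity_override(self):
        avail = Availability(patient_facing_hours_per_day=6)
        minutes = available_minutes_by_cadre(avail, ["NMT", "MO"],
                                             {"NMT": 90})
        assert minutes["MO"] - minutes["NMT"] == pytest.approx(90 * 6 * 60)

    def test_leave_exceeding_year_is_error(self):
        with pytest.raises(ValueError):
            Availability(vacation_days=400)


def one_facility(volume=10000.0, minutes=15.0, shares=None,
                 avail=120000.0, ftype="rural_health_centre"):
    shares = shares or {"NMT": 1.0}
    return facility_requirement(
        {"act": volume},
        {("act", ftype): minutes},
        {("act", ftype): shares},
        {c: avail for c in shares},
        ftype)


class TestFacilityRequirement:
    def test_hand_arithmetic(self):
        req = one_facility()
        assert req["NMT"] == pytest.approx(150000 / 120000) == 1.25

    def test_zero_volumes_annihilate(self):
        req = one_facility(volume=0.0)
        assert req["NMT"] == 0.0

    def test_shares_split_in_exact_ratio(self):
        req = one_facility(shares={"NMT": 0.6, "MO": 0.4})
        assert req["NMT"] / req["MO"] == pytest.approx(1.5)

    def test_missing_time_entry_names_the_pair(self):
        with pytest.raises(MissingWfomInputError, match="act.*central"):
            facility_requirement({"act": 10.0}, {}, {("act", "central_hospital"):
                                                    {"NMT": 1.0}},
                                 {"NMT": 1e5}, "central_hospital")

    def test_missing_share_entry_names_the_pair(self):
        with pytest.raises(MissingWfomInputError, match="shares"):
            facility_requirement({"act": 10.0},
                                 {("act", "district_hospital"): 5.0}, {},
                                 {"NMT": 1e5}, "district_hospital")


def random_small_system(seed):
    rng = np.random.default_rng(seed)
    n_fac = int(rng.integers(1, 6))
    n_act = int(rng.integers(1, 7))
    n_cad = int(rng.integers(1, 5))
    ftypes = [str(np.array(["rural_health_centre", "district_hospital",
                            "central_hospital"])[rng.integers(3)])
              for _ in range(n_fac)]
    facilities = pd.DataFrame({
        "facility": [f"f{i}" for i in range(n_fac)],
        "facility_type": ftypes,
        "district": [f"d{i % 2}" for i in range(n_fac)]})
    acts = [f"a{j}" for j in range(n_act)]
    cadres = [f"c{k}" for k in range(n_cad)]
    volumes = pd.DataFrame(
        [(f"f{i}", a, int(rng.integers(0, 5000)))
         for i in range(n_fac) for a in acts],
        columns=["facility", "activity", "annual_count"])
    times = pd.DataFrame(
        [(a, t, float(rng.uniform(2, 60)))
         for a in acts for t in set(ftypes)],
        columns=["activity", "facility_type", "minutes"])
    share_rows = []
    for a in acts:
        for t in set(ftypes):
            w = rng.dirichlet(np.ones(n_cad))
            share_rows += [(a, t, c, float(s)) for c, s in zip(cadres, w)]
    shares = pd.DataFrame(share_rows, columns=["activity", "facility_type",
                                               "subcadre", "share"])
    avail = {c: float(rng.uniform(8e4, 1.4e5)) for c in cadres}
    return volumes, times, shares, facilities, avail


def oracle_requirements(volumes, times, shares, facilities, avail):
    """Independent brute-force double loop over volume rows and share rows."""
    ftype = dict(zip(facilities["facility"], facilities["facility_type"]))
    out = {}
    for vrow in volumes.itertuples(index=False):
        t = times[(times["activity"] == vrow.activity)
                  & (times["facility_type"] == ftype[vrow.facility])]
        minutes = float(t["minutes"].iloc[0])
        s = shares[(shares["activity"] == vrow.activity)
                   & (shares["facility_type"] == ftype[vrow.facility])]
        for srow in s.itertuples(index=False):
            key = (vrow.facility, srow.subcadre)
            out[key] = out.get(key, 0.0) + (vrow.annual_count * minutes
                                            * srow.share / avail[srow.subcadre])
    return out


class TestComputeRequirements:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        volumes, times, shares, facilities, avail = random_small_system(seed)
        result = compute_requirements(volumes, times, shares, facilities, avail)
        got = {(r.facility, r.subcadre): r.required
               for r in result.table.itertuples(index=False) if r.required > 0}
        expect = {k: v for k, v in
                  oracle_requirements(volumes, times, shares, facilities,
                                      avail).items() if v > 0}
        assert set(got) == set(expect)
        for k in expect:
            assert got[k] == pytest.approx(expect[k], abs=1e-9)

    def test_linearity_in_volumes(self):
        volumes, times, shares, facilities, avail = random_small_system(3)
        base = compute_requirements(volumes, times, shares, facilities, avail)
        scaled_volumes = volumes.assign(annual_count=volumes["annual_count"] * 3)
        scaled = compute_requirements(scaled_volumes, times, shares,
                                      facilities, avail)
        merged = base.table.merge(scaled.table, on=["facility", "subcadre"])
        assert np.allclose(merged["required_y"], 3 * merged["required_x"])

    def test_monotonicity(self):
        volumes, times, shares, facilities, avail = random_small_system(4)
        base = compute_requirements(volumes, times, shares, facilities,
                                    avail).by_cadre()
        more_time = times.assign(minutes=times["minutes"] * 1.5)
        up = compute_requirements(volumes, more_time, shares, facilities,
                                  avail).by_cadre()
        assert all(up[c] >= base[c] - 1e-12 for c in base)
        more_avail = {c: v * 1.5 for c, v in avail.items()}
        down = compute_requirements(volumes, times, shares, facilities,
                                    more_avail).by_cadre()
        assert all(down[c] <= base[c] + 1e-12 for c in base)

    def test_share_conservation(self):
        """Total service minutes distributed to cadres equals sum of
        volume x minutes: the share matrix neither creates nor loses time."""
        volumes, times, shares, facilities, avail = random_small_system(5)
        result = compute_requirements(volumes, times, shares, facilities, avail)
        distributed = sum(r.required * avail[r.subcadre]
                          for r in result.table.itertuples(index=False))
        ftype = dict(zip(facilities["facility"], facilities["facility_type"]))
        tlut = {(r.activity, r.facility_type): r.minutes
                for r in times.itertuples(index=False)}
        direct = sum(r.annual_count * tlut[(r.activity, ftype[r.facility])]
                     for r in volumes.itertuples(index=False))
        assert distributed == pytest.approx(direct, rel=1e-9)

    def test_sparse_facilities_excluded_and_counted(self):
        volumes, times, shares, facilities, avail = random_small_system(6)
        empty = volumes.copy()
        fac0 = facilities["facility"].iloc[0]
        empty.loc[empty["facility"] == fac0, "annual_count"] = 0
        result = compute_requirements(empty, times, shares, facilities, avail,
                                      min_activities=1)
        assert fac0 in result.excluded_facilities
        assert fac0 not in set(result.table["facility"])

    def test_shares_renormalized_with_warning(self, caplog):
        volumes = pd.DataFrame([("f0", "a", 1000)],
                               columns=["facility", "activity", "annual_count"])
        times = pd.DataFrame([("a", "district_hospital", 10.0)],
                             columns=["activity", "facility_type", "minutes"])
        shares = pd.DataFrame([("a", "district_hospital", "c0", 0.3),
                               ("a", "district_hospital", "c1", 0.3)],
                              columns=["activity", "facility_type",
                                       "subcadre", "share"])
        facilities = pd.DataFrame([("f0", "district_hospital", "d0")],
                                  columns=["facility", "facility_type",
                                           "district"])
        import logging
        with caplog.at_level(logging.WARNING, logger="hrhplan"):
            result = compute_requirements(volumes, times, shares, facilities,
                                          {"c0": 1e5, "c1": 1e5})
        assert "renormaliz" in caplog.text
        assert result.by_cadre()["c0"] == pytest.approx(1000 * 10 * 0.5 / 1e5)


class TestAggregation:
    def test_single_facility_aggregate_equals_facility_table(self):
        volumes, times, shares, facilities, avail = random_small_system(7)
        one = facilities.iloc[[0]]
        vol = volumes[volumes["facility"] == one["facility"].iloc[0]]
        result = compute_requirements(vol, times, shares, one, avail)
        agg = aggregate_requirements(result, one, "national")
        assert agg.set_index("subcadre")["required"].to_dict() == \
            pytest.approx(result.by_cadre())

    def test_national_totals_equal_sum_over_facility_types(self, small_bundle):
        cadres = sorted(small_bundle.shares["subcadre"].unique())
        avail = available_minutes_by_cadre(small_bundle.availability, cadres)
        result = compute_requirements(small_bundle.volumes, small_bundle.times,
                                      small_bundle.shares,
                                      small_bundle.facilities, avail)
        by_type = aggregate_requirements(result, small_bundle.facilities,
                                         "facility_type")
        national = aggregate_requirements(result, small_bundle.facilities,
                                          "national")
        per_cadre_type = by_type.groupby("subcadre")["required"].sum()
        per_cadre_nat = national.set_index("subcadre")["required"]
        assert np.allclose(per_cadre_type.sort_index(),
                           per_cadre_nat.sort_index())

    def test_unmapped_facility_is_error(self):
        volumes, times, shares, facilities, avail = random_small_system(8)
        result = compute_requirements(volumes, times, shares, facilities, avail)
        with pytest.raises(KeyError, match="missing from registry"):
            aggregate_requirements(result, facilities.iloc[0:0], "district")

    def test_integer_posts_use_ceiling(self):
        volumes, times, shares, facilities, avail = random_small_system(9)
        result = compute_requirements(volumes, times, shares, facilities, avail)
        agg = aggregate_requirements(result, facilities, "national",
                                     integer_posts=True)
        assert (agg["posts"] >= agg["required"]).all()
        assert (agg["posts"] - agg["required"] < 1).all()


class TestGapAnalysis:
    def test_published_pharmacist_gap_shape(self):
        snap = WorkforceSnapshot(REF, {("PHO", "national"): 66})
        df = gap_analysis({"PHO": 545.0}, snap)
        row = df.iloc[0]
        assert row["gap_vs_optimal"] == 479
        assert row["pct_gap"] == 88

    def test_published_nursing_gap_shape(self):
        snap = WorkforceSnapshot(REF, {("NMO", "national"): 992})
        df = gap_analysis({"NMO": 992.0 + 1603.0}, snap)
        assert df.iloc[0]["pct_gap"] == 62

    def test_filled_equals_required(self):
        snap = WorkforceSnapshot(REF, {("NMT", "d0"): 10})
        df = gap_analysis({"NMT": 10.0}, snap)
        row = df.iloc[0]
        assert row["gap_vs_optimal"] == 0
        assert row["pct_optimal_filled"] == 100

    def test_requirement_above_establishment_flagged(self):
        snap = WorkforceSnapshot(REF, {("LO", "d0"): 94})
        est = EstablishmentTable({("LO", "d0"): 83})
        df = gap_analysis({"LO": 120.0}, snap, est)
        assert bool(df.iloc[0]["exceeds_establishment"])

    def test_netting_conventions(self):
        req = pd.DataFrame([("d0", "NMT", 10.0), ("d1", "NMT", 10.0)],
                           columns=["key", "subcadre", "required"])
        filled = {"d0": 14.0, "d1": 4.0}
        assert total_gap(req, filled, "national") == pytest.approx(2.0)
        assert total_gap(req, filled, "positive_parts") == pytest.approx(6.0)
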