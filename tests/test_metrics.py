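"""Spatial-accuracy metrics, reclassification, rank tests, comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from flowregions import (
    Partition,
    compactness,
    compare_methods,
    connectivity,
    localization_index,
    mann_whitney_u,
    market_share_index,
    net_patient_flow,
    percentage,
    reclassification,
)
from flowregions.regions import RegionSet

from conftest import toy_cohort


def flows(rows):
    """rows: (home_zip, facility, count) triplets -> cohort frame."""
    out = []
    i = 0
    for z, h, n in rows:
        for _ in range(n):
            out.append((f"e{i}", f"p{i}", z, h, 0, 1))
            i += 1
    return toy_cohort(out)


TWO_REGIONS = Partition({"z1": 0, "z2": 1, "h1": 0, "h2": 1})


class TestLocalizationIndex:
    def test_closed_system_is_one_everywhere(self):
        li = localization_index(flows([("z1", "h1", 5), ("z2", "h2", 7)]),
                                TWO_REGIONS)
        assert (li == 1.0).all()

    def test_direct_ratio(self):
        li = localization_index(flows([("z1", "h1", 8), ("z1", "h2", 2)]),
                                TWO_REGIONS)
        assert li.loc[0] == pytest.approx(0.8)

    def test_region_without_residents_flagged_undefined(self):
        li = localization_index(flows([("z1", "h1", 5), ("z1", "h2", 5)]),
                                TWO_REGIONS)
        assert np.isnan(li.loc[1])
        assert li.attrs["undefined"] == [1]

    def test_matches_brute_force_tally_on_random_fixture(self):
        rng = np.random.default_rng(0)
        zips = [f"z{i}" for i in range(6)]
        hosps = [f"h{i}" for i in range(4)]
        part = Partition({u: int(rng.integers(0, 3))
                          for u in zips + hosps})
        rows = [(zips[rng.integers(0, 6)], hosps[rng.integers(0, 4)], 1)
                for _ in range(50)]
        cohort = flows(rows)
        li = localization_index(cohort, part)
        for r in sorted(set(part.labels.values())):
            res = [1 for z, h, _ in rows if part[z] == r]
            same = [1 for z, h, _ in rows if part[z] == r and part[h] == r]
            if res:
                assert li.loc[r] == pytest.approx(len(same) / len(res))


class TestMarketShareIndex:
    def test_closed_system_is_zero(self):
        msi = market_share_index(flows([("z1", "h1", 5), ("z2", "h2", 7)]),
                                 TWO_REGIONS)
        assert (msi == 0.0).all()

    def test_direct_ratio(self):
        msi = market_share_index(flows([("z2", "h1", 5), ("z1", "h1", 15)]),
                                 TWO_REGIONS)
        assert msi.loc[0] == pytest.approx(0.25)

    def test_inflow_bookkeeping_matches_npf_numerators(self):
        cohort = flows([("z1", "h1", 10), ("z1", "h2", 4), ("z2", "h2", 6),
                        ("z2", "h1", 2)])
        msi = market_share_index(cohort, TWO_REGIONS)
        npf = net_patient_flow(cohort, TWO_REGIONS)
        treated = {0: 12, 1: 10}
        outgoing = {0: 4, 1: 2}
        for r in (0, 1):
            incoming = msi.loc[r] * treated[r]
            assert npf.loc[r] == pytest.approx(incoming / outgoing[r])


class TestNetPatientFlow:
    def test_direct_ratio(self):
        cohort = flows([("z1", "h1", 1), ("z2", "h1", 4), ("z1", "h2", 2)])
        npf = net_patient_flow(cohort, TWO_REGIONS)
        assert npf.loc[0] == pytest.approx(2.0)

    def test_balanced_flows_score_one(self):
        cohort = flows([("z1", "h2", 3), ("z2", "h1", 3)])
        npf = net_patient_flow(cohort, TWO_REGIONS)
        assert (npf == 1.0).all()

    def test_two_region_reciprocity(self):
        cohort = flows([("z1", "h1", 9), ("z1", "h2", 6), ("z2", "h2", 8),
                        ("z2", "h1", 3)])
        npf = net_patient_flow(cohort, TWO_REGIONS)
        assert npf.loc[0] == pytest.approx(1 / npf.loc[1])

    def test_zero_outgoing_flagged_undefined(self):
        npf = net_patient_flow(flows([("z1", "h1", 5), ("z2", "h1", 5)]),
                               TWO_REGIONS)
        assert np.isnan(npf.loc[0])  # nothing leaves region 0
        assert npf.loc[1] == 0.0
        assert npf.attrs["undefined"] == [0]


def pairs(rows):
    return pd.DataFrame(rows, columns=["sender_id", "receiver_id",
                                       "sender_facility", "receiver_facility",
                                       "gap_days"])


class TestConnectivity:
    def test_zero_without_transfers(self):
        conn = connectivity(pairs([]), TWO_REGIONS)
        assert (conn == 0).all()

    def test_counts_within_region_only(self):
        p = Partition({"h1": 0, "h2": 0, "h3": 1})
        tr = pairs([("a", "b", "h1", "h2", 0)] * 3 + [("c", "d", "h1", "h3", 0)] * 2)
        conn = connectivity(tr, p)
        assert conn.loc[0] == 3 and conn.loc[1] == 0

    def test_conservation_against_total(self, small_system):
        _, _, _, cohort, transfers = small_system
        p = Partition({u: sum(map(ord, u)) % 3 for u in
                       set(cohort["home_zip"]) | set(cohort["facility"])})
        conn = connectivity(transfers, p)
        crossing = sum(1 for r in transfers.itertuples()
                       if p[r.sender_facility] != p[r.receiver_facility])
        assert conn.sum() + crossing == len(transfers)


class TestCompactness:
    def region(self, geom):
        return RegionSet(label=0, zip_ids=[], hospital_ids=[], footprint=geom)

    def test_disc_scores_one(self):
        disc = Point(0, 0).buffer(3.0, quad_segs=512)
        assert compactness(self.region(disc)) == pytest.approx(1.0, abs=1e-3)

    def test_unit_square_closed_form(self):
        sq = box(0, 0, 1, 1)
        assert compactness(self.region(sq)) == pytest.approx(2 / np.sqrt(np.pi),
                                                             abs=1e-12)

    def test_scale_invariance(self):
        small = compactness(self.region(box(0, 0, 1, 2)))
        big = compactness(self.region(box(0, 0, 10, 20)))
        assert small == pytest.approx(big, abs=1e-12)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            compactness(self.region(box(0, 0, 1, 1).intersection(box(5, 5, 6, 6))))


class TestPercentage:
    @pytest.mark.parametrize("num,den,want", [
        (3212, 405_493, 0.79),
        (10_037, 839_375, 1.20),
        (37, 139, 26.62),
        (48, 336, 14.29),
        (1, 800, 0.13),  # 0.125% rounds half-up at the 2nd decimal
    ])
    def test_printed_precision(self, num, den, want):
        assert percentage(num, den) == want

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            percentage(1, 0)


class TestMannWhitney:
    def test_extreme_separation_exact(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_for_n4_n4(self, seed):
        """Exact p by brute-force enumeration of all 8C4 label splits."""
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1.0, 9.0))  # tie-free
        x, y = pooled[:4], pooled[4:]
        u_obs, p_obs = mann_whitney_u(x, y)

        def u_of(xs, ys):
            return sum(1 for a in xs for b in ys if a > b)

        us = [u_of(pooled[list(idx)],
                   pooled[[i for i in range(8) if i not in idx]])
              for idx in itertools.combinations(range(8), 4)]
        lo = min(u_obs, 16 - u_obs)
        p_exact = sum(1 for u in us if min(u, 16 - u) <= lo) / len(us)
        assert u_obs == u_of(x, y)
        assert p_obs == pytest.approx(p_exact)


class TestReclassification:
    def fixture(self):
        # reference: {h1..h4}=R0, {h5,h6}=R1; detected moves h4 into region 1
        ref = Partition({f"h{i}": (0 if i <= 4 else 1) for i in range(1, 7)})
        ren = Partition({f"h{i}": (0 if i <= 3 else 1) for i in range(1, 7)})
        cohort = flows([(f"z", f"h{i}", 10 * (7 - i)) for i in range(1, 7)])
        tr = pairs([("a", "b", "h1", "h2", 0), ("c", "d", "h5", "h6", 0)])
        return ref, ren, cohort, tr

    def test_identical_partitions_zero_everywhere(self):
        ref, _, cohort, tr = self.fixture()
        rc = reclassification(ref, ref, cohort, tr)
        assert (rc.per_region["hospital_pct"] == 0).all()
        assert rc.overall_hospital_pct == 0.0

    def test_hand_counted_fixture(self):
        ref, ren, cohort, tr = self.fixture()
        rc = reclassification(ref, ren, cohort, tr,
                              hospital_ids=[f"h{i}" for i in range(1, 7)])
        row = rc.per_region.set_index("reference_region").loc[0]
        # hub of R0 is h1 (transfer degree 1, highest volume); h4 moved
        assert row["hub"] == "h1"
        assert row["hospital_pct"] == 25.0
        assert rc.n_hospitals_reclassified == 1
        assert rc.overall_hospital_pct == percentage(1, 6)

    def test_hub_tie_breaks_on_volume_then_id(self):
        ref = Partition({"h1": 0, "h2": 0})
        ren = Partition({"h1": 0, "h2": 1})
        cohort = flows([("z", "h2", 5), ("z", "h1", 3)])
        rc = reclassification(ref, ren, cohort, pairs([]),
                              hospital_ids=["h1", "h2"])
        assert rc.per_region.iloc[0]["hub"] == "h2"  # larger volume

    def test_reference_region_without_hospitals_skipped(self):
        ref = Partition({"h1": 0, "h2": 0, "zX": 1})
        ren = Partition({"h1": 0, "h2": 0, "zX": 0})
        cohort = flows([("z", "h1", 2), ("z", "h2", 2)])
        rc = reclassification(ref, ren, cohort, pairs([]),
                              hospital_ids=["h1", "h2"])
        assert rc.skipped_regions == [1]


class TestWeightedIdentities:
    @pytest.mark.parametrize("seed", range(10))
    def test_boundary_crossings_counted_once(self, seed):
        rng = np.random.default_rng(seed)
        zips = [f"z{i}" for i in range(8)]
        hosps = [f"h{i}" for i in range(5)]
        part = Partition({u: int(rng.integers(0, 3)) for u in zips + hosps})
        rows = [(zips[rng.integers(0, 8)], hosps[rng.integers(0, 5)], 1)
                for _ in range(200)]
        cohort = flows(rows)
        li = localization_index(cohort, part)
        msi = market_share_index(cohort, part)
        residents = cohort.groupby(cohort["home_zip"].map(part.labels)).size()
        treated = cohort.groupby(cohort["facility"].map(part.labels)).size()
        out_total = sum(residents.get(r, 0) * (1 - li.loc[r])
                        for r in set(part.labels.values())
                        if residents.get(r, 0))
        in_total = sum(treated.get(r, 0) * msi.loc[r]
                       for r in set(part.labels.values())
                       if treated.get(r, 0))
        assert out_total == pytest.approx(in_total)


class TestCompareMethods:
    def test_self_comparison_is_identical_and_zero_reclassified(self, small_system):
        _, geo, _, cohort, transfers = small_system
        from flowregions import detect_rens

        res = detect_rens(cohort, transfers, geo, seed=0)
        report = compare_methods(cohort, transfers, geo,
                                 res.partition, res.partition)
        pd.testing.assert_frame_equal(report.ren_table, report.reference_table)
        assert report.reclassification.overall_hospital_pct == 0.0
        assert report.ren_modularity_phase1 == report.reference_modularity_phase1

    def test_summary_means_lie_within_ranges(self, small_system):
        _, geo, _, cohort, transfers = small_system
        from flowregions import detect_rens, generate_reference_partition

        cfg = small_system[0]
        res = detect_rens(cohort, transfers, geo, seed=0)
        ref = generate_reference_partition(geo, cfg)
        report = compare_methods(cohort, transfers, geo, res.partition, ref)
        summ = report.summary_frame()
        for _, row in summ.iterrows():
            assert row["ren_min"] - 1e-12 <= row["ren_mean"] <= row["ren_max"] + 1e-12
            assert row["ref_min"] - 1e-12 <= row["ref_mean"] <= row["ref_max"] + 1e-12

    def test_json_report_roundtrips(self, tmp_path, small_system):
        import json

        _, geo, _, cohort, transfers = small_system
        from flowregions import detect_rens

        res = detect_rens(cohort, transfers, geo, seed=0)
        report = compare_methods(cohort, transfers, geo,
                                 res.partition, res.partition)
        path = tmp_path / "report.json"
        report.to_json(path)
        d = json.loads(path.read_text())
        assert {"metrics", "modularity", "reclassification", "per_region"} <= set(d)

    def test_direction_on_benchmark(self, benchmark_runs):
        """Detected regions beat the perturbed reference on LI and MSI."""
        li_wins = sum(1 for r in benchmark_runs if r["ren_li"] > r["ref_li"])
        msi_wins = sum(1 for r in benchmark_runs if r["ren_msi"] < r["ref_msi"])
        q_wins = sum(1 for r in benchmark_runs if r["q_ren"] > r["q_ref"])
        assert li_wins >= 9 and msi_wins >= 9 and q_wins >= 9
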