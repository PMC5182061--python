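"""Adjacency construction, partner filtering and derived circuit statistics."""

import math

import numpy as np
import pytest

import connclust as cc
from connclust.cluster import ClusterResult

from conftest import make_connectome


class TestBuildAdjacency:
    def test_polyadic_counting(self):
        c = make_connectome(
            [(1, "a", "medial", None), (2, "b", "medial", None),
             (3, "c", "medial", None)],
            [(1, (0, 0, 0), 1, [2, 2, 3])],
        )
        adj = cc.build_adjacency(c, [1], [2, 3])
        assert adj.count(1, 2) == 2
        assert adj.count(1, 3) == 1

    def test_disconnected_sets_zero_matrix(self, toy_connectome):
        adj = cc.build_adjacency(toy_connectome, [3], [5, 6])
        assert adj.counts.sum() == 0

    def test_fixture_equals_hand_tally(self, toy_connectome):
        adj = cc.build_adjacency(
            toy_connectome, sorted(toy_connectome.skeletons),
            sorted(toy_connectome.skeletons),
        )
        assert adj.count(1, 3) == 2
        assert adj.count(3, 1) == 2
        assert adj.count(2, 4) == 1
        assert adj.count(7, 1) == 3
        assert adj.count(7, 2) == 2
        assert adj.count(8, 1) == 1
        assert adj.count(1, 8) == 1

    def test_sum_conservation(self, small_fixture):
        c, _ = small_fixture
        ids = sorted(c.skeletons)
        adj = cc.build_adjacency(c, ids, ids)
        assert adj.counts.sum() == sum(len(x.post_links) for x in c.connectors)

    def test_planted_edges_recovered(self, small_fixture):
        c, gt = small_fixture
        ids = sorted(c.skeletons)
        adj = cc.build_adjacency(c, ids, ids)
        for s, t, n in gt.planted_edges:
            assert adj.count(s, t) == n

    def test_unknown_id_rejected(self, toy_connectome):
        with pytest.raises(KeyError):
            cc.build_adjacency(toy_connectome, [1, 99], [2])


class TestFilterPartners:
    def test_hand_enumeration(self, toy_connectome):
        res = cc.filter_partners(toy_connectome, [1, 2], min_syn=3)
        # pair 3/4 qualifies through 3's four links; sensory 8 is exempt
        assert res.included == {3, 4, 8}
        assert res.excluded == {
            5: "below_threshold",
            6: "below_threshold",
            7: "no_homolog",
        }
        # focal presynaptic links: 2 to 3, 1 to 4, 2 to 5, 2 to 6, 1 to 8
        assert res.coverage_pre == pytest.approx(100.0 * 4 / 8)
        # focal postsynaptic links: 2 from 3, 5 from 7, 1 from 8
        assert res.coverage_post == pytest.approx(100.0 * 3 / 8)

    def test_monotone_in_min_syn(self, toy_connectome):
        included = []
        coverage = []
        for ms in range(0, 7):
            r = cc.filter_partners(toy_connectome, [1, 2], min_syn=ms)
            included.append(r.included)
            coverage.append((r.coverage_pre, r.coverage_post))
        for a, b in zip(included, included[1:]):
            assert b <= a
        for a, b in zip(coverage, coverage[1:]):
            assert b[0] <= a[0] + 1e-9 and b[1] <= a[1] + 1e-9

    def test_medial_partner_passes_homology(self, toy_connectome):
        res = cc.filter_partners(toy_connectome, [1, 2], min_syn=1,
                                 exempt_classes=())
        assert 8 in res.included  # medial, 2 links, no exemption needed

    def test_empty_candidates(self):
        c = make_connectome([(1, "a", "medial", None)], [])
        res = cc.filter_partners(c, [1])
        assert res.included == set() and res.excluded == {}
        assert res.coverage_pre == 100.0 and res.coverage_post == 100.0


class TestConnectionFraction:
    def test_simple_fraction(self):
        # 4 of 10 outgoing links onto the partner set
        posts = [2] * 4 + [3] * 6
        c = make_connectome(
            [(1, "a", "medial", None), (2, "b", "medial", None),
             (3, "c", "medial", None)],
            [(i + 1, (0, 0, 0), 1, [p]) for i, p in enumerate(posts)],
        )
        assert cc.connection_fraction(c, 1, {2}, "outgoing") == pytest.approx(40.0)
        assert cc.connection_fraction(c, 1, {2, 3}, "outgoing") == pytest.approx(100.0)

    def test_partition_sums_to_100(self, small_fixture):
        c, _ = small_fixture
        ids = sorted(c.skeletons)
        neuron = c.ids_by_class(["hugin"])[0]
        partners = [p for p in ids]
        half = set(partners[: len(partners) // 2])
        rest = set(partners) - half
        for direction in ("incoming", "outgoing"):
            total = cc.connection_fraction(c, neuron, half, direction) + \
                cc.connection_fraction(c, neuron, rest, direction)
            assert total == pytest.approx(100.0, abs=1e-9)

    def test_no_links_is_undefined(self):
        c = make_connectome([(1, "a", "medial", None)], [])
        assert math.isnan(cc.connection_fraction(c, 1, {1}, "incoming"))


class TestRegionFraction:
    def region_connectome(self):
        regions = {
            "SEZ": cc.RegionMask("SEZ", (((-1e4, -1e4, -1e4), (1e4, 1e4, 1e4)),)),
            "all": cc.RegionMask("all", (((-1e9,) * 3, (1e9,) * 3),)),
        }
        inside = [(0, 0, 0)] * 5
        outside = [(50000, 0, 0)] * 3
        connectors = [
            (i + 1, pos, 2, [1]) for i, pos in enumerate(inside + outside)
        ]
        return make_connectome(
            [(1, "a", "medial", None), (2, "b", "medial", None)],
            connectors, regions=regions,
        )

    def test_box_fraction(self):
        c = self.region_connectome()
        assert cc.region_fraction(c, 1, "SEZ", "incoming") == pytest.approx(62.5)
        assert cc.region_fraction(c, 1, "all", "incoming") == pytest.approx(100.0)

    def test_unknown_region(self):
        with pytest.raises(KeyError):
            cc.region_fraction(self.region_connectome(), 1, "nope", "incoming")

    def test_generator_regions_split_completely(self, small_fixture):
        c, _ = small_fixture
        neuron = c.ids_by_class(["hugin"])[0]
        total = cc.region_fraction(c, neuron, "SEZ", "incoming") + cc.region_fraction(
            c, neuron, "protocerebrum", "incoming"
        )
        # the two emitted boxes share only the boundary plane; jittered
        # positions fall on it with probability 0
        assert total == pytest.approx(100.0, abs=1e-9)


class TestClassConnectivity:
    def within_only_connectome(self):
        neurons = [
            (1, "hugin-PC", "left", 2),
            (2, "hugin-PC", "right", 1),
            (3, "hugin-RG", "left", 4),
            (4, "hugin-RG", "right", 3),
        ]
        connectors = [
            (1, (0, 0, 0), 1, [2]),
            (2, (0, 0, 0), 2, [1]),
            (3, (0, 0, 0), 3, [4]),
            (4, (0, 0, 0), 4, [3]),
        ]
        return make_connectome(neurons, connectors)

    def test_within_class_wiring_only(self):
        summary = cc.class_connectivity(self.within_only_connectome(), [1, 2, 3, 4])
        across = {
            k: v for k, v in summary.class_pair_totals.items() if k[0] != k[1]
        }
        assert across == {}
        assert summary.class_pair_totals[("hugin-PC", "hugin-PC")] == 2
        assert summary.same_class_percent.loc[1, "outgoing"] == pytest.approx(100.0)
        assert all(summary.bilateral_ok.values())

    def test_left_only_connection_flagged(self):
        neurons = [
            (1, "hugin-PC", "left", 2),
            (2, "hugin-PC", "right", 1),
            (3, "hugin-RG", "left", 4),
            (4, "hugin-RG", "right", 3),
        ]
        connectors = [(1, (0, 0, 0), 1, [3])]  # left-only, no mirror
        c = make_connectome(neurons, connectors)
        summary = cc.class_connectivity(c, [1, 2, 3, 4])
        assert summary.bilateral_ok[(1, 3)] is False

    def test_mirrored_generator_all_bilateral(self, small_fixture):
        c, _ = small_fixture
        sided = [
            i for i, s in c.skeletons.items() if s.side in ("left", "right")
        ]
        summary = cc.class_connectivity(c, sided)
        assert summary.bilateral_ok  # generator wires sided neurons
        assert all(summary.bilateral_ok.values())

    def test_side_label_exchange_invariance(self):
        c = self.within_only_connectome()
        summary_a = cc.class_connectivity(c, [1, 2, 3, 4])
        for skel in c.skeletons.values():
            skel.side = {"left": "right", "right": "left"}[skel.side]
        summary_b = cc.class_connectivity(c, [1, 2, 3, 4])
        assert summary_a.bilateral_ok == summary_b.bilateral_ok


class TestAxisDistribution:
    def test_single_point_mass(self):
        recs = [cc.SynapseRecord(1, i, "pre", (0.0, 5.0, 2.0)) for i in range(9)]
        edges, counts = cc.axis_distribution(recs, "dorsoventral", 4)
        assert counts.sum() == 9
        assert (counts > 0).sum() == 1

    def test_uniform_grid(self):
        recs = [
            cc.SynapseRecord(1, i, "pre", (0.0, 0.0, float(i)))
            for i in range(100)
        ]
        edges, counts = cc.axis_distribution(recs, "anteroposterior", 10)
        assert list(counts) == [10] * 10
        assert edges[0] == 0.0 and edges[-1] == 99.0

    def test_gaussian_cloud_mean_within_3_se(self, full_fixture):
        c, gt = full_fixture
        sensory = sorted(gt.group_of)
        group0 = [s for s in sensory if gt.group_of[s] == 0]
        recs = [r for s in group0 for r in c.synapse_records(s) if r.sign == "pre"]
        edges, counts = cc.axis_distribution(recs, "dorsoventral", 30)
        centers = (edges[:-1] + edges[1:]) / 2
        hist_mean = float(np.average(centers, weights=counts))
        sd = gt.config.cloud_sd
        se = sd / math.sqrt(len(recs))
        true_mean = gt.cloud_centers[0][1]
        # histogram binning adds at most half a bin width of extra error
        half_bin = float(edges[1] - edges[0]) / 2
        assert abs(hist_mean - true_mean) <= 3 * se + half_bin

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cc.axis_distribution([], "dorsoventral", 5)


class TestDcvProximity:
    def dcv_connectome(self, n_with=9, n_without=1, radius=450.0):
        positions = [(float(2000 * i), 0.0, 0.0) for i in range(n_with + n_without)]
        connectors = [(i + 1, p, 1, [2]) for i, p in enumerate(positions)]
        dcvs = [(1, (p[0] + radius, 0.0, 0.0)) for p in positions[:n_with]]
        return make_connectome(
            [(1, "a", "medial", None), (2, "b", "medial", None)],
            connectors, dcvs=dcvs,
        )

    def test_nine_of_ten(self):
        c = self.dcv_connectome()
        assert cc.dcv_proximity(c, 1, radius=450.0) == pytest.approx(90.0)

    def test_colocated_everywhere(self):
        c = self.dcv_connectome(n_with=10, n_without=0)
        assert cc.dcv_proximity(c, 1, radius=450.0) == pytest.approx(100.0)

    def test_no_dcvs_zero(self):
        c = make_connectome(
            [(1, "a", "medial", None), (2, "b", "medial", None)],
            [(1, (0, 0, 0), 1, [2])],
        )
        assert cc.dcv_proximity(c, 1) == 0.0

    def test_no_presites_undefined(self):
        c = self.dcv_connectome()
        assert math.isnan(cc.dcv_proximity(c, 2))

    def test_monotone_in_radius(self, small_fixture):
        c, _ = small_fixture
        neuron = c.ids_by_class(["hugin"])[0]
        radii = [50, 200, 450, 1000, 5000]
        vals = [cc.dcv_proximity(c, neuron, r) for r in radii]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestSharedInputProfile:
    def test_planted_shared_inputs(self, small_fixture):
        c, gt = small_fixture
        reference = c.ids_by_class(["hugin-PC"])
        groups = {}
        for label in gt.config.target_block_labels:
            groups[label] = [t for t, l in gt.block_of.items() if l == label]
        table = cc.shared_input_profile(c, reference, groups)
        for label, partners in gt.shared_input_partners.items():
            for q in partners:
                homolog = c.homolog_of(q)
                for p in (q, homolog):
                    assert p in table.index
                    assert table.loc[p, "links_to_reference"] > 0
                    assert bool(table.loc[p, f"shared_{label}"])

    def test_group_only_partner_has_zero_elsewhere(self):
        neurons = [
            (1, "ref", "medial", None),
            (2, "up", "medial", None),
            (3, "g1", "medial", None),
            (4, "g2", "medial", None),
        ]
        connectors = [
            (1, (0, 0, 0), 2, [1]),  # partner feeds reference
            (2, (0, 0, 0), 2, [3]),  # and group g1 only
        ]
        c = make_connectome(neurons, connectors)
        table = cc.shared_input_profile(c, [1], {"g1": [3], "g2": [4]})
        assert table.loc[2, "links_to_g1"] == 1
        assert table.loc[2, "links_to_g2"] == 0
        assert bool(table.loc[2, "shared_g1"]) and not bool(table.loc[2, "shared_g2"])

    def test_overlapping_groups_rejected(self, toy_connectome):
        with pytest.raises(ValueError, match="overlap"):
            cc.shared_input_profile(toy_connectome, [1], {"a": [3], "b": [3, 4]})


class TestAssignIdentities:
    def make_cluster(self, sizes):
        assignment = {}
        skid = 0
        for ci, n in enumerate(sizes, start=1):
            for _ in range(n):
                skid += 1
                assignment[skid] = ci
        return ClusterResult(assignment, cut_score=0.4, n_clusters=len(sizes))

    def test_unique_size_assignment(self):
        cut = self.make_cluster([3, 2, 7])
        mapping = cc.assign_identities(cut, {"DH44": 3, "DMS": 2, "IPC": 7})
        labels = [mapping[i] for i in sorted(mapping)]
        assert labels == ["DH44"] * 3 + ["DMS"] * 2 + ["IPC"] * 7

    def test_size_mismatch_reports_both(self):
        cut = self.make_cluster([4, 8])
        with pytest.raises(ValueError, match=r"\[4, 8\].*\[2, 3, 7\]"):
            cc.assign_identities(cut, {"DH44": 3, "DMS": 2, "IPC": 7})

    def test_ambiguous_equal_sizes(self):
        cut = self.make_cluster([2, 2])
        with pytest.raises(ValueError, match="ambiguous"):
            cc.assign_identities(cut, {"A": 2, "B": 2})
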