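"""Distance-resolved statistics against brute-force and networkx oracles."""

import networkx as nx
import numpy as np
import pytest

from geosocial.fixtures import planted_p1_slope, planted_reciprocity, planted_triangles
from geosocial.geography import InputError, Location
from geosocial.metrics import (
    DistanceBinning,
    clustering_curve,
    default_binning,
    degree_distribution,
    disparity_distribution,
    link_probability_curve,
    local_clustering,
    overlap_curve,
    reciprocity_curve,
    scalar_summary,
    social_overlap,
    triad_census,
    triangle_disparity,
    triangles,
)
from geosocial.network import DirectedGeoNetwork

from conftest import (
    brute_overlap,
    brute_pair_distances,
    brute_triads,
    brute_triangles,
    brute_undirected_adj,
    random_geo_digraph,
)

WIDE = DistanceBinning.log_bins(0.5, 25000.0, 40)


def equatorial_net(lons, edges):
    net = DirectedGeoNetwork({i: Location(0.0, lon) for i, lon in enumerate(lons)})
    for u, v in edges:
        net.add_edge(u, v)
    return net


class TestLinkProbability:
    def test_three_collinear_nodes(self):
        net = equatorial_net([0.0, 1.0, 2.0], [(0, 1)])
        curve = link_probability_curve(net, WIDE)
        b1 = int(WIDE.assign(np.array([111.2]))[0])
        b2 = int(WIDE.assign(np.array([222.4]))[0])
        assert curve.values[b1] == 0.5  # 1 linked of 2 pairs at ~111 km
        assert curve.values[b2] == 0.0

    def test_complete_graph_all_ones(self):
        net = equatorial_net(
            [0.0, 0.5, 1.3, 2.9], [(u, v) for u in range(4) for v in range(4) if u != v]
        )
        curve = link_probability_curve(net, WIDE)
        assert np.all(curve.values[curve.defined] == 1.0)

    def test_pair_counts_are_exhaustive(self, small_random_net):
        curve = link_probability_curve(small_random_net, WIDE)
        n = small_random_net.n_nodes
        assert curve.counts.sum() == n * (n - 1) // 2

    def test_matches_brute_force(self, small_random_net):
        net = small_random_net
        curve = link_probability_curve(net, WIDE)
        dists = brute_pair_distances(net)
        adj = brute_undirected_adj(net)
        total = np.zeros(WIDE.n_bins)
        linked = np.zeros(WIDE.n_bins)
        for (a, b), d in dists.items():
            bin_ = int(WIDE.assign(np.array([d]))[0])
            total[bin_] += 1
            if b in adj[a]:
                linked[bin_] += 1
        expect = np.where(total > 0, linked / np.maximum(total, 1), np.nan)
        np.testing.assert_allclose(curve.values, expect, equal_nan=True)

    def test_monte_carlo_close_to_exact(self):
        net = random_geo_digraph(400, 0.02, 9)
        exact = link_probability_curve(net, WIDE)
        mc = link_probability_curve(net, WIDE, pair_budget=2_000_000, seed=0,
                                    exact_threshold=10)
        both = exact.defined & mc.defined & (exact.counts > 50)
        assert np.max(np.abs(exact.values[both] - mc.values[both])) < 0.01


class TestDegreeDistribution:
    def test_mutual_edges_count_once(self):
        net = equatorial_net([0, 1, 2], [(0, 1), (1, 0), (0, 2)])
        ks, counts = degree_distribution(net, symmetrize=True)
        assert dict(zip(ks, counts)) == {0: 0, 1: 2, 2: 1}

    def test_histogram_sums_to_n(self, small_random_net):
        _, counts = degree_distribution(small_random_net)
        assert counts.sum() == small_random_net.n_nodes

    def test_empty_network_and_star(self):
        net = equatorial_net([0, 1, 2], [])
        ks, counts = degree_distribution(net)
        assert counts[0] == 3
        star = equatorial_net(list(np.arange(6) * 0.3), [(0, i) for i in range(1, 6)])
        ks, counts = degree_distribution(star)
        assert counts[5] == 1 and counts[1] == 5


class TestReciprocity:
    def test_boundary_values(self):
        mutual = equatorial_net([0.0, 1.0], [(0, 1), (1, 0)])
        one_way = equatorial_net([0.0, 1.0], [(0, 1)])
        c1 = reciprocity_curve(mutual, WIDE)
        c2 = reciprocity_curve(one_way, WIDE)
        assert np.nansum(c1.values) == 1.0
        assert np.nansum(c2.values) == 0.0

    def test_planted_per_scale_reciprocity_recovered(self):
        net, planted = planted_reciprocity({10.0: 0.8, 1000.0: 0.2})
        curve = reciprocity_curve(net, WIDE)
        for scale, frac in planted.items():
            b = int(WIDE.assign(np.array([scale]))[0])
            assert curve.values[b] == pytest.approx(frac, abs=1e-12)

    def test_global_reciprocity_matches_networkx(self, small_random_net):
        s = scalar_summary(small_random_net)
        g = small_random_net.to_networkx()
        assert s.global_reciprocity == pytest.approx(nx.overall_reciprocity(g))


class TestSocialOverlap:
    def test_stated_boundary_cases(self):
        # share all friends -> 1
        net = equatorial_net([0, 1, 2], [(0, 1), (0, 2), (1, 2)])
        assert social_overlap(net, 0, 1) == 1.0
        # no shared friends but another neighbor exists -> 0
        net2 = equatorial_net([0, 1, 2], [(0, 1), (1, 2)])
        assert social_overlap(net2, 0, 1) == 0.0

    def test_half_overlap(self):
        # Gamma_0 = {1, 2, 3}, Gamma_1 = {0, 2}
        net = equatorial_net([0, 1, 2, 3], [(0, 1), (0, 2), (0, 3), (1, 2)])
        assert social_overlap(net, 0, 1) == 0.5

    def test_isolated_dyad_is_undefined(self):
        net = equatorial_net([0, 1], [(0, 1)])
        assert social_overlap(net, 0, 1) is None

    def test_disconnected_pair_rejected(self):
        net = equatorial_net([0, 1, 2], [(0, 1)])
        with pytest.raises(InputError):
            social_overlap(net, 0, 2)

    def test_curve_matches_brute_force(self, small_random_net):
        net = small_random_net
        curve = overlap_curve(net, WIDE)
        adj = brute_undirected_adj(net)
        sums = np.zeros(WIDE.n_bins)
        total = np.zeros(WIDE.n_bins)
        for (a, b), d in brute_pair_distances(net).items():
            if b not in adj[a]:
                continue
            ov = brute_overlap(net, a, b)
            if ov is None:
                continue
            bin_ = int(WIDE.assign(np.array([d]))[0])
            sums[bin_] += ov
            total[bin_] += 1
        expect = np.where(total > 0, sums / np.maximum(total, 1), np.nan)
        np.testing.assert_allclose(curve.values, expect, equal_nan=True)

    def test_complete_graph_full_overlap(self):
        net = equatorial_net(
            [0.0, 0.01, 0.02, 0.03],
            [(u, v) for u in range(4) for v in range(4) if u != v],
        )
        curve = overlap_curve(net, WIDE)
        assert np.all(curve.values[curve.defined] == 1.0)


class TestClustering:
    def test_triangle_and_path(self):
        tri = equatorial_net([0.0, 1.0, 2.0], [(0, 1), (1, 2), (0, 2)])
        c = clustering_curve(tri, WIDE)
        assert np.all(c.values[c.defined] == 1.0)
        path = equatorial_net([0.0, 1.0, 2.0], [(0, 1), (1, 2)])
        assert np.nansum(clustering_curve(path, WIDE).values) == 0.0

    def test_triangle_yields_three_closed_triads(self):
        tri = equatorial_net([0.0, 1.0, 2.0], [(0, 1), (1, 2), (0, 2)])
        records = list(triad_census(tri))
        assert len(records) == 3
        assert all(closed for *_, closed in records)

    def test_matches_brute_force(self, small_random_net):
        net = small_random_net
        mine = sorted(
            (repr(c), repr(min(i, k, key=repr)), repr(max(i, k, key=repr)), closed)
            for (c, i, k, _, closed) in triad_census(net)
        )
        brute = sorted(
            (repr(c), repr(min(i, k, key=repr)), repr(max(i, k, key=repr)), closed)
            for (c, i, k, closed) in brute_triads(net)
        )
        assert mine == brute

    def test_planted_scales(self):
        net, expected = planted_triangles(scales_km=(10.0, 1000.0))
        curve = clustering_curve(net, WIDE)
        for scale, c_expected in expected.items():
            b = int(WIDE.assign(np.array([scale]))[0])
            assert curve.values[b] == pytest.approx(c_expected)

    def test_weighted_mean_equals_global_clustering(self, small_random_net):
        curve = clustering_curve(small_random_net, WIDE)
        s = scalar_summary(small_random_net)
        assert curve.weighted_mean() == pytest.approx(s.global_clustering, abs=1e-14)

    def test_global_clustering_matches_networkx_transitivity(self, small_random_net):
        g = small_random_net.to_networkx().to_undirected()
        s = scalar_summary(small_random_net)
        assert s.global_clustering == pytest.approx(nx.transitivity(g))

    def test_local_clustering_matches_networkx(self, small_random_net):
        g = small_random_net.to_networkx().to_undirected()
        nxc = nx.clustering(g)
        for i in small_random_net.nodes():
            mine = local_clustering(small_random_net, i)
            if mine is not None:
                assert mine == pytest.approx(nxc[i])


class TestDisparity:
    @pytest.mark.parametrize(
        "sides, expected",
        [
            ((100.0, 100.0, 100.0), 0.0),
            ((100.0, 100.0, 200.0), 0.5),
            ((100.0, 100.0, 1e-9), pytest.approx(1.0, abs=1e-6)),
        ],
    )
    def test_formula(self, sides, expected):
        assert triangle_disparity(*sides) == expected

    def test_triangle_enumeration_matches_brute_force(self, small_random_net):
        mine = sorted(tuple(sorted(t, key=repr)) for t in triangles(small_random_net))
        brute = sorted(tuple(sorted(t, key=repr)) for t in brute_triangles(small_random_net))
        assert mine == brute

    def test_histogram_normalized(self, small_random_net):
        _, probs, counts = disparity_distribution(small_random_net)
        if counts.sum() > 0:
            assert probs.sum() == pytest.approx(1.0)

    def test_stretched_isosceles_lands_high(self):
        # two nearly co-located users plus one distant: D close to 1
        net = DirectedGeoNetwork(
            {0: Location(0, 0), 1: Location(0, 0.001), 2: Location(0, 5.0)}
        )
        for u, v in [(0, 1), (1, 2), (0, 2)]:
            net.add_edge(u, v)
        _, probs, _ = disparity_distribution(net, n_bins=10)
        assert probs[-1] == 1.0


class TestScalarSummary:
    def test_isolated_nodes_excluded_from_connected_count(self):
        net = equatorial_net(list(np.arange(10) * 0.5), [(0, 1), (2, 3), (4, 5)])
        assert scalar_summary(net).n_connected == 6

    def test_triangle_with_isolate(self):
        net = equatorial_net([0.0, 1.0, 2.0, 50.0], [(0, 1), (1, 2), (0, 2)])
        assert scalar_summary(net).mean_local_clustering == 1.0

    def test_mixed_reciprocity(self):
        net = equatorial_net([0, 1, 2], [(0, 1), (1, 0), (0, 2)])
        assert scalar_summary(net).global_reciprocity == pytest.approx(2 / 3)


class TestCurveHygiene:
    def test_all_probability_values_within_unit_interval(self, small_random_net):
        for curve in (
            link_probability_curve(small_random_net, WIDE),
            reciprocity_curve(small_random_net, WIDE),
            overlap_curve(small_random_net, WIDE),
            clustering_curve(small_random_net, WIDE),
        ):
            v = curve.values[curve.defined]
            assert np.all((v >= 0.0) & (v <= 1.0))

    def test_degree_probabilities_sum_to_one(self, small_random_net):
        _, counts = degree_distribution(small_random_net)
        assert (counts / counts.sum()).sum() == pytest.approx(1.0)

    def test_binning_validation(self):
        with pytest.raises(InputError):
            DistanceBinning(np.array([0.0, 1.0]))
        with pytest.raises(InputError):
            DistanceBinning(np.array([2.0, 1.0]))

    def test_p1_slope_recovery_on_planted_network(self):
        net, slope = planted_p1_slope(n_agents=800, slope=1.0, seed=3)
        curve = link_probability_curve(net, default_binning(net))
        m = curve.defined & (curve.counts > 300) & (curve.binning.centers() > 8.0)
        x = np.log(curve.binning.centers()[m])
        y = np.log(np.maximum(curve.values[m], 1e-12))
        fit = np.polyfit(x, y, 1)[0]
        assert fit == pytest.approx(-slope, abs=0.1)
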