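"""Hub, locality, centrality, density, recovery and robustness metrics."""

import numpy as np
import pytest

from connectopt import Digraph, Partition, PositionTable, SpatialNetwork
from connectopt import random_connected_digraph
from connectopt.metrics import (
    degree_preserving_random,
    degree_density_correlation,
    geographical_centrality,
    hub_removal_impact,
    hub_zscores,
    locality,
    match_partitions,
    neighborhood_density,
    recovery_rate,
    shuffle_significance,
    shuffled_match_null,
    spatial_clusters,
)
from connectopt.synth import ring_layout, two_cluster_layout, \
    head_cord_tail_layout

from oracles import match_mismatch_bruteforce


def bidirectional_star(n):
    edges = [(0, i) for i in range(1, n)] + [(i, 0) for i in range(1, n)]
    return Digraph.from_edges(edges, n)


class TestHubZscores:
    def test_regular_graph_has_no_hubs(self, cycle4):
        rep = hub_zscores(cycle4)
        assert rep.n_hub == 0
        assert np.all(rep.frame["z"] == 0)

    def test_star_center_z_closed_form(self):
        # star on 21 nodes: center degree 2(n-1), leaves 2; the center's
        # z-score works out to sqrt(n-1)
        rep = hub_zscores(bidirectional_star(21))
        assert rep.frame.loc[0, "z"] == pytest.approx(np.sqrt(20))
        assert rep.n_hub == 1 and rep.hub_indices.tolist() == [0]
        assert rep.k_hub == 40

    def test_in_out_variants(self):
        # every node sends exactly one link (all into node 0): out-degrees
        # are uniform, only the in-degree variant flags a hub
        g = Digraph.from_edges([(i, 0) for i in range(1, 21)] + [(0, 1)], 21)
        assert hub_zscores(g, mode="in").n_hub == 1
        assert hub_zscores(g, mode="out").n_hub == 0

    def test_mean_in_degree_equals_density(self):
        g = random_connected_digraph(50, 400, np.random.default_rng(0))
        rep = hub_zscores(g, mode="in")
        assert rep.frame["in_degree"].mean() == pytest.approx(400 / 50)


class TestLocality:
    def test_nearest_neighbour_ring_is_fully_local(self):
        lay = ring_layout(10)
        edges = [(i, (i + 1) % 10) for i in range(10)] \
            + [(i, (i - 1) % 10) for i in range(10)]
        net = SpatialNetwork(Digraph.from_edges(edges, 10), lay)
        rep = locality(net)
        assert rep.F == pytest.approx(1.0)
        assert np.allclose(rep.frame["F_i"].dropna(), 1.0)

    def test_collinear_long_link(self):
        pos = PositionTable(("a", "b", "c", "d"),
                            np.array([[0.0], [1.0], [2.0], [10.0]]))
        net = SpatialNetwork(Digraph.from_edges([(0, 3)], 4), pos)
        rep = locality(net)
        assert rep.frame.loc[0, "F_i"] == pytest.approx(0.1)

    def test_isolated_node_excluded(self):
        pos = PositionTable(("a", "b", "c"),
                            np.array([[0.0, 0], [1.0, 0], [5.0, 0]]))
        net = SpatialNetwork(Digraph.from_edges([(0, 1), (1, 0)], 3), pos)
        rep = locality(net)
        assert np.isnan(rep.frame.loc[2, "F_i"])
        assert rep.F == pytest.approx(1.0)


class TestGeographicalCentrality:
    def test_uniform_ring_all_tied(self):
        net = SpatialNetwork(Digraph(np.zeros((8, 8), bool)), ring_layout(8))
        df = geographical_centrality(net)
        assert (df["rank"] == 1).all() and df["tied"].all()

    def test_collinear_middle_most_central(self):
        pos = PositionTable(("a", "b", "c"), np.array([[0.0], [1.0], [5.0]]))
        net = SpatialNetwork(Digraph(np.zeros((3, 3), bool)), pos)
        df = geographical_centrality(net).set_index("node")
        assert df.loc[1, "rank"] == 1 and df.loc[1, "D"] == 5.0

    def test_subset_scope(self):
        pos = PositionTable(tuple("abcd"),
                            np.array([[0.0], [1.0], [10.0], [11.0]]))
        net = SpatialNetwork(Digraph(np.zeros((4, 4), bool)), pos)
        df = geographical_centrality(net, subset=[2, 3])
        assert set(df["node"]) == {2, 3}
        with pytest.raises(ValueError):
            geographical_centrality(net, subset=[2])

    def test_global_center_in_denser_cluster(self):
        lay, labels = two_cluster_layout(60, frac_a=0.75, separation=20.0,
                                         spreads=(1.0, 1.0), seed=0)
        net = SpatialNetwork(Digraph(np.zeros((60, 60), bool)), lay)
        top = geographical_centrality(net).iloc[0]["node"]
        assert labels.labels[int(top)] == 1   # the 75% cluster


class TestNeighborhoodDensity:
    def test_isolated_pair_disc_density(self):
        pos = PositionTable(("a", "b"), np.array([[0.0, 0.0], [1.0, 0.0]]))
        net = SpatialNetwork(Digraph(np.zeros((2, 2), bool)), pos)
        prof = neighborhood_density(net, [1.0])
        assert np.allclose(prof.rho[:, 0], 1.0 / np.pi)

    def test_full_radius_counts_everyone(self):
        lay, _ = two_cluster_layout(30, seed=1)
        net = SpatialNetwork(Digraph(np.zeros((30, 30), bool)), lay)
        prof = neighborhood_density(net, [0.2, 1.0])
        assert np.all(prof.counts[:, -1] == 29)
        assert np.all(np.diff(prof.counts, axis=1) >= 0)  # monotone in r

    def test_dimension_guard(self):
        pos = PositionTable(("a", "b"), np.array([[0.0], [1.0]]))
        net = SpatialNetwork(Digraph(np.zeros((2, 2), bool)), pos)
        with pytest.raises(ValueError, match="2-D or 3-D"):
            neighborhood_density(net, [1.0])

    def test_uniform_grid_interior_roughly_constant(self):
        xs, ys = np.meshgrid(np.arange(6.0), np.arange(6.0))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        pos = PositionTable(tuple(f"g{i}" for i in range(36)), coords)
        net = SpatialNetwork(Digraph(np.zeros((36, 36), bool)), pos)
        prof = neighborhood_density(net, [0.25])
        interior = [i for i, (x, y) in enumerate(coords)
                    if 1 <= x <= 4 and 1 <= y <= 4]
        rho = prof.rho[interior, 0]
        assert rho.std() / rho.mean() < 0.1


class TestDegreeDensityCorrelation:
    def test_proportional_vectors_correlate_fully(self):
        lay, _ = two_cluster_layout(40, seed=2)
        net0 = SpatialNetwork(Digraph(np.zeros((40, 40), bool)), lay)
        prof = neighborhood_density(net0, [0.3])
        rho = prof.rho[:, 0]
        order = np.minimum(np.argsort(np.argsort(rho)), 38)
        # wire out-degree monotone in density rank
        adj = np.zeros((40, 40), bool)
        for i in range(40):
            for t in range(1, order[i] + 2):
                adj[i, (i + t) % 40] = True
        net = net0.with_graph(Digraph(adj))
        rep = degree_density_correlation(net, [0.3], mode="out",
                                         surrogate_reps=50)
        assert rep.frame["corr"].iloc[0] > 0.9
        assert rep.frame["significant"].iloc[0]

    def test_shuffle_band_calibration_light(self):
        rng = np.random.default_rng(0)
        hits = 0
        trials = 120
        for t in range(trials):
            x, y = rng.normal(size=(2, 80))
            c, band = shuffle_significance(x, y, reps=60, seed=t)
            hits += abs(c) > band
        assert 0.01 <= hits / trials <= 0.12   # ~5% nominal


class TestRecoveryRate:
    def test_identity_and_complement(self):
        g = random_connected_digraph(8, 20, np.random.default_rng(0))
        assert recovery_rate(g, g).R == 1.0
        comp = Digraph(~g.adjacency & ~np.eye(8, dtype=bool))
        assert recovery_rate(g, comp).R == 0.0

    def test_hand_constructed_counts(self):
        n = 5
        ref = np.zeros((n, n), bool)
        ones = [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (4, 0), (1, 3), (2, 0)]
        for ij in ones:
            ref[ij] = True                      # N1 = 8, N0 = 12
        cand = ref.copy()
        cand[0, 1] = cand[0, 2] = False         # lose 2 ones -> N11 = 6
        cand[1, 0] = cand[3, 0] = cand[4, 1] = True   # 3 zeros now 1 -> N00 = 9
        rep = recovery_rate(Digraph(ref), Digraph(cand))
        assert (rep.N1, rep.N0, rep.N11, rep.N00) == (8, 12, 6, 9)
        assert rep.R1 == rep.R0 == rep.R == 0.75

    def test_symmetric_in_agreement(self):
        rng = np.random.default_rng(1)
        a = Digraph((rng.random((7, 7)) < 0.4) & ~np.eye(7, dtype=bool))
        b = Digraph((rng.random((7, 7)) < 0.4) & ~np.eye(7, dtype=bool))
        assert recovery_rate(a, b).N11 == recovery_rate(b, a).N11
        assert recovery_rate(a, b).N00 == recovery_rate(b, a).N00

    def test_empty_restriction_flagged(self):
        g = random_connected_digraph(6, 12, np.random.default_rng(2))
        empty = Digraph(np.zeros((6, 6), bool))
        rep = recovery_rate(empty, g)
        assert rep.flagged and np.isnan(rep.R)

    def test_distance_bin_restriction(self):
        lay = ring_layout(10)
        g = random_connected_digraph(10, 30, np.random.default_rng(3))
        net = SpatialNetwork(g, lay)
        rep_all = recovery_rate(g, g)
        rep_bin = recovery_rate(g, g, distance_bin=(0.0, 1.0), spatial=net)
        assert rep_bin.N1 + rep_bin.N0 < rep_all.N1 + rep_all.N0
        assert rep_bin.R == 1.0


class TestDegreePreservingNull:
    def test_degree_sequences_exactly_preserved(self):
        g = random_connected_digraph(20, 80, np.random.default_rng(0))
        for b in degree_preserving_random(g, reps=3, rng=1):
            np.testing.assert_array_equal(b.in_degree, g.in_degree)
            np.testing.assert_array_equal(b.out_degree, g.out_degree)
            assert b.K == g.K

    def test_three_cycle_is_swap_rigid(self):
        g = Digraph.from_edges([(0, 1), (1, 2), (2, 0)], 3)
        b = degree_preserving_random(g, reps=1, rng=0)[0]
        np.testing.assert_array_equal(b.adjacency, g.adjacency)

    def test_randomization_changes_links_reproducibly(self):
        g = random_connected_digraph(20, 80, np.random.default_rng(0))
        b1 = degree_preserving_random(g, reps=1, rng=7)[0]
        b2 = degree_preserving_random(g, reps=1, rng=7)[0]
        np.testing.assert_array_equal(b1.adjacency, b2.adjacency)
        assert (b1.adjacency != g.adjacency).sum() > 0


class TestPartitionMatching:
    def test_identical_partitions(self):
        p = Partition(np.array([1, 1, 2, 2, 3]))
        rep = match_partitions(p, p)
        assert rep.mismatch_rate == 0.0 and len(rep.matched) == 5

    def test_two_b_groups_inside_one_a_group(self):
        # A: {0..3}=1, {4..7}=2, {8..9}=3 ; B splits A1 in two and strays
        A = Partition(np.array([1, 1, 1, 1, 2, 2, 2, 2, 3, 3]))
        B = Partition(np.array([1, 1, 2, 2, 3, 3, 3, 4, 4, 4]))
        rep = match_partitions(A, B)
        assert rep.mapping[1] == 1 and rep.mapping[2] == 1
        # B3={4,5,6}->A2 fully matched; B4={7,8,9}: 8,9 in A3, 7 mismatched
        assert rep.mapping[4] == 3
        assert rep.mismatched.tolist() == [7]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_per_node_check(self, seed):
        rng = np.random.default_rng(seed)
        a = Partition.from_labels(rng.integers(0, 3, size=8))
        b = Partition.from_labels(rng.integers(0, 4, size=8))
        rep = match_partitions(a, b)
        assert sorted(rep.mismatched.tolist()) == \
            match_mismatch_bruteforce(a.labels, b.labels)

    def test_shuffled_null_singletons_zero(self):
        p = Partition(np.arange(1, 9))
        assert shuffled_match_null(p, p, reps=20, seed=0) == 0.0

    def test_shuffled_null_two_halves_half(self):
        n = 200
        p = Partition(np.array([1] * (n // 2) + [2] * (n // 2)))
        null = shuffled_match_null(p, p, reps=300, seed=0)
        assert null == pytest.approx(0.5, abs=0.03)

    def test_shuffled_null_monte_carlo_stable(self):
        rng = np.random.default_rng(0)
        a = Partition.from_labels(rng.integers(0, 3, size=90))
        b = Partition.from_labels(rng.integers(0, 4, size=90))
        e1 = shuffled_match_null(a, b, reps=500, seed=1)
        e2 = shuffled_match_null(a, b, reps=500, seed=2)
        assert abs(e1 - e2) < 0.02


class TestSpatialClusters:
    def test_well_separated_blobs_all_methods(self):
        lay, truth = two_cluster_layout(40, separation=40.0,
                                        spreads=(1.0, 1.0), seed=0)
        from connectopt.metrics import CLUSTER_METHODS

        for method in CLUSTER_METHODS:
            part = spatial_clusters(lay, 2, method)
            rep = match_partitions(truth, part)
            assert rep.mismatch_rate == 0.0, method

    def test_singletons_and_bounds(self):
        lay = ring_layout(5)
        assert spatial_clusters(lay, 5, "ward").k == 5
        with pytest.raises(ValueError):
            spatial_clusters(lay, 6, "ward")
        with pytest.raises(ValueError, match="unknown clustering"):
            spatial_clusters(lay, 2, "nope")

    def test_head_cord_tail_recovered_by_ward(self):
        lay, truth = head_cord_tail_layout(90, seed=0)
        part = spatial_clusters(lay, 3, "ward")
        rep = match_partitions(truth, part)
        assert rep.mismatch_rate < 0.1


class TestHubRemoval:
    def test_complete_digraph_unchanged(self):
        g = Digraph(~np.eye(6, dtype=bool))
        rep = hub_removal_impact(g)
        assert rep.ratio == 1.0 and rep.unreachable_pairs == 0

    def test_star_removal_disconnects(self):
        rep = hub_removal_impact(bidirectional_star(8))
        assert rep.removed == 0
        assert np.isinf(rep.ratio) and rep.unreachable_pairs > 0

    def test_tiny_graph_guard(self):
        g = Digraph.from_edges([(0, 1), (1, 0)], 2)
        with pytest.raises(ValueError):
            hub_removal_impact(g)

    def test_hub_plus_ring_ratio_exceeds_one(self):
        # ring lattice + bidirectional hub: removal forces long ring paths
        n = 20
        edges = [(i, (i + 1) % n) for i in range(1, n)] \
            + [(i, (i - 1) % n) for i in range(1, n)] \
            + [(0, i) for i in range(1, n)] + [(i, 0) for i in range(1, n)]
        edges = list({e for e in edges if e[0] != e[1]})
        g = Digraph.from_edges(edges, n)
        rep = hub_removal_impact(g)
        assert rep.removed == 0
        assert rep.ratio > 1.5
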