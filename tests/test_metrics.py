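"""Network statistics against closed forms and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rewirenet import (
    Partition,
    average_path_length,
    degree_assortativity,
    edge_density,
    global_clustering,
    metric_record,
    modularity,
    normalize_metrics,
    rich_club_curve,
    rich_club_profile,
    small_world_index,
    subgraph,
)
from rewirenet.initialization import random_graph
from rewirenet.metrics import scope_pair_count

from conftest import complete_graph, path_graph, star_graph, triangle_plus_pendant


class TestEdgeDensity:
    def test_complete_triangle(self):
        assert edge_density(complete_graph(3)) == 1.0

    def test_reference_configuration(self, rng):
        adj = random_graph(300, 5200, rng)
        assert edge_density(adj) == pytest.approx(10400 / (300 * 299))

    def test_empty_graph(self):
        assert edge_density(np.zeros((10, 10))) == 0.0


class TestClustering:
    def test_complete_graph_fully_clustered(self):
        assert global_clustering(complete_graph(4)) == 1.0

    def test_star_has_no_triangles(self):
        assert global_clustering(star_graph(3)) == 0.0

    def test_triangle_plus_pendant(self):
        assert global_clustering(triangle_plus_pendant()) == pytest.approx(0.6)

    def test_trace_formula_equals_triplet_enumeration(self, rng):
        """Exact agreement with brute-force closed/connected triplet counts
        on random 12-node graphs."""
        for _ in range(50):
            m = int(rng.integers(3, 40))
            adj = random_graph(12, m, rng)
            closed = 0
            connected = 0
            for trio in itertools.combinations(range(12), 3):
                for center in trio:
                    a, b = [v for v in trio if v != center]
                    if adj[center, a] and adj[center, b]:
                        connected += 1
                        if adj[a, b]:
                            closed += 1
            expected = closed / connected if connected else 0.0
            assert global_clustering(adj) == pytest.approx(expected, abs=1e-12)


class TestPathLength:
    def test_complete_graph(self):
        assert average_path_length(complete_graph(3)) == 1.0

    def test_path_graph(self):
        assert average_path_length(path_graph(3)) == pytest.approx(8 / 6)

    def test_disconnected_pairs_contribute_zero(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        assert average_path_length(adj) == pytest.approx(2 / 6)

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        for _ in range(20):
            adj = random_graph(10, int(rng.integers(0, 20)), rng)
            g = nx.from_numpy_array(adj)
            total = 0
            for u, lengths in nx.all_pairs_shortest_path_length(g):
                for v, d in lengths.items():
                    if u != v:
                        total += d
            assert average_path_length(adj) == pytest.approx(total / 90, abs=1e-12)


class TestSmallWorld:
    def test_complete_graph_unity(self):
        assert small_world_index(1.0, 1.0) == 1.0

    def test_arithmetic(self):
        assert small_world_index(0.6, 1.25) == pytest.approx(0.48)

    def test_zero_path_length_undefined(self):
        assert np.isnan(small_world_index(0.5, 0.0))


class TestModularity:
    def test_two_disjoint_triangles(self):
        adj = np.zeros((6, 6))
        adj[:3, :3] = complete_graph(3)
        adj[3:, 3:] = complete_graph(3)
        q, labels = modularity(adj)
        assert q == pytest.approx(0.5)
        assert len(set(labels)) == 2

    def test_complete_graph_single_community(self):
        q, labels = modularity(complete_graph(5))
        assert q == pytest.approx(0.0)
        assert len(set(labels)) == 1

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity(np.zeros((4, 4)))

    @staticmethod
    def _newman_q(adj, labels):
        m = adj.sum() / 2
        deg = adj.sum(axis=1)
        same = labels[:, None] == labels[None, :]
        return float(((adj - np.outer(deg, deg) / (2 * m)) * same).sum() / (2 * m))

    def test_two_cliques_with_bridge_matches_bipartition_search(self):
        """Greedy Q equals the best split over all 2-partitions of two K4s
        joined by one edge."""
        adj = np.zeros((8, 8))
        adj[:4, :4] = complete_graph(4)
        adj[4:, 4:] = complete_graph(4)
        adj[3, 4] = adj[4, 3] = 1.0
        best = -1.0
        for mask in range(1, 128):  # nontrivial bipartitions
            labels = np.array([(mask >> i) & 1 for i in range(8)])
            best = max(best, self._newman_q(adj, labels))
        q, _ = modularity(adj)
        assert q == pytest.approx(best)

    def test_greedy_never_beats_exhaustive_partition_search(self, rng):
        """On <= 7-node graphs, fast-greedy Q is bounded by the maximum over
        every partition of the node set."""

        def all_partitions(items):
            if not items:
                yield []
                return
            first, rest = items[0], items[1:]
            for part in all_partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [[first] + part[i]] + part[i + 1 :]
                yield [[first]] + part

        for _ in range(5):
            adj = random_graph(7, int(rng.integers(4, 15)), rng)
            if adj.sum() == 0:
                continue
            best = -1.0
            for part in all_partitions(list(range(7))):
                labels = np.empty(7, dtype=int)
                for ci, block in enumerate(part):
                    labels[block] = ci
                best = max(best, self._newman_q(adj, labels))
            q, labels = modularity(adj)
            assert q <= best + 1e-12
            assert q == pytest.approx(self._newman_q(adj, labels))


class TestAssortativity:
    def test_path_graph_perfectly_disassortative(self):
        assert degree_assortativity(path_graph(3)) == pytest.approx(-1.0)

    def test_star_graph_closed_form(self):
        assert degree_assortativity(star_graph(5)) == pytest.approx(-1.0)

    def test_regular_graph_undefined(self):
        assert np.isnan(degree_assortativity(complete_graph(4)))

    def test_matches_networkx_on_random_graphs(self, rng):
        checked = 0
        while checked < 10:
            adj = random_graph(12, int(rng.integers(5, 30)), rng)
            ours = degree_assortativity(adj)
            if np.isnan(ours):
                continue
            theirs = nx.degree_assortativity_coefficient(nx.from_numpy_array(adj))
            assert ours == pytest.approx(theirs, abs=1e-10)
            checked += 1


class TestRichClub:
    def test_complete_graph_all_clubs_complete(self):
        ks, rc, sizes = rich_club_curve(complete_graph(5))
        np.testing.assert_array_equal(ks, [1, 2, 3, 4])
        np.testing.assert_allclose(rc, 1.0)
        np.testing.assert_array_equal(sizes, [5, 5, 5, 5])

    def test_triangle_plus_pendant_club_at_two(self):
        ks, rc, sizes = rich_club_curve(triangle_plus_pendant())
        assert rc[ks == 2][0] == pytest.approx(1.0)
        assert sizes[ks == 2][0] == 3

    def test_club_membership_shrinks_with_k(self, rng):
        adj = random_graph(25, 70, rng)
        _, _, sizes = rich_club_curve(adj)
        assert np.all(np.diff(sizes) <= 0)

    def test_matches_networkx_shifted_convention(self, rng):
        # networkx uses degree > k; ours keeps degree >= k, so RC(k) == nx(k-1)
        adj = random_graph(20, 60, rng)
        ks, rc, sizes = rich_club_curve(adj)
        theirs = nx.rich_club_coefficient(nx.from_numpy_array(adj), normalized=False)
        for k, val, size in zip(ks, rc, sizes):
            if (k - 1) in theirs and size >= 2:
                assert val == pytest.approx(theirs[k - 1])

    def test_normalized_profile_on_complete_graph_is_unity(self, rng):
        profile = rich_club_profile(complete_graph(6), null_count=20, rng=rng)
        np.testing.assert_allclose(profile.rc_norm, 1.0)
        # nulls identical to the input: no significance claims possible
        assert not profile.significant.any()

    def test_null_ensemble_preserves_degrees_and_flags_planted_club(self, rng):
        # dense core + sparse periphery: the core should register as a club
        adj = np.zeros((20, 20))
        adj[:6, :6] = complete_graph(6)
        for i in range(6, 20):
            adj[i, i - 6] = adj[i - 6, i] = 1.0
        profile = rich_club_profile(adj, null_count=60, rng=rng)
        assert profile.rc_norm[profile.k == 5][0] > 1.0


class TestScopes:
    def test_edge_partition_identity(self, rng):
        adj = random_graph(60, 200, rng)
        part = Partition.default(60, 10)
        counts = {
            scope: int(subgraph(adj, part, scope).sum() // 2)
            for scope in ("minority", "majority", "interpartition")
        }
        assert sum(counts.values()) == 200

    def test_minority_scope_is_induced_subgraph(self, rng):
        adj = random_graph(60, 200, rng)
        part = Partition.default(60, 10)
        sub = subgraph(adj, part, "minority")
        assert sub.shape == (10, 10)
        np.testing.assert_array_equal(sub, adj[:10, :10])

    def test_interpartition_density_uses_cross_pair_denominator(self):
        part = Partition.default(6, 2)
        adj = np.zeros((6, 6))
        adj[0, 3] = adj[3, 0] = 1.0
        adj[1, 4] = adj[4, 1] = 1.0
        rec = metric_record(adj, part, "interpartition")
        assert rec["edge_density"] == pytest.approx(2 / (2 * 4))
        assert scope_pair_count(part, "interpartition") == 8


class TestNormalization:
    def _series(self, clustering, assort):
        return pd.DataFrame(
            {
                "scope": ["whole"],
                "edge_density": [0.2],
                "clustering": [clustering],
                "path_length": [2.0],
                "small_world": [0.1],
                "modularity": [0.4],
                "assortativity": [assort],
            }
        )

    def _baseline(self):
        return pd.DataFrame(
            {
                "edge_density": [0.2],
                "clustering": [0.25],
                "path_length": [2.0],
                "small_world": [0.125],
                "modularity": [0.2],
                "assortativity": [-0.01],
            },
            index=["whole"],
        )

    def test_metric_equal_to_baseline_normalizes_to_one(self):
        out = normalize_metrics(self._series(0.25, 0.5), self._baseline())
        assert out["clustering"].iloc[0] == pytest.approx(1.0)
        assert out["edge_density"].iloc[0] == pytest.approx(1.0)

    def test_assortativity_passes_through(self):
        out = normalize_metrics(self._series(0.25, 0.5), self._baseline())
        assert out["assortativity"].iloc[0] == 0.5

    def test_fresh_random_graph_self_normalizes_near_unity(self, rng):
        from rewirenet import baseline_metric_means

        part = Partition.default(40, 8)
        baseline = baseline_metric_means(40, 160, part, count=40, rng=rng)
        adj = random_graph(40, 160, rng)
        rec = metric_record(adj, part, "whole")
        series = pd.DataFrame([rec])
        out = normalize_metrics(series, baseline)
        assert out["clustering"].iloc[0] == pytest.approx(1.0, abs=0.35)
        assert out["path_length"].iloc[0] == pytest.approx(1.0, abs=0.15)
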