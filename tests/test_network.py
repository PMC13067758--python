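"""Proximity features: BFS oracle agreement, null calibration, overlaps."""

import dataclasses

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcmspred.kb_io import KnowledgeBase, PPIGraph
from tcmspred.network import (FeatureConfig, GraphDistances, build_pair_features,
                              closest_proximity, load_pair_features,
                              overlap_stats, proximity_z, save_pair_features,
                              shortest_path_from)


def _random_graph(n=50, p=0.08, seed=0) -> PPIGraph:
    g = nx.gnp_random_graph(n, p, seed=seed)
    mapping = {i: f"G{i:02d}" for i in g.nodes}
    return PPIGraph.from_edges(
        [(mapping[a], mapping[b]) for a, b in g.edges],
        extra_nodes=mapping.values())


class TestShortestPath:
    def test_path_graph_distances(self):
        g = PPIGraph.from_edges([("A", "B"), ("B", "C")])
        d = shortest_path_from(g, "A")
        assert d["A"] == 0 and d["B"] == 1 and d["C"] == 2

    def test_unknown_source_raises(self):
        g = PPIGraph.from_edges([("A", "B")])
        with pytest.raises(KeyError):
            shortest_path_from(g, "Z")

    def test_unreachable_nodes_absent(self):
        g = PPIGraph.from_edges([("A", "B")], extra_nodes=["X"])
        assert "X" not in shortest_path_from(g, "A")

    def test_matches_dijkstra_oracle_on_random_graph(self):
        """BFS hop counts equal unit-weight Dijkstra for all sources."""
        graph = _random_graph(50, 0.08, seed=4)
        nxg = graph.to_networkx()
        for src in sorted(graph.nodes):
            bfs = shortest_path_from(graph, src)
            oracle = nx.single_source_dijkstra_path_length(nxg, src, weight=None)
            assert bfs == dict(oracle)


class TestClosestProximity:
    def test_identical_sets_give_zero(self):
        g = _random_graph(20, 0.2, seed=1)
        some = set(sorted(g.nodes)[:5])
        assert closest_proximity(g, some, some) == 0.0

    def test_path_graph_average(self):
        g = PPIGraph.from_edges([("A", "B"), ("B", "C")])
        assert closest_proximity(g, {"A", "C"}, {"B"}) == pytest.approx(1.0)

    def test_isolated_target_hits_sentinel(self):
        g = PPIGraph.from_edges([("A", "B"), ("B", "C")], extra_nodes=["X"])
        # largest component diameter 2 -> sentinel 3
        assert closest_proximity(g, {"X"}, {"A"}) == 3.0

    def test_empty_set_rejected(self):
        g = PPIGraph.from_edges([("A", "B")])
        with pytest.raises(ValueError):
            closest_proximity(g, set(), {"A"})

    def test_invariant_under_node_relabeling(self):
        graph = _random_graph(30, 0.12, seed=2)
        rng = np.random.default_rng(3)
        names = sorted(graph.nodes)
        relabel = dict(zip(names, rng.permutation(names)))
        g2 = PPIGraph.from_edges(
            [(relabel[a], relabel[b]) for a, b in graph.edges],
            extra_nodes=[relabel[n] for n in graph.nodes])
        T = set(names[:6])
        G = set(names[10:18])
        d1 = closest_proximity(graph, T, G)
        d2 = closest_proximity(g2, {relabel[t] for t in T},
                               {relabel[g] for g in G})
        assert d1 == pytest.approx(d2)

    def test_adding_symptom_gene_to_targets_never_increases_distance(self):
        graph = _random_graph(40, 0.1, seed=5)
        rng = np.random.default_rng(6)
        names = sorted(graph.nodes)
        for _ in range(20):
            T = set(rng.choice(names, 6, replace=False))
            G = set(rng.choice(names, 6, replace=False))
            g_new = rng.choice(sorted(G))
            d_before = closest_proximity(graph, T, G)
            # brute-force recomputation of the enlarged set
            gd = GraphDistances(graph)
            d_after = closest_proximity(graph, T | {g_new}, G)
            n = len(T | {g_new})
            brute = np.mean([
                min((nx.shortest_path_length(graph.to_networkx(), t, g)
                     for g in G if nx.has_path(graph.to_networkx(), t, g)),
                    default=gd.sentinel)
                for t in T | {g_new}])
            assert d_after == pytest.approx(float(brute))
            assert d_after <= d_before + 1e-12


class TestProximityZ:
    def test_null_draws_have_near_zero_mean_z(self):
        """Self-consistency: degree-matched null sets must score z ~ 0."""
        graph = _random_graph(120, 0.06, seed=8)
        gd = GraphDistances(graph)
        rng = np.random.default_rng(9)
        names = np.array(sorted(graph.nodes))
        zs = []
        for i in range(200):
            T = set(rng.choice(names, 8, replace=False))
            G = set(rng.choice(names, 10, replace=False))
            zs.append(proximity_z(gd, T, G, n_perm=50, seed=1000 + i).z)
        assert abs(np.mean(zs)) < 0.15

    def test_minimum_permutations_enforced(self):
        g = _random_graph(20, 0.2, seed=1)
        T, G = set(sorted(g.nodes)[:3]), set(sorted(g.nodes)[5:8])
        proximity_z(g, T, G, n_perm=10, seed=0)
        with pytest.raises(ValueError):
            proximity_z(g, T, G, n_perm=5, seed=0)

    def test_degenerate_null_reports_zero_z(self):
        # sets spanning the whole graph: every null draw is the same sets
        g = PPIGraph.from_edges([("A", "B"), ("B", "C"), ("A", "C"),
                                 ("A", "D"), ("B", "D"), ("C", "D")])
        every = {"A", "B", "C", "D"}
        res = proximity_z(g, every, every, n_perm=10, seed=0)
        assert res.degenerate_null and res.z == 0.0

    def test_deterministic_under_seed(self):
        g = _random_graph(40, 0.1, seed=2)
        T = set(sorted(g.nodes)[:5])
        G = set(sorted(g.nodes)[8:14])
        r1 = proximity_z(g, T, G, n_perm=30, seed=5)
        r2 = proximity_z(g, T, G, n_perm=30, seed=5)
        assert (r1.d_obs, r1.mu_rand, r1.sigma_rand, r1.z) == \
               (r2.d_obs, r2.mu_rand, r2.sigma_rand, r2.z)


class TestOverlapStats:
    def test_identical_and_disjoint(self):
        assert overlap_stats({"a", "b"}, {"a", "b"}) == (1.0, 1.0)
        assert overlap_stats({"a"}, {"b"}) == (0.0, 0.0)

    def test_partial_overlap(self):
        j, o = overlap_stats({"a", "b"}, {"b", "c"})
        assert j == pytest.approx(1 / 3)
        assert o == pytest.approx(1 / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_stats(set(), {"a"})

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.sets(st.integers(0, 20), min_size=1, max_size=10),
           st.sets(st.integers(0, 20), min_size=1, max_size=10))
    def test_jaccard_never_exceeds_overlap_coefficient(self, a, b):
        T = {str(x) for x in a}
        G = {str(x) for x in b}
        j, o = overlap_stats(T, G)
        assert j <= o + 1e-12


class TestPairFeatures:
    def _kb(self):
        edges = [("G1", "G2"), ("G2", "G3"), ("G3", "G4"), ("G4", "G5"),
                 ("G1", "G3"), ("G2", "G5"), ("G1", "G5"), ("G3", "G5"),
                 ("G2", "G4"), ("G1", "G4")]
        return KnowledgeBase(
            herb_targets={"H1": frozenset({"G1", "G2", "G3"}),
                          "H2": frozenset({"G4"})},
            symptom_genes={"S1": frozenset({"G4", "G5"})},
            ppi=PPIGraph.from_edges(edges))

    def _emb(self):
        from tcmspred.embedding import EmbeddingTable
        return EmbeddingTable(vocab=["H1", "S1"],
                              vectors_in=np.ones((2, 4)),
                              vectors_out=np.zeros((2, 4)))

    def test_padding_and_mask(self):
        fc = FeatureConfig(seq_len=8, n_perm=10, seed=0)
        f = build_pair_features(self._kb(), self._emb(), "H1", "S1", fc)
        assert f.herb_token_seq.shape == (8,)
        assert f.herb_mask.sum() == 3
        assert (f.herb_token_seq[3:] == -1).all()

    def test_truncation_keeps_lexicographic_prefix(self):
        fc = FeatureConfig(seq_len=2, n_perm=10, seed=0)
        kb = self._kb()
        f = build_pair_features(kb, self._emb(), "H1", "S1", fc)
        kept = [kb.genes[i] for i in f.herb_token_seq]
        assert kept == sorted(kb.herb_targets["H1"])[:2]

    def test_oov_token_gets_zero_vector_with_warning(self):
        fc = FeatureConfig(seq_len=4, n_perm=10, seed=0)
        warns: list[str] = []
        f = build_pair_features(self._kb(), self._emb(), "H2", "S1", fc,
                                warnings_out=warns)
        assert not f.semantic_herb.any()
        assert any("H2" in w for w in warns)

    def test_repeated_calls_identical(self):
        fc = FeatureConfig(seq_len=4, n_perm=10, seed=0)
        f1 = build_pair_features(self._kb(), self._emb(), "H1", "S1", fc)
        f2 = build_pair_features(self._kb(), self._emb(), "H1", "S1", fc)
        assert f1.proximity == f2.proximity
        np.testing.assert_array_equal(f1.herb_token_seq, f2.herb_token_seq)

    def test_unknown_ids_raise(self):
        fc = FeatureConfig(seq_len=4, n_perm=10, seed=0)
        with pytest.raises(KeyError):
            build_pair_features(self._kb(), self._emb(), "HX", "S1", fc)


def test_feature_cache_round_trip(tmp_path, small_features):
    feats, _ = small_features
    save_pair_features(feats[:40], tmp_path)
    loaded = load_pair_features(tmp_path)
    assert len(loaded) == 40
    for a, b in zip(feats[:40], loaded):
        assert (a.herb, a.symptom) == (b.herb, b.symptom)
        assert a.proximity == pytest.approx(b.proximity)
        np.testing.assert_array_equal(a.herb_token_seq, b.herb_token_seq)
        np.testing.assert_array_equal(a.symptom_mask, b.symptom_mask)
        np.testing.assert_allclose(a.semantic_herb, b.semantic_herb)
        assert a.config_digest == b.config_digest
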