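"""RWR, degree-preserving nulls, KDE filtering, signed network merging."""

import networkx as nx
import numpy as np
import pytest

from signet import propagation as prop
from signet.factors import SeedSet


def _weighted(edges):
    g = nx.Graph()
    for u, v, c in edges:
        g.add_edge(u, v, confidence=c)
    return g


class TestSymmetricNormalize:
    def test_single_unit_edge(self):
        op = prop.symmetric_normalize(_weighted([("a", "b", 1.0)]))
        W = op.matrix.toarray()
        assert np.allclose(W, [[0, 1], [1, 0]])

    def test_star_k13(self):
        g = _weighted([("c", "x", 1.0), ("c", "y", 1.0), ("c", "z", 1.0)])
        op = prop.symmetric_normalize(g)
        W = op.matrix.toarray()
        i = op.index["c"]
        for leaf in "xyz":
            assert np.isclose(W[i, op.index[leaf]], 1 / np.sqrt(3))

    def test_symmetric_spectral_radius(self, random_weighted_graph):
        g = random_weighted_graph(25, 0.2, 3)
        op = prop.symmetric_normalize(g)
        W = op.matrix.toarray()
        assert np.allclose(W, W.T)
        assert np.max(np.abs(np.linalg.eigvalsh(W))) <= 1 + 1e-10


class TestRWR:
    def test_two_node_closed_form(self):
        op = prop.symmetric_normalize(_weighted([("a", "b", 1.0)]))
        p = prop.rwr(op, {"a": 1.0}, damping=0.5, tol=1e-14)
        assert np.allclose(p[["a", "b"]], [2 / 3, 1 / 3], atol=1e-9)

    def test_uniform_on_cycle(self):
        g = _weighted([(i, (i + 1) % 6, 1.0) for i in range(6)])
        op = prop.symmetric_normalize(g)
        p = prop.rwr(op, {n: 1 / 6 for n in range(6)}, damping=0.9)
        assert np.allclose(p, 1 / 6, atol=1e-9)

    def test_low_damping_returns_restart(self):
        g = _weighted([("a", "b", 1.0), ("b", "c", 0.5)])
        op = prop.symmetric_normalize(g)
        p = prop.rwr(op, {"a": 1.0}, damping=1e-6)
        assert p["a"] > 0.999

    def test_mass_conservation_and_entropy_monotone_on_star(self):
        g = _weighted([("c", f"l{i}", 1.0) for i in range(5)])
        op = prop.symmetric_normalize(g)
        entropies = []
        for d in np.arange(0.1, 0.95, 0.1):
            p = prop.rwr(op, {"c": 1.0}, damping=d)
            assert abs(p.sum() - 1.0) < 1e-9
            entropies.append(-(p * np.log(p.clip(lower=1e-300))).sum())
        assert (np.diff(entropies) > 0).all()

    def test_matches_closed_form_on_random_graphs(self, random_weighted_graph):
        for seed in range(10):
            g = random_weighted_graph(30, 0.15, seed)
            op = prop.symmetric_normalize(g)
            nodes = sorted(g.nodes())
            restart = {nodes[0]: 0.7, nodes[1]: 0.3}
            it = prop.rwr(op, restart, damping=0.95, tol=1e-13)
            cf = prop.rwr_closed_form(op, restart, damping=0.95)
            assert np.abs(it - cf).sum() < 1e-8


class TestRewire:
    def test_triangle_fixed(self):
        g = _weighted([("a", "b", 0.5), ("b", "c", 0.6), ("a", "c", 0.7)])
        out = prop.degree_preserving_rewire(g, seed=0)
        assert sorted(d for _, d in out.degree()) == [2, 2, 2]

    def test_degree_sequence_invariant(self, random_weighted_graph):
        g = random_weighted_graph(40, 0.15, 5)
        before = sorted(d for _, d in g.degree())
        for seed in range(5):
            out = prop.degree_preserving_rewire(g, seed=seed)
            assert sorted(d for _, d in out.degree()) == before
            assert out.number_of_edges() == g.number_of_edges()

    def test_path_degree_sequence_and_confidences_travel(self):
        g = _weighted([("a", "b", 0.9), ("b", "c", 0.8), ("c", "d", 0.7)])
        seen = set()
        for seed in range(20):
            out = prop.degree_preserving_rewire(g, n_swaps=50, seed=seed)
            assert sorted(d for _, d in out.degree()) == [1, 1, 2, 2]
            confs = sorted(c for _, _, c in out.edges(data="confidence"))
            assert confs == [0.7, 0.8, 0.9]
            seen.add(frozenset(map(frozenset, out.edges())))
        # only two simple graphs exist on this degree sequence
        assert len(seen) <= 2


class TestEmpiricalSignificance:
    def test_add_one_formula_bound(self, random_weighted_graph):
        g = random_weighted_graph(30, 0.2, 7)
        nodes = sorted(g.nodes())
        op = prop.symmetric_normalize(g)
        obs = prop.rwr(op, {nodes[0]: 1.0})
        p = prop.empirical_node_significance(g, {nodes[0]: 1.0}, n_null=100,
                                             seed=1, observed=obs)
        assert p.min() >= 1 / 101
        assert p.max() <= 1.0
        # the seed keeps its restart mass, so its observed score is maximal
        assert obs.idxmax() == nodes[0]


class TestSemanticSimilarity:
    def test_cases(self):
        ann = {"a": {1, 2, 3}, "b": {2, 3, 4}, "c": {9}, "d": {1, 2, 3}}
        assert prop.semantic_similarity(ann, "a", "d") == 1.0
        assert prop.semantic_similarity(ann, "a", "c") == 0.0
        assert prop.semantic_similarity(ann, "a", "b") == 0.5
        assert prop.semantic_similarity(ann, "a", "zzz") == 0.0


class TestKdeFilter:
    def test_cutoff_zero_keeps_all(self):
        ann = {f"n{i}": {i} for i in range(5)}
        kept, _ = prop.kde_filter({f"n{i}": 1.0 for i in range(5)},
                                  ["n0"], ann, cutoff=0.0)
        assert len(kept) == 5

    def test_bimodal_keeps_high_mode(self):
        rng = np.random.default_rng(2)
        ann = {"seed": set(range(10))}
        candidates = {}
        for i in range(50):  # high-similarity mode ~0.9
            ann[f"h{i}"] = set(range(9)) | {100 + i}
            candidates[f"h{i}"] = 1.0
        for i in range(50):  # low mode ~0.1
            ann[f"l{i}"] = {0, 1} | set(rng.integers(200, 400, size=8))
            candidates[f"l{i}"] = 1.0
        kept, sims = prop.kde_filter(candidates, ["seed"], ann, cutoff=0.5)
        assert set(kept) == {f"h{i}" for i in range(50)}

    def test_near_one_cutoff_keeps_only_max(self):
        ann = {"s": {1, 2, 3, 4}}
        candidates = {}
        for i, k in enumerate(range(4)):
            ann[f"c{i}"] = set(list(ann["s"])[: k + 1]) | {50 + i}
            candidates[f"c{i}"] = 1.0
        kept, sims = prop.kde_filter(candidates, ["s"], ann, cutoff=0.999999)
        best = max(sims.values())
        assert all(sims[c] >= best - 1e-12 for c in kept)

    def test_degenerate_similarities_keep_all(self):
        ann = {"s": {1}, "a": {2}, "b": {3}}
        with pytest.warns(UserWarning, match="degenerate"):
            kept, _ = prop.kde_filter({"a": 1.0, "b": 1.0}, ["s"], ann)
        assert kept == ["a", "b"]


class TestPropagateFactorAndMerge:
    def test_planted_path_retention(self, small_world):
        graph, truth, ann = small_world
        path = truth.planted_paths[0]
        seedset = SeedSet(positive={n: 1.0 for n in path},
                          negative={n: -1.0 for n in
                                    sorted(graph.nodes())[:4]
                                    if n not in path},
                          factor=1, quantile=0.05)
        pos, neg = prop.propagate_factor(graph, seedset, n_null=150,
                                         ann=ann, seed=5)
        assert sum(n in pos.retained for n in path) / len(path) >= 0.8
        assert abs(pos.scores.sum() - 1.0) < 1e-9

    def test_identical_seed_sides_identical_results(self, small_world):
        graph, truth, ann = small_world
        seeds = {n: 1.0 for n in truth.planted_paths[0]}
        seedset = SeedSet(positive=seeds, negative=seeds, factor=1,
                          quantile=0.05)
        pos, neg = prop.propagate_factor(graph, seedset, n_null=100,
                                         ann=ann, seed=5)
        assert pos.retained == neg.retained
        assert np.allclose(pos.scores, neg.scores)

    def test_rwr_threshold_one_keeps_argmax_and_seeds(self, small_world):
        graph, truth, ann = small_world
        seeds = {truth.planted_paths[0][0]: 1.0}
        seedset = SeedSet(positive=seeds, negative=seeds, factor=1,
                          quantile=0.05)
        pos, _ = prop.propagate_factor(graph, seedset, rwr_threshold=1.0,
                                       n_null=100, ann=None, seed=5)
        non_seed = [n for n in pos.retained if n not in seeds]
        assert all(pos.scores[n] >= pos.scores.max() - 1e-15
                   for n in non_seed)

    def test_signed_merge_and_union_properties(self, small_world):
        graph, truth, ann = small_world
        p1, p2 = truth.planted_paths[:2]
        r1 = prop.PropagationResult(None, None, list(p1), {})
        r2 = prop.PropagationResult(None, None, list(p2), {})
        net = prop.build_signed_network(r1, r2, graph, factor=1)
        hub = next(iter(truth.convergence_hubs))
        assert net.signs[hub] == {"+", "-"}
        for u, v in net.graph.edges():
            assert graph.has_edge(u, v)
        other = prop.build_signed_network(r2, r1, graph, factor=3)
        u1 = prop.union_networks(net, other)
        u2 = prop.union_networks(other, net)
        assert u1.nodes == u2.nodes
        assert prop.union_networks(net, net).nodes == net.nodes
        both = len(net.nodes) + len(other.nodes) - len(net.nodes
                                                       & other.nodes)
        assert len(u1.nodes) == both
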