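import itertools
import math

import networkx as nx
import numpy as np
import pytest

from multimorbnet.fin_connectivity import (
    binned_swap_null,
    binned_swap_replicates,
    degree_bin,
    edge_disease_overlap,
    mean_to_common,
    mean_to_unique,
    topological_overlap,
)
from multimorbnet.io_formats import DiseaseProteinSet


def dset(name, members):
    return DiseaseProteinSet(name, frozenset(members))


def brute_force_to(G, a, b):
    """Independent oracle: explicit adjacency-matrix neighbor enumeration."""
    nodes = list(G.nodes())
    A = nx.to_numpy_array(G, nodelist=nodes)
    ia, ib = nodes.index(a), nodes.index(b)
    common = sum(
        1 for k in range(len(nodes))
        if k not in (ia, ib) and A[ia, k] and A[ib, k]
    )
    adj = 1 if A[ia, ib] else 0
    return (common + adj) / min(A[ia].sum(), A[ib].sum())


class TestTopologicalOverlap:
    @pytest.mark.parametrize(
        "edges,a,b,expected",
        [
            ([("a", "c"), ("c", "b")], "a", "b", 1.0),          # shared sole neighbor
            ([("a", "x"), ("b", "y")], "a", "b", 0.0),          # different components
            ([("a", "b"), ("b", "c"), ("a", "c")], "a", "b", 1.0),  # triangle
            ([("a", "b")], "a", "b", 1.0),                      # sole edge, +1 term
        ],
    )
    def test_hand_enumerated_cases(self, edges, a, b, expected):
        assert topological_overlap(nx.Graph(edges), a, b) == expected

    def test_symmetric_and_bounded(self):
        G = nx.erdos_renyi_graph(20, 0.3, seed=0)
        for a, b in itertools.combinations([n for n in G if G.degree(n) > 0], 2):
            to = topological_overlap(G, a, b)
            assert 0.0 <= to <= 1.0
            assert to == topological_overlap(G, b, a)

    def test_matches_brute_force_on_all_small_graphs(self):
        """Exhaustive agreement with the neighbor-enumeration oracle (n <= 6)."""
        from networkx.generators.atlas import graph_atlas_g

        checked = 0
        for G in graph_atlas_g():
            if G.number_of_nodes() > 6:
                break
            usable = [n for n in G if G.degree(n) > 0]
            for a, b in itertools.combinations(usable, 2):
                assert topological_overlap(G, a, b) == pytest.approx(
                    brute_force_to(G, a, b)
                )
                checked += 1
        assert checked > 1000

    def test_absent_node_rejected(self):
        G = nx.Graph([("a", "b")])
        with pytest.raises(ValueError, match="absent"):
            topological_overlap(G, "a", "zz")


class TestMeanTO:
    def test_adjacent_star_leaves_fully_overlap(self, star_graph):
        sets = [dset("d1", {"n1", "n2"}), dset("d2", {"n1", "n2"})]
        res = mean_to_common(star_graph, sets)
        assert res.mean_to == 1.0  # both leaves see only the hub

    def test_complete_graph_is_maximal(self):
        G = nx.complete_graph(6)
        sets = [dset("d1", {0, 1, 2, 3}), dset("d2", {1, 2, 3, 4})]
        res = mean_to_common(G, sets)
        assert res.mean_to == 1.0

    def test_too_few_common_nodes_not_computable(self):
        G = nx.Graph([("a", "b")])
        res = mean_to_common(G, [dset("d1", {"a"}), dset("d2", {"a"})])
        assert not res.computable and "not computable" in res.note

    def test_unique_cross_separated_components(self):
        G = nx.Graph([("a", "x"), ("b", "y")])
        res = mean_to_unique(G, [dset("d1", {"a"}), dset("d2", {"b"})])
        assert res.mean_to == 0.0

    def test_unique_adjacent_degree_one_pair(self):
        G = nx.Graph([("a", "b")])
        res = mean_to_unique(G, [dset("d1", {"a"}), dset("d2", {"b"})])
        assert res.mean_to == 1.0

    def test_unique_mean_invariant_to_disease_order(self, small_study):
        G = small_study.network
        sets = [s.restrict_to(G) for s in small_study.disease_sets]
        forward = mean_to_unique(G, sets)
        reverse = mean_to_unique(G, sets[::-1])
        assert forward.mean_to == pytest.approx(reverse.mean_to)

    def test_within_mode_single_disease(self, star_graph):
        res = mean_to_unique(star_graph, [dset("d", {"n1", "n2", "n3"})],
                             mode="within")
        assert res.mean_to == 1.0  # leaves share the hub as sole neighbor


class TestDegreeBin:
    @pytest.mark.parametrize("d,expected", [(1, 1), (2, 2), (7, 3), (20, 4), (150, 6)])
    def test_values(self, d, expected):
        assert degree_bin(d) == expected
        assert degree_bin(d) == round(math.log(d) + 1)

    def test_invalid_degree(self):
        with pytest.raises(ValueError):
            degree_bin(0)


class TestBinnedSwapNull:
    def test_replicates_preserve_counts_cells_and_bins(self, small_study):
        G = small_study.network
        sets = [s.restrict_to(G) for s in small_study.disease_sets]
        a, b, c = (s.proteins for s in sets)
        bins = {n: degree_bin(G.degree(n)) for n in G if G.degree(n) >= 1}
        orig_bins = sorted(bins[p] for p in (a | b | c))
        for reps in binned_swap_replicates(G, sets, R=20, seed=1):
            ra, rb, rc = (s.proteins for s in reps)
            assert (len(ra), len(rb), len(rc)) == (len(a), len(b), len(c))
            assert len(ra & rb) == len(a & b)
            assert len(ra & rc) == len(a & c)
            assert len(rb & rc) == len(b & c)
            assert len(ra & rb & rc) == len(a & b & c)
            assert sorted(bins[p] for p in (ra | rb | rc)) == orig_bins

    def test_singleton_bin_maps_to_itself(self):
        # a node alone in its bin can only be exchanged for itself
        G = nx.path_graph(3)
        G.add_edge(3, 4)
        sets = [dset("d1", {1}), dset("d2", {1})]
        for reps in binned_swap_replicates(G, sets, R=5, seed=0):
            assert reps[0].proteins == frozenset({1})

    def test_calibration_z_near_zero_on_random_sets(self):
        """Uniform random disease sets should not look significant."""
        zs = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            G = nx.erdos_renyi_graph(400, 0.03, seed=seed)
            nodes = sorted(n for n in G if G.degree(n) > 0)
            common = list(rng.choice(nodes, size=8, replace=False))
            sets = [dset("d1", set(common) | set(rng.choice(nodes, 20, replace=False))),
                    dset("d2", set(common) | set(rng.choice(nodes, 20, replace=False)))]
            obs = mean_to_common(G, sets)

            def stat(g, ss):
                r = mean_to_common(g, ss)
                return r.mean_to if r.computable else 0.0

            null = binned_swap_null(G, sets, stat, R=200, seed=seed + 50)
            sd = null.samples.std(ddof=1)
            zs.append((obs.mean_to - null.samples.mean()) / sd)
        assert abs(np.mean(zs)) < 1.0


class TestEdgeOverlap:
    def test_identical_sets_full_overlap(self):
        G = nx.erdos_renyi_graph(20, 0.2, seed=2)
        s = dset("d", set(list(G)[:5]))
        res = edge_disease_overlap(G, [s, dset("d2", s.proteins)])
        assert res.jaccard == 1.0

    def test_star_hand_enumeration(self, star_graph):
        res = edge_disease_overlap(
            star_graph, [dset("A", {"n0"}), dset("B", {"n1"})]
        )
        hub_degree = star_graph.degree("n0")
        assert res.edge_counts["A"] == hub_degree
        assert res.edge_counts["B"] == 1
        assert res.common_edges == 1
        assert res.jaccard == pytest.approx(1 / hub_degree)
        assert res.unique_edge_counts["B"] == 0
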