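"""Topological overlap, average linkage and threshold module cuts."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from bigramnet import (
    average_linkage,
    cut_modules,
    from_edges,
    module_hierarchy,
    topological_overlap,
)
from bigramnet.hierarchy import DEFAULT_THRESHOLDS, to_newick
from bigramnet.synthetic import planted_modular_network
from conftest import random_net


def brute_force_tom(g, u, v):
    if u == v:
        return 1.0
    nu, nv = set(g.neighbors(u)), set(g.neighbors(v))
    denom = min(len(nu), len(nv))
    if denom == 0:
        return 0.0
    return (len(nu & nv) + (1 if g.has_edge(u, v) else 0)) / denom


def refines(fine, coarse):
    return all(any(m <= M for M in coarse) for m in fine)


class TestTopologicalOverlap:
    def test_triangle_pairs_fully_overlap(self):
        tri = from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        tom = topological_overlap(tri)
        assert tom.overlap("A", "B") == pytest.approx(1.0)

    def test_cross_component_overlap_is_zero(self):
        net = from_edges([("A", "B"), ("X", "Y")])
        assert topological_overlap(net).overlap("A", "X") == 0.0

    def test_path_endpoints_and_edge(self, path3):
        tom = topological_overlap(path3)
        assert tom.overlap("A", "C") == pytest.approx(1.0)  # shared neighbour B
        assert tom.overlap("A", "B") == pytest.approx(1.0)  # direct link bonus

    def test_matrix_invariants(self):
        net = random_net(10, 0.3, 4)
        m = topological_overlap(net).matrix
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert (m >= 0).all() and (m <= 1).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_set_intersection_oracle(self, seed):
        net = random_net(9, 0.35, seed)
        tom = topological_overlap(net)
        for u, v in itertools.combinations(sorted(net.graph.nodes), 2):
            assert tom.overlap(u, v) == pytest.approx(
                brute_force_tom(net.graph, u, v)
            )

    def test_plus_one_variant_bounded_by_ravasz(self):
        net = random_net(12, 0.3, 1)
        a = topological_overlap(net, "ravasz").matrix
        b = topological_overlap(net, "plus_one").matrix
        off = ~np.eye(len(a), dtype=bool)
        assert (b[off] <= a[off] + 1e-12).all()


class TestAverageLinkage:
    def test_identical_rows_merge_first_at_zero(self):
        d = np.array([[0, 0, 0.8], [0, 0, 0.8], [0.8, 0.8, 0]], dtype=float)
        dend = average_linkage(d, ["A", "B", "C"])
        assert dend.heights[0] == pytest.approx(0.0)

    def test_hand_agglomeration(self):
        # AB=0.1, AC=BC=0.9 -> merge (A,B) at 0.1, then join C at 0.9
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        dend = average_linkage(d, ["A", "B", "C"])
        assert dend.heights.tolist() == pytest.approx([0.1, 0.9])

    def test_leaf_count_matches_dimension(self):
        net = random_net(14, 0.25, 2)
        tom = topological_overlap(net)
        dend = average_linkage(tom.dissimilarity, tom.vertices)
        assert dend.n_leaves == net.n_vertices
        assert np.all(np.diff(dend.heights) >= -1e-12)  # monotone merges

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 0.1], [0.4, 0]])
        with pytest.raises(ValueError):
            average_linkage(d, ["A", "B"])


class TestCutModules:
    @pytest.fixture
    def dend(self):
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        return average_linkage(d, ["A", "B", "C"])

    def test_cut_above_root_single_module(self, dend):
        h = cut_modules(dend, [0.95])
        assert h.partitions[0.95] == [frozenset({"A", "B", "C"})]

    def test_cut_below_all_merges_singletons(self, dend):
        h = cut_modules(dend, [0.05])
        assert sorted(len(m) for m in h.partitions[0.05]) == [1, 1, 1]

    def test_cut_is_strictly_below_threshold(self, dend):
        # merge at exactly 0.1 must be split by a cut at 0.1
        h = cut_modules(dend, [0.1])
        assert sorted(len(m) for m in h.partitions[0.1]) == [1, 1, 1]

    def test_partition_is_disjoint_cover(self):
        net = random_net(16, 0.25, 8)
        h = module_hierarchy(net)
        for t, mods in h.partitions.items():
            flat = [v for m in mods for v in m]
            assert sorted(flat) == sorted(net.graph.nodes)

    def test_bad_threshold_rejected(self, dend):
        with pytest.raises(ValueError):
            cut_modules(dend, [0.0])


class TestModuleRecovery:
    def test_planted_two_level_recovery(self):
        """Coarse cut finds top-level modules, finer cut the sub-cliques."""
        net, top_of, sub_of = planted_modular_network()
        h = module_hierarchy(net)
        verts = h.dendrogram.labels

        def flat_labels(t):
            lab = {v: i for i, m in enumerate(h.partitions[t]) for v in m}
            return [lab[v] for v in verts]

        assert adjusted_rand_score([top_of[v] for v in verts], flat_labels(0.95)) == 1.0
        assert adjusted_rand_score([sub_of[v] for v in verts], flat_labels(0.7)) == 1.0

    def test_refinement_chain_across_default_thresholds(self):
        net, _, _ = planted_modular_network()
        h = module_hierarchy(net)
        ts = sorted(DEFAULT_THRESHOLDS, reverse=True)
        for coarse_t, fine_t in zip(ts, ts[1:]):
            assert refines(h.partitions[fine_t], h.partitions[coarse_t])

    def test_invariant_under_order_preserving_relabeling(self):
        """Renaming vertices without changing their lexicographic order
        leaves every partition unchanged (ties are broken by label
        order, so only the order can matter, not the names)."""
        net = random_net(15, 0.3, 6)
        relabel = {v: f"x{i:03d}" for i, v in enumerate(sorted(net.graph.nodes))}
        shuffled = from_edges(
            sorted((relabel[u], relabel[v]) for u, v in net.graph.edges)
        )
        ha, hb = module_hierarchy(net), module_hierarchy(shuffled)
        for t in DEFAULT_THRESHOLDS:
            mapped = sorted(
                sorted(relabel[v] for v in m) for m in ha.partitions[t]
            )
            got = sorted(sorted(m) for m in hb.partitions[t])
            assert mapped == got

    def test_pooled_equals_per_component_clustering(self):
        """Components only merge at height 1, so pooled == per-component cuts."""
        import networkx as nx

        net = from_edges(
            [("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y"), ("Y", "Z")]
        )
        pooled = module_hierarchy(net)
        for t in DEFAULT_THRESHOLDS:
            per_comp = []
            for comp in nx.connected_components(net.graph):
                sub = net.subgraph(comp)
                if sub.n_vertices == 1:
                    per_comp.append(frozenset(comp))
                    continue
                per_comp.extend(module_hierarchy(sub).partitions[t])
            assert sorted(map(sorted, pooled.partitions[t])) == sorted(
                map(sorted, per_comp)
            )


class TestNewick:
    def test_leaves_round_trip(self):
        import io

        from Bio import Phylo

        net = random_net(9, 0.35, 12)
        tom = topological_overlap(net)
        dend = average_linkage(tom.dissimilarity, tom.vertices)
        tree = Phylo.read(io.StringIO(to_newick(dend)), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(tom.vertices)
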