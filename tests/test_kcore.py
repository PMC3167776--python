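"""k-core peeling, shell indices and cross-group core comparison.

The independent oracle uses the subset-union characterisation: the
k-core is the union of all vertex subsets whose induced subgraph has
minimum degree >= k, so shell(v) = max over subsets containing v of
the induced minimum degree.  networkx's core_number provides a second
independent cross-check.
"""

import networkx as nx
import pytest

from bigramnet import (
    ShellIndexTable,
    build_group_network,
    compare_groups,
    decompose,
    from_edges,
    innermost_core,
    k_core,
)
from bigramnet.assignments import DomainHit, ProteinArchitecture
from bigramnet.synthetic import GroupPlan, multi_group_plan, planted_core_network
from conftest import random_net


def brute_force_shells(g: nx.Graph) -> dict:
    """Shell oracle by exhaustive subset enumeration (bitmask)."""
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * len(nodes)
    for u, v in g.edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    best = [0] * len(nodes)
    for subset in range(1, 1 << len(nodes)):
        mindeg = min(
            (adj[i] & subset).bit_count()
            for i in range(len(nodes))
            if subset >> i & 1
        )
        for i in range(len(nodes)):
            if subset >> i & 1 and mindeg > best[i]:
                best[i] = mindeg
    return {v: best[idx[v]] for v in nodes}


class TestKCore:
    def test_k4_is_its_own_3core(self, k4):
        assert k_core(k4, 3).vertices == {"A", "B", "C", "D"}

    def test_path_has_empty_2core(self, path3):
        assert k_core(path3, 2).n_vertices == 0

    def test_peripheral_hub_leaves_2core(self, toy_core_hub):
        """A degree-4 hub wired mostly to leaves peels out at k = 2."""
        core2 = k_core(toy_core_hub, 2)
        assert "F" not in core2.vertices
        assert core2.vertices == {"A", "B", "C", "D"}

    def test_negative_k_rejected(self, k4):
        with pytest.raises(ValueError):
            k_core(k4, -1)

    @pytest.mark.parametrize("seed", range(8))
    def test_nesting_chain(self, seed):
        net = random_net(14, 0.3, seed)
        prev = set(net.graph.nodes)
        for k in range(1, 15):
            cur = k_core(net, k).vertices
            assert cur <= prev
            prev = cur


class TestDecompose:
    def test_k4_all_shell_3(self, k4):
        assert set(decompose(k4).shells.values()) == {3}

    def test_tree_all_shell_1(self):
        tree = from_edges([("A", "B"), ("B", "C"), ("B", "D"), ("D", "E")])
        assert set(decompose(tree).shells.values()) == {1}

    def test_peripheral_merged_at_zero(self, k4):
        table = decompose(k4, peripheral={"LONER"})
        assert table.shells["LONER"] == 0
        assert table.max_shell == 3

    def test_shell_bounded_by_degree(self, toy_core_hub):
        table = decompose(toy_core_hub)
        for v, s in table.shells.items():
            assert s <= toy_core_hub.degree(v)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_subset_union_oracle(self, seed):
        net = random_net(9, 0.35, seed)
        assert decompose(net).shells == brute_force_shells(net.graph)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_networkx_core_number(self, seed):
        net = random_net(30, 0.15, seed)
        assert decompose(net).shells == nx.core_number(net.graph)

    @pytest.mark.parametrize("seed", range(5))
    def test_shell_geq_k_iff_in_kcore(self, seed):
        net = random_net(12, 0.3, seed)
        table = decompose(net)
        for k in range(0, max(table.shells.values()) + 2):
            members = k_core(net, k).vertices
            assert members == {v for v, s in table.shells.items() if s >= k}

    def test_invariant_under_edge_counts(self):
        a = from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        b = a.copy()
        nx.set_edge_attributes(b.graph, 7, "count")
        assert decompose(a).shells == decompose(b).shells


class TestInnermostCore:
    def test_max_shell_set_and_nested_count(self):
        table = ShellIndexTable({"A": 3, "B": 3, "C": 1})
        assert innermost_core(table) == {"A", "B"}
        assert table.nested_core_count == 2

    def test_all_zero_gives_empty_core(self):
        assert innermost_core(ShellIndexTable({"A": 0, "B": 0})) == set()

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            innermost_core(ShellIndexTable({}))

    def test_planted_clique_recovered_exactly(self):
        net, truth = planted_core_network(core_size=8)
        table = decompose(net)
        assert table.shells == truth
        assert innermost_core(table) == {d for d, s in truth.items() if s == 7}


class TestCompareGroups:
    def test_simple_overlap(self):
        t1 = ShellIndexTable({"A": 2, "B": 2, "C": 1}, group="g1")
        t2 = ShellIndexTable({"B": 3, "C": 3, "D": 1}, group="g2")
        cmp = compare_groups([t1, t2])
        assert cmp.shared_by_all == {"B"}
        assert cmp.shared_by_at_least_two == {"B"}

    def test_disjoint_cores(self):
        t1 = ShellIndexTable({"A": 2, "X": 1}, group="g1")
        t2 = ShellIndexTable({"B": 2, "Y": 1}, group="g2")
        cmp = compare_groups([t1, t2])
        assert cmp.shared_by_all == set() and cmp.shared_by_at_least_two == set()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([ShellIndexTable({"A": 1})])

    def test_planted_four_kingdom_overlap(self):
        result = multi_group_plan(GroupPlan(n_groups=4, shared_by_all=6,
                                            shared_by_at_least_two=18))
        tables = [decompose(result.networks[g], group=g) for g in sorted(result.networks)]
        cmp = compare_groups(tables)
        assert len(cmp.shared_by_all) == 6
        assert len(cmp.shared_by_at_least_two) == 18
        assert cmp.shared_by_all <= cmp.shared_by_at_least_two


class TestGroupNetworks:
    @staticmethod
    def _arch(genome, protein, *doms):
        hits, pos = [], 1
        for d in doms:
            hits.append(DomainHit(d, ((pos, pos + 99),)))
            pos += 110  # gap 10: linked
        return ProteinArchitecture(protein, genome, hits)

    def test_counts_pool_across_member_genomes(self):
        archs = {
            "g1": [self._arch("g1", "p1", "A", "B")],
            "g2": [self._arch("g2", "p1", "A", "B")],
        }
        nets = build_group_network(archs, {"g1": "K", "g2": "K"})
        assert nets["K"].edge_count("A", "B") == 2

    def test_union_of_member_vertex_sets(self):
        archs = {
            "g1": [self._arch("g1", "p1", "A", "B")],
            "g2": [self._arch("g2", "p1", "C", "D")],
        }
        nets = build_group_network(archs, {"g1": "K", "g2": "K"})
        assert nets["K"].vertices == {"A", "B", "C", "D"}

    def test_unmapped_genome_named_in_error(self):
        archs = {"gX": [self._arch("gX", "p1", "A", "B")]}
        with pytest.raises(KeyError, match="gX"):
            build_group_network(archs, {})
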