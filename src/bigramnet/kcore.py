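"""k-core decomposition and the networking-versatility (shell) index.

The k-core of a graph is its maximum induced subgraph in which every
vertex has degree at least k; the greedy peeling algorithm — remove
vertices of degree below k until none remain — produces it uniquely.
A domain's *networking versatility index* is the largest k whose
k-core still contains it.  Vertices never seen in any bigram
(peripheral domains) have index 0; a high index marks a domain woven
deep into the network's core, which is not the same as a high degree:
a hub whose neighbours are mostly leaves peels away at k = 2 and keeps
a shell index of 1 regardless of its degree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from bigramnet.assignments import ProteinArchitecture, all_bigrams, peripheral_domains
from bigramnet.graph import BigramNetwork, build_network

__all__ = [
    "ShellIndexTable",
    "CoreComparison",
    "k_core",
    "decompose",
    "innermost_core",
    "compare_groups",
    "build_group_network",
    "write_shell_table",
    "write_core_comparison",
]


@dataclass
class ShellIndexTable:
    """Per-domain shell (networking-versatility) indices for one group."""

    shells: dict[str, int]
    group: str = ""

    @property
    def max_shell(self) -> int:
        return max(self.shells.values(), default=0)

    @property
    def nested_core_count(self) -> int:
        """Number of distinct nonzero shell values (nested cores)."""
        return len({s for s in self.shells.values() if s > 0})


@dataclass
class CoreComparison:
    """Cross-group bookkeeping of innermost-core membership."""

    innermost: dict[str, set[str]]
    shared_by_all: set[str]
    shared_by_at_least_two: set[str]

    @property
    def counts(self) -> dict[str, int]:
        out = {g: len(s) for g, s in self.innermost.items()}
        out["shared_by_all"] = len(self.shared_by_all)
        out["shared_by_at_least_two"] = len(self.shared_by_at_least_two)
        return out


def k_core(net: BigramNetwork, k: int) -> BigramNetwork:
    """Greedy peeling: drop vertices of degree < k until none remain.

    Returns the (possibly empty) maximum induced subgraph with minimum
    degree ≥ k.  Removal order cannot change the result; vertices are
    peeled in lexicographic order for determinism all the same.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    g = net.graph.copy()
    while True:
        doomed = sorted(v for v, d in g.degree() if d < k)
        if not doomed:
            break
        g.remove_nodes_from(doomed)
    return BigramNetwork(g, provenance=net.provenance)


def decompose(
    net: BigramNetwork, peripheral: Iterable[str] = (), group: str = ""
) -> ShellIndexTable:
    """Shell index for every vertex: the largest k with v in the k-core.

    Bucket-peeling in O(V + E); within a degree bucket vertices are
    peeled in lexicographic order.  Edge multiplicities are ignored
    (the decomposition is defined on the unweighted topology).
    ``peripheral`` merges extra domains at shell 0 — the domains that
    never occur in a bigram and so sit outside every core.
    """
    g = net.graph
    degree = {v: d for v, d in g.degree()}
    shells: dict[str, int] = {}
    # bucket queue keyed by current degree
    buckets: dict[int, set[str]] = {}
    for v, d in degree.items():
        buckets.setdefault(d, set()).add(v)
    current_k = 0
    remaining = set(g.nodes)
    while remaining:
        d = min(b for b, s in buckets.items() if s)
        current_k = max(current_k, d)
        v = min(buckets[d])
        buckets[d].discard(v)
        shells[v] = current_k
        remaining.discard(v)
        for u in g.neighbors(v):
            if u in remaining:
                du = degree[u]
                buckets[du].discard(u)
                degree[u] = du - 1
                buckets.setdefault(du - 1, set()).add(u)
        if not buckets.get(d):
            buckets.pop(d, None)
    for dom in peripheral:
        shells.setdefault(dom, 0)
    return ShellIndexTable(shells, group=group)


def innermost_core(table: ShellIndexTable) -> set[str]:
    """Domains at the maximum shell — the most networking-versatile.

    Empty when every shell is 0 (no domain sits in any core).
    """
    if not table.shells:
        raise ValueError("empty shell table")
    if table.max_shell == 0:
        return set()
    return {v for v, s in table.shells.items() if s == table.max_shell}


def compare_groups(tables: Sequence[ShellIndexTable]) -> CoreComparison:
    """Innermost-core overlap across genome groups (kingdoms).

    ``shared_by_at_least_two`` is inclusive of ``shared_by_all``.
    """
    if len(tables) < 2:
        raise ValueError("need at least two groups to compare")
    cores = {t.group or f"group{i}": innermost_core(t) for i, t in enumerate(tables)}
    names = list(cores)
    union: set[str] = set().union(*cores.values())
    shared_all = set(cores[names[0]])
    for g in names[1:]:
        shared_all &= cores[g]
    shared_two = {d for d in union if sum(d in cores[g] for g in names) >= 2}
    return CoreComparison(cores, shared_all, shared_two)


def build_group_network(
    archs_by_genome: Mapping[str, Sequence[ProteinArchitecture]],
    grouping: Mapping[str, str],
    max_gap: int = 30,
    include_peripheral: bool = False,
) -> dict[str, BigramNetwork]:
    """Pool genomes into group-level (kingdom) bigram networks.

    Bigram occurrences from all genomes mapped to a group are pooled
    before network construction, so edge counts accumulate across
    member genomes.  With ``include_peripheral`` the group's peripheral
    domains are added as isolated vertices.
    """
    for genome in archs_by_genome:
        if genome not in grouping:
            raise KeyError(f"genome {genome!r} has no group assignment")
    by_group: dict[str, list[ProteinArchitecture]] = {}
    for genome, archs in archs_by_genome.items():
        by_group.setdefault(grouping[genome], []).extend(archs)
    nets = {}
    for group in sorted(by_group):
        archs = by_group[group]
        isolated = peripheral_domains(archs, max_gap) if include_peripheral else ()
        nets[group] = build_network(
            all_bigrams(archs, max_gap), include_isolated=isolated, provenance=group
        )
    return nets


def write_shell_table(
    table: ShellIndexTable, net: BigramNetwork, path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("group\tdomain_id\tshell\tdegree\n")
        for dom in sorted(table.shells):
            deg = net.graph.degree(dom) if dom in net.graph else 0
            out.write(f"{table.group}\t{dom}\t{table.shells[dom]}\t{deg}\n")


def write_core_comparison(cmp: CoreComparison, path: str | Path) -> None:
    payload = {
        "innermost": {g: sorted(s) for g, s in cmp.innermost.items()},
        "shared_by_all": sorted(cmp.shared_by_all),
        "shared_by_at_least_two": sorted(cmp.shared_by_at_least_two),
        "counts": cmp.counts,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
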