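"""Bigram-network container and topology statistics.

The network is an undirected simple graph over domain types.  Each
edge records how many bigram occurrences realised it, but every
statistic here is topological (unweighted): the k-core machinery the
versatility index rests on is defined for unweighted graphs only, and
the counts are carried purely as annotation.

Two conventions are provided for the average shortest distance.  The
"inclusive" convention evaluates

    l = 2 / (n (n + 1)) * sum_{i >= j} d_ij

with the zero diagonal included in the sum, so its denominator counts
the n(n+1)/2 pairs with i >= j.  The "standard" convention is the
usual mean over the n(n-1)/2 distinct unordered pairs.  Both are
computed on the largest connected component, where all distances are
finite.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx

from bigramnet.assignments import Bigram

__all__ = [
    "BigramNetwork",
    "GraphStats",
    "build_network",
    "from_edges",
    "clustering_coefficient",
    "average_clustering",
    "average_distance",
    "degree_histogram",
    "c_of_k",
    "network_stats",
    "write_vertex_stats",
    "write_summary",
]


@dataclass
class BigramNetwork:
    """Undirected simple graph over domain types with bigram counts.

    Wraps a :class:`networkx.Graph` whose edges carry a ``count``
    attribute (total bigram occurrences).  ``provenance`` labels the
    genome or genome group the network was built from.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    provenance: str = ""

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("bigram network must not contain self-loops")

    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_count(self, u: str, v: str) -> int:
        return self.graph.edges[u, v]["count"]

    def degree(self, v: str) -> int:
        return self.graph.degree(v)

    def subgraph(self, vertices: Iterable[str]) -> "BigramNetwork":
        return BigramNetwork(
            nx.Graph(self.graph.subgraph(vertices)), provenance=self.provenance
        )

    def copy(self) -> "BigramNetwork":
        return BigramNetwork(self.graph.copy(), provenance=self.provenance)


def build_network(
    bigrams: Iterable[Bigram | tuple[str, str]],
    include_isolated: Iterable[str] = (),
    provenance: str = "",
) -> BigramNetwork:
    """Collapse bigram occurrences into an undirected simple graph.

    One edge per unordered distinct domain pair, annotated with the
    total occurrence count.  ``include_isolated`` adds vertices with no
    edges (typically the peripheral domain set) so that downstream
    shell tables cover the whole repertoire.
    """
    counts: Counter = Counter()
    for bg in bigrams:
        if isinstance(bg, Bigram):
            a, b = bg.upstream, bg.downstream
        else:
            a, b = bg
        if a == b:
            raise ValueError(f"self-pair {a!r} violates the distinct-domain rule")
        counts[(a, b) if a < b else (b, a)] += 1
    g = nx.Graph()
    g.add_nodes_from(sorted(include_isolated))
    for (a, b), n in sorted(counts.items()):
        g.add_edge(a, b, count=n)
    return BigramNetwork(g, provenance=provenance)


def from_edges(
    edges: Iterable[tuple[str, str]],
    include_isolated: Iterable[str] = (),
    provenance: str = "",
) -> BigramNetwork:
    """Build a network directly from an undirected edge list (count 1 each)."""
    return build_network(list(edges), include_isolated, provenance)


def clustering_coefficient(net: BigramNetwork, v: str) -> float:
    """C(i) = 2 n_i / (k_i (k_i - 1)): realised fraction of neighbour links.

    ``n_i`` counts edges among the neighbours of ``v``.  Zero by
    convention when the degree is below 2 (the formula is undefined
    there).
    """
    if v not in net.graph:
        raise KeyError(f"unknown vertex {v!r}")
    return nx.clustering(net.graph, v)


def average_clustering(net: BigramNetwork) -> float:
    """Mean of C(i) over *all* vertices; isolated vertices contribute 0."""
    if net.n_vertices == 0:
        raise ValueError("average clustering undefined on an empty network")
    return sum(nx.clustering(net.graph).values()) / net.n_vertices


def largest_component(net: BigramNetwork) -> BigramNetwork:
    """Induced subgraph on the largest connected component (ties: lexicographic)."""
    if net.n_vertices == 0:
        raise ValueError("empty network has no components")
    comps = sorted(nx.connected_components(net.graph), key=lambda c: (-len(c), min(c)))
    return net.subgraph(comps[0])


def average_distance(
    net: BigramNetwork,
    convention: Literal["inclusive", "standard"] = "inclusive",
) -> float:
    """Average shortest distance on the largest connected component.

    convention="inclusive": l = 2/(n(n+1)) * Σ_{i≥j} d_ij (zero diagonal
    included in the sum, n(n+1) denominator).
    convention="standard": mean over the n(n−1)/2 distinct pairs.
    """
    lcc = largest_component(net)
    n = lcc.n_vertices
    total = 0
    for _, dists in nx.all_pairs_shortest_path_length(lcc.graph):
        total += sum(dists.values())
    pair_sum = total / 2  # each unordered pair counted twice, diagonal is zero
    if convention == "inclusive":
        return 2.0 * pair_sum / (n * (n + 1))
    if convention == "standard":
        if n < 2:
            return 0.0
        return pair_sum / (n * (n - 1) / 2)
    raise ValueError(f"unknown distance convention {convention!r}")


def degree_histogram(net: BigramNetwork) -> dict[int, int]:
    """n(k): number of vertices with degree exactly k (empty degrees absent)."""
    hist: Counter = Counter(d for _, d in net.graph.degree())
    return dict(sorted(hist.items()))


def c_of_k(net: BigramNetwork) -> dict[int, float]:
    """c(k): mean clustering coefficient over vertices of degree k."""
    clust = nx.clustering(net.graph)
    by_degree: dict[int, list[float]] = {}
    for v, d in net.graph.degree():
        by_degree.setdefault(d, []).append(clust[v])
    return {k: sum(vals) / len(vals) for k, vals in sorted(by_degree.items())}


@dataclass
class GraphStats:
    """Bundle of the per-network topology statistics."""

    n_vertices: int
    n_edges: int
    degree: dict[str, int]
    clustering: dict[str, float]
    average_clustering: float
    average_distance_inclusive: float
    average_distance_standard: float
    degree_hist: dict[int, int]
    ck: dict[int, float]
    component_sizes: list[int]


def network_stats(net: BigramNetwork) -> GraphStats:
    """Compute the full statistic bundle for one network."""
    clust = nx.clustering(net.graph)
    return GraphStats(
        n_vertices=net.n_vertices,
        n_edges=net.n_edges,
        degree={v: d for v, d in net.graph.degree()},
        clustering=dict(clust),
        average_clustering=average_clustering(net),
        average_distance_inclusive=average_distance(net, "inclusive"),
        average_distance_standard=average_distance(net, "standard"),
        degree_hist=degree_histogram(net),
        ck=c_of_k(net),
        component_sizes=sorted(
            (len(c) for c in nx.connected_components(net.graph)), reverse=True
        ),
    )


def write_vertex_stats(stats: GraphStats, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("domain_id\tdegree\tclustering\n")
        for v in sorted(stats.degree):
            out.write(f"{v}\t{stats.degree[v]}\t{stats.clustering[v]:.6f}\n")


def write_summary(stats: GraphStats, path: str | Path) -> None:
    summary = {
        "n_vertices": stats.n_vertices,
        "n_edges": stats.n_edges,
        "average_clustering": stats.average_clustering,
        "average_distance_inclusive": stats.average_distance_inclusive,
        "average_distance_standard": stats.average_distance_standard,
        "component_sizes": stats.component_sizes,
    }
    Path(path).write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
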