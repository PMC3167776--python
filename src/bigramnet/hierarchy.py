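"""Topological overlap, average-linkage clustering and module cuts.

The topological overlap of two vertices blends shared neighbourhood
with direct linkage:

    OT(i, j) = (|N(i) ∩ N(j)| + a_ij) / min(k_i, k_j)

with a_ij = 1 for an edge, OT(i, i) = 1, and OT = 0 whenever either
vertex is isolated.  Two domains overlap fully when the lower-degree
one's neighbourhood (plus any direct link) is contained in the
other's — the signature of membership in the same module.  Converting
to dissimilarity d = 1 − OT and applying unweighted average-linkage
clustering gives a dendrogram; cutting it at a descending ladder of
heights (0.95, 0.9, 0.7, 0.5, 0.3 by default) peels nested modules:
each lower cut refines the partition above it.

A "plus_one" variant with denominator min(k_i, k_j) + 1 − a_ij is
available; it differs only in normalisation and is kept behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from bigramnet.graph import BigramNetwork

__all__ = [
    "TOMatrix",
    "Dendrogram",
    "ModuleHierarchy",
    "DEFAULT_THRESHOLDS",
    "topological_overlap",
    "average_linkage",
    "cut_modules",
    "module_hierarchy",
    "to_newick",
    "write_module_table",
]

DEFAULT_THRESHOLDS = (0.95, 0.9, 0.7, 0.5, 0.3)


@dataclass
class TOMatrix:
    """Symmetric topological-overlap matrix with its vertex order."""

    matrix: np.ndarray
    vertices: list[str]

    def overlap(self, u: str, v: str) -> float:
        i, j = self.vertices.index(u), self.vertices.index(v)
        return float(self.matrix[i, j])

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.matrix


@dataclass
class Dendrogram:
    """Average-linkage merge tree over labelled leaves.

    ``merge`` is a scipy linkage matrix: row t merges clusters
    merge[t, 0] and merge[t, 1] at height merge[t, 2].
    """

    merge: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merge[:, 2] if self.merge.size else np.empty(0)


@dataclass
class ModuleHierarchy:
    """Partitions of the vertex set at each threshold, coarsest first.

    Thresholds are heights in dissimilarity units d = 1 − OT: the
    partition at threshold t consists of maximal clusters whose
    internal merges all happen strictly below t.  Lower thresholds
    refine higher ones.
    """

    dendrogram: Dendrogram
    partitions: dict[float, list[frozenset[str]]]
    component_of: dict[str, int] = field(default_factory=dict)

    def modules_at(self, threshold: float) -> list[frozenset[str]]:
        return self.partitions[threshold]

    def n_modules(self, threshold: float, min_size: int = 1) -> int:
        return sum(1 for m in self.partitions[threshold] if len(m) >= min_size)


def topological_overlap(
    net: BigramNetwork, variant: Literal["ravasz", "plus_one"] = "ravasz"
) -> TOMatrix:
    """Compute the topological overlap matrix over all vertices.

    Vertices are ordered lexicographically; the matrix is symmetric
    with unit diagonal and entries in [0, 1].
    """
    if net.n_vertices == 0:
        raise ValueError("empty network")
    vertices = sorted(net.graph.nodes)
    a = nx.to_numpy_array(net.graph, nodelist=vertices, weight=None)
    deg = a.sum(axis=1)
    shared = a @ a  # (i,j): number of common neighbours (no self-loops)
    j_mat = shared + a
    if variant == "ravasz":
        denom = np.minimum.outer(deg, deg)
    elif variant == "plus_one":
        denom = np.minimum.outer(deg, deg) + 1.0 - a
    else:
        raise ValueError(f"unknown TOM variant {variant!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        om = np.where(denom > 0, j_mat / denom, 0.0)
    np.clip(om, 0.0, 1.0, out=om)
    np.fill_diagonal(om, 1.0)
    return TOMatrix(om, vertices)


def average_linkage(
    dissim: np.ndarray, labels: Sequence[str]
) -> Dendrogram:
    """Unweighted average-linkage (UPGMA) agglomeration.

    Ties in merge order are broken deterministically by sorting leaves
    lexicographically before linkage, which fixes scipy's scan order.
    """
    d = np.asarray(dissim, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    order = np.argsort(np.asarray(labels, dtype=object))
    labels_sorted = [labels[i] for i in order]
    d = d[np.ix_(order, order)]
    if len(labels_sorted) == 1:
        return Dendrogram(np.empty((0, 4)), labels_sorted)
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(z, labels_sorted)


def cut_modules(
    dendrogram: Dendrogram,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    component_of: dict[str, int] | None = None,
) -> ModuleHierarchy:
    """Cut the dendrogram at each threshold into disjoint modules.

    At threshold t a module is a maximal cluster whose internal merge
    heights are all strictly below t; merges at exactly t are split.
    """
    for t in thresholds:
        if not (0.0 < t <= 1.0):
            raise ValueError(f"threshold {t} outside (0, 1]")
    partitions: dict[float, list[frozenset[str]]] = {}
    labels = dendrogram.labels
    for t in sorted(thresholds, reverse=True):
        if dendrogram.merge.size == 0:
            flat = np.ones(len(labels), dtype=int)
        else:
            # fcluster merges heights <= t; "strictly below t" needs a nudge
            flat = fcluster(
                dendrogram.merge, np.nextafter(t, -np.inf), criterion="distance"
            )
        groups: dict[int, set[str]] = {}
        for lab, cid in zip(labels, flat):
            groups.setdefault(int(cid), set()).add(lab)
        partitions[t] = sorted(
            (frozenset(g) for g in groups.values()), key=lambda m: min(m)
        )
    return ModuleHierarchy(dendrogram, partitions, component_of or {})


def module_hierarchy(
    net: BigramNetwork,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    variant: Literal["ravasz", "plus_one"] = "ravasz",
) -> ModuleHierarchy:
    """TOM → dissimilarity → average linkage → threshold cuts, end to end.

    All vertices are clustered in one pooled matrix.  Vertices in
    different connected components have overlap exactly 0, hence
    dissimilarity exactly 1, so under average linkage components can
    only merge at height 1.0 — every cut below 1 yields the same
    partition as clustering each component separately.  Component
    membership is recorded for reporting.
    """
    tom = topological_overlap(net, variant=variant)
    dend = average_linkage(tom.dissimilarity, tom.vertices)
    comp_of: dict[str, int] = {}
    comps = sorted(nx.connected_components(net.graph), key=lambda c: (-len(c), min(c)))
    for i, comp in enumerate(comps):
        for v in comp:
            comp_of[v] = i
    return cut_modules(dend, thresholds, comp_of)


def _newick_node(node, parent_height: float, labels: list[str]) -> str:
    length = max(parent_height - node.dist, 0.0)
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _newick_node(node.left, node.dist, labels)
    right = _newick_node(node.right, node.dist, labels)
    return f"({left},{right}):{length:.6g}"


def to_newick(dendrogram: Dendrogram) -> str:
    """Export the dendrogram as Newick, branch lengths = height differences."""
    if dendrogram.n_leaves == 1:
        return f"{dendrogram.labels[0]}:0;"
    root = to_tree(dendrogram.merge)
    left = _newick_node(root.left, root.dist, dendrogram.labels)
    right = _newick_node(root.right, root.dist, dendrogram.labels)
    return f"({left},{right}):0;"


def write_module_table(hierarchy: ModuleHierarchy, path: str | Path) -> None:
    """TSV of (threshold, module id, domain, component); deterministic order."""
    with open(path, "w", encoding="utf-8") as out:
        out.write("threshold\tmodule_id\tdomain_id\tcomponent\n")
        for t in sorted(hierarchy.partitions, reverse=True):
            for mid, module in enumerate(hierarchy.partitions[t]):
                for dom in sorted(module):
                    comp = hierarchy.component_of.get(dom, -1)
                    out.write(f"{t}\t{mid}\t{dom}\t{comp}\n")
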