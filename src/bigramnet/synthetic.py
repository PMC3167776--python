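"""Synthetic genomes with planted network structure.

Every pipeline stage is validated against generated data whose ground
truth is known by construction: assignment tables whose adjacent
domain pairs realise a chosen target network, planted peripheral
domains, hierarchical scale-free graphs with the C(k) ~ k^-1
signature, clique-plus-tree graphs with known shell indices, and
multi-group plans with prescribed innermost-core overlaps.

Gap lengths are drawn from the two sides of the 30-residue adjacency
rule: linked pairs uniform on [0, 29], unlinked on [30, 100].  Only
the threshold matters to the pipeline, so uniform supports straddling
it are sufficient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from bigramnet.assignments import DomainHit, ProteinArchitecture, write_assignments
from bigramnet.conservation import AlignmentFamily
from bigramnet.graph import BigramNetwork, build_network, from_edges

__all__ = [
    "SyntheticSpec",
    "GroupPlan",
    "GroupPlanResult",
    "hierarchical_network",
    "planted_core_network",
    "genome_from_network",
    "multi_group_plan",
    "make_family",
    "simulate",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic genome.

    Defaults describe a small but architecturally realistic genome:
    a few hundred walk-sampled multi-domain proteins (mean ~3 domains
    per architecture), domain lengths of 40–200 residues, linked gaps
    uniform on [0, 29] and unlinked on [30, 100], and a planted set of
    peripheral domains seen only in single-domain proteins or at
    unlinked distances.
    """

    seed: int = 0
    genome_id: str = "synth"
    n_walk_proteins: int = 200
    mean_walk_length: float = 3.0
    max_walk_length: int = 6
    domain_length: tuple[int, int] = (40, 200)
    linked_gap: tuple[int, int] = (0, 29)
    unlinked_gap: tuple[int, int] = (30, 100)
    n_peripheral: int = 10
    #: fraction of peripheral domains additionally shown at unlinked
    #: distance inside a multi-domain protein (the rest appear only in
    #: single-domain proteins)
    peripheral_attached_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.linked_gap[0] <= self.linked_gap[1] < 30):
            raise ValueError("linked gap support must lie within [0, 29]")
        if self.unlinked_gap[0] < 30:
            raise ValueError("unlinked gap support must start at >= 30")
        if not (0.0 <= self.peripheral_attached_fraction <= 1.0):
            raise ValueError("peripheral_attached_fraction must be in [0, 1]")


def hierarchical_network(base_size: int, levels: int) -> BigramNetwork:
    """Deterministic hierarchical scale-free graph (replica construction).

    Level 1 is a clique of ``base_size`` vertices with a designated
    hub.  Each further level makes ``base_size − 1`` replicas of the
    current structure and wires every replica's peripheral (bottom
    level) vertex to the original hub.  The result has
    ``base_size**levels`` vertices and the hierarchical-modularity
    signature: high clustering at low degree decaying roughly as
    C(k) ~ k^-1 toward the hubs.
    """
    if base_size < 3 or levels < 1:
        raise ValueError("need base_size >= 3 and levels >= 1")
    b = base_size
    g = nx.complete_graph(b)
    center = 0
    peripherals = list(range(1, b))
    for level in range(2, levels + 1):
        block = b ** (level - 1)
        template = g.copy()
        new_peripherals = []
        for i in range(1, b):
            offset = i * block
            g.add_edges_from((u + offset, v + offset) for u, v in template.edges)
            new_peripherals.extend(p + offset for p in peripherals)
        g.add_edges_from((p, center) for p in new_peripherals)
        peripherals = new_peripherals
    width = len(str(b**levels - 1))
    mapping = {v: f"D{v:0{width}d}" for v in g.nodes}
    net = from_edges(
        (mapping[u], mapping[v]) for u, v in sorted(g.edges)
    )
    net.provenance = f"hierarchical(base={b}, levels={levels})"
    return net


def planted_core_network(
    core_size: int = 8,
    trees_per_core_vertex: int = 1,
    tree_depth: int = 2,
) -> tuple[BigramNetwork, dict[str, int]]:
    """Clique of core domains with pendant paths: known shell indices.

    Returns the network and the planted shell truth: clique members
    have shell ``core_size − 1``; every path vertex has shell 1
    (pendant trees peel at k = 2).
    """
    if core_size < 3:
        raise ValueError("core clique needs >= 3 vertices")
    core = [f"CORE{i:02d}" for i in range(core_size)]
    edges = [(a, b) for i, a in enumerate(core) for b in core[i + 1 :]]
    truth = {c: core_size - 1 for c in core}
    for ci, c in enumerate(core):
        for t in range(trees_per_core_vertex):
            prev = c
            for d in range(tree_depth):
                leaf = f"TREE{ci:02d}_{t}_{d}"
                edges.append((prev, leaf))
                truth[leaf] = 1
                prev = leaf
    return from_edges(edges), truth


def planted_modular_network(
    n_top: int = 3,
    cliques_per_top: int = 2,
    clique_size: int = 4,
) -> tuple[BigramNetwork, dict[str, int], dict[str, int]]:
    """Two-level modular graph with known module labels at both levels.

    Sub-modules are cliques.  Cliques within a top-level module are
    chained by *two* bridge edges (strong coupling); consecutive
    top-level modules are chained by a *single* bridge edge (weak
    coupling).  Under the topological-overlap dissimilarity this
    yields three separated height bands in the average-linkage
    dendrogram: cliques complete their internal merges first, cliques
    of one top module merge next, and top modules merge last — so at
    the default cut ladder the 0.95 cut recovers the top-level
    modules and the 0.7 cut recovers the sub-modules exactly.

    Returns (network, top_label per vertex, sub_label per vertex).
    """
    if clique_size < 4 or cliques_per_top < 2 or n_top < 2:
        raise ValueError("need clique_size >= 4, cliques_per_top >= 2, n_top >= 2")
    edges: list[tuple[str, str]] = []
    top_of: dict[str, int] = {}
    sub_of: dict[str, int] = {}

    def vname(t: int, c: int, v: int) -> str:
        return f"M{t}_{c}_{v:02d}"

    sub_id = 0
    for t in range(n_top):
        for c in range(cliques_per_top):
            members = [vname(t, c, v) for v in range(clique_size)]
            for name in members:
                top_of[name] = t
                sub_of[name] = sub_id
            edges.extend(
                (a, b) for i, a in enumerate(members) for b in members[i + 1 :]
            )
            sub_id += 1
        for c in range(cliques_per_top - 1):
            # two bridges: strong intra-top coupling
            edges.append((vname(t, c, 0), vname(t, c + 1, 0)))
            edges.append((vname(t, c, 1), vname(t, c + 1, 1)))
    for t in range(n_top - 1):
        # one bridge: weak inter-top coupling
        edges.append((vname(t, 0, 2), vname(t + 1, 0, 3)))
    return from_edges(edges), top_of, sub_of


def _walk_lengths(rng: np.random.Generator, spec: SyntheticSpec, n: int) -> np.ndarray:
    # geometric architecture lengths >= 2, truncated at max_walk_length
    p = 1.0 / max(spec.mean_walk_length - 1.0, 1.0)
    lengths = 2 + rng.geometric(p, size=n) - 1
    return np.minimum(lengths, spec.max_walk_length)


def genome_from_network(
    net: BigramNetwork, spec: SyntheticSpec
) -> list[ProteinArchitecture]:
    """Emit proteins whose adjacent distinct-domain pairs realise ``net``.

    Coverage: one two-domain protein per network edge guarantees every
    edge is realised at least once; further multi-domain proteins are
    random walks on the network (consecutive architecture positions
    are always network edges, so no spurious edge can arise).  Planted
    peripheral domains (``PER...``) appear only in single-domain
    proteins or at unlinked (>= 30 residue) distances.  Deterministic
    for a given spec (same seed → byte-identical table).
    """
    if net.n_vertices == 0:
        raise ValueError("target network is empty")
    rng = np.random.default_rng(spec.seed)
    adjacency = {v: sorted(net.graph.neighbors(v)) for v in net.graph.nodes}
    archs: list[ProteinArchitecture] = []
    counter = 0

    def new_protein(domains: Sequence[str], gaps: Sequence[int]) -> None:
        nonlocal counter
        counter += 1
        hits = []
        pos = 1
        for i, dom in enumerate(domains):
            if i > 0:
                pos += gaps[i - 1] + 1
            length = int(rng.integers(spec.domain_length[0], spec.domain_length[1] + 1))
            hits.append(DomainHit(dom, ((pos, pos + length - 1),)))
            pos = pos + length - 1
        archs.append(ProteinArchitecture(f"P{counter:05d}", spec.genome_id, hits))

    def linked_gap() -> int:
        return int(rng.integers(spec.linked_gap[0], spec.linked_gap[1] + 1))

    def unlinked_gap() -> int:
        return int(rng.integers(spec.unlinked_gap[0], spec.unlinked_gap[1] + 1))

    # 1. edge coverage
    for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
        new_protein([a, b], [linked_gap()])
    # 2. isolated target vertices appear as single-domain proteins
    for v in sorted(net.graph.nodes):
        if net.graph.degree(v) == 0:
            new_protein([v], [])
    # 3. walk-sampled multi-domain proteins
    lengths = _walk_lengths(rng, spec, spec.n_walk_proteins)
    non_isolated = sorted(v for v in net.graph.nodes if net.graph.degree(v) > 0)
    for length in lengths:
        if not non_isolated:
            break
        walk = [non_isolated[rng.integers(len(non_isolated))]]
        while len(walk) < length:
            nbrs = adjacency[walk[-1]]
            walk.append(nbrs[rng.integers(len(nbrs))])
        new_protein(walk, [linked_gap() for _ in walk[1:]])
    # 4. planted peripheral domains
    for i in range(spec.n_peripheral):
        per = f"PER{i:03d}"
        if (
            rng.random() < spec.peripheral_attached_fraction
            and non_isolated
        ):
            host = non_isolated[rng.integers(len(non_isolated))]
            new_protein([host, per], [unlinked_gap()])
        else:
            new_protein([per], [])
    return archs


@dataclass
class GroupPlan:
    """Planned cross-group innermost-core overlap structure.

    ``shared_by_at_least_two`` is inclusive of ``shared_by_all``; the
    excess is distributed over group pairs, each such domain placed in
    exactly two groups' cores.
    """

    n_groups: int = 4
    shared_by_all: int = 6
    shared_by_at_least_two: int = 18
    genomes_per_group: int = 2
    min_core_size: int = 0  # 0: derived from the plan
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("a group comparison needs >= 2 groups")
        if self.shared_by_at_least_two < self.shared_by_all:
            raise ValueError("shared-by-all must be a subset of shared-by->=2")


@dataclass
class GroupPlanResult:
    networks: dict[str, BigramNetwork]
    grouping: dict[str, str]  # genome -> group
    planted_cores: dict[str, set[str]]
    archs_by_genome: dict[str, list[ProteinArchitecture]] = field(default_factory=dict)


def multi_group_plan(plan: GroupPlan, with_genomes: bool = False) -> GroupPlanResult:
    """Build per-group networks whose innermost cores overlap as planned.

    Each group's innermost core is a clique: the globally shared
    domains, the pair-shared domains allotted to pairs containing the
    group, and group-specific filler domains padding cliques to
    distinct sizes.  Pendant paths of group-specific domains (shell 1)
    surround each clique, so the clique is exactly the innermost core.
    With ``with_genomes`` each group also gets assignment-table
    genomes realising its network.
    """
    groups = [f"G{i}" for i in range(plan.n_groups)]
    common = [f"COM{i:02d}" for i in range(plan.shared_by_all)]
    n_pairwise = plan.shared_by_at_least_two - plan.shared_by_all
    pairs = [
        (i, j) for i in range(plan.n_groups) for j in range(i + 1, plan.n_groups)
    ]
    pair_domains: dict[int, list[str]] = {i: [] for i in range(plan.n_groups)}
    for d in range(n_pairwise):
        i, j = pairs[d % len(pairs)]
        name = f"PAIR{d:02d}"
        pair_domains[i].append(name)
        pair_domains[j].append(name)

    cores: dict[str, set[str]] = {}
    networks: dict[str, BigramNetwork] = {}
    grouping: dict[str, str] = {}
    archs_by_genome: dict[str, list[ProteinArchitecture]] = {}
    max_members = max(
        (len(common) + len(pair_domains[i]) for i in range(plan.n_groups)), default=0
    )
    base_size = max(plan.min_core_size, max_members + 2, 4)
    for gi, group in enumerate(groups):
        members = list(common) + pair_domains[gi]
        target_size = base_size + gi  # distinct clique sizes across groups
        fillers = [
            f"{group}_FILL{j:02d}" for j in range(target_size - len(members))
        ]
        clique = members + fillers
        edges = [
            (a, b) for i, a in enumerate(sorted(clique)) for b in sorted(clique)[i + 1 :]
        ]
        # pendant paths (shell 1) keep the clique as the unique innermost core
        for ci, c in enumerate(sorted(clique)[: max(3, target_size // 2)]):
            prev = c
            for depth in range(2):
                leaf = f"{group}_T{ci:02d}_{depth}"
                edges.append((prev, leaf))
                prev = leaf
        net = from_edges(edges, provenance=group)
        networks[group] = net
        cores[group] = set(clique)
        if with_genomes:
            for g in range(plan.genomes_per_group):
                genome_id = f"{group.lower()}_genome{g}"
                spec = SyntheticSpec(
                    seed=plan.seed + 1000 * gi + g,
                    genome_id=genome_id,
                    n_walk_proteins=50,
                    n_peripheral=3,
                )
                archs_by_genome[genome_id] = genome_from_network(net, spec)
                grouping[genome_id] = group
        else:
            grouping[f"{group.lower()}_genome0"] = group
    return GroupPlanResult(networks, grouping, cores, archs_by_genome)


def make_family(
    label: str,
    n_members: int,
    length: int = 120,
    substitution_prob: float = 0.1,
    seed: int = 0,
) -> AlignmentFamily:
    """Alignment family with controllable expected pairwise identity.

    Members are independent mutants of a random ancestor: each site
    substitutes with probability p to a uniformly random *different*
    residue, so two members match at a site with probability
    (1−p)² + p²/19, giving expected identity ≈ 100·((1−p)² + p²/19).
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    ancestor = rng.integers(0, len(aa), size=length)
    seqs = []
    for _ in range(n_members):
        member = ancestor.copy()
        mutate = rng.random(length) < substitution_prob
        shifts = rng.integers(1, len(aa), size=int(mutate.sum()))
        member[mutate] = (member[mutate] + shifts) % len(aa)
        seqs.append("".join(aa[member]))
    ids = [f"{label}_{i:03d}" for i in range(n_members)]
    return AlignmentFamily(label, ids, seqs)


def simulate(
    outdir: str | Path,
    spec: SyntheticSpec | None = None,
    plan: GroupPlan | None = None,
) -> dict:
    """Write a full synthetic fixture: assignments, grouping, truth JSON.

    Uses a multi-group plan (4 kingdoms by default) with genomes; the
    truth file records the planted per-group networks, innermost
    cores, and per-genome peripheral domains.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan = plan or GroupPlan(seed=(spec.seed if spec else 0))
    result = multi_group_plan(plan, with_genomes=True)
    all_archs = [
        a for genome in sorted(result.archs_by_genome)
        for a in result.archs_by_genome[genome]
    ]
    write_assignments(all_archs, outdir / "assignments.tsv")
    with open(outdir / "grouping.tsv", "w", encoding="utf-8") as out:
        out.write("genome_id\tgroup\n")
        for genome in sorted(result.grouping):
            out.write(f"{genome}\t{result.grouping[genome]}\n")
    truth = {
        "planted_cores": {g: sorted(c) for g, c in result.planted_cores.items()},
        "planted_edges": {
            g: sorted([sorted(e) for e in net.graph.edges])
            for g, net in result.networks.items()
        },
        "shared_by_all": plan.shared_by_all,
        "shared_by_at_least_two": plan.shared_by_at_least_two,
        "seed": plan.seed,
    }
    (outdir / "truth.json").write_text(
        json.dumps(truth, indent=2) + "\n", encoding="utf-8"
    )
    return truth
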