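"""Degree-preserving random ensembles for observed-vs-null comparison.

High average clustering relative to degree-matched random graphs is
the modularity signal: the randomization keeps every vertex's degree
but rewires who links to whom, destroying triangles and module
structure while holding the degree sequence fixed.  Randomization is
by repeated double-edge swaps on a copy of the observed graph; swaps
that would create a self-loop or a parallel edge are rejected, so the
result is always a simple graph with exactly the observed degree
sequence.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np

from bigramnet.graph import BigramNetwork, average_clustering, average_distance

__all__ = [
    "NullEnsembleSummary",
    "StatResult",
    "DEFAULT_STATISTICS",
    "randomize",
    "ensemble_compare",
    "write_summary_json",
]

#: Statistics available to :func:`ensemble_compare` by name.
DEFAULT_STATISTICS: dict[str, Callable[[BigramNetwork], float]] = {
    "average_clustering": average_clustering,
    "average_distance": lambda net: average_distance(net, "inclusive"),
}


@dataclass
class StatResult:
    observed: float
    null_mean: float
    null_sd: float
    z: float | None  # None when the ensemble is degenerate (sd == 0)
    degenerate: bool


@dataclass
class NullEnsembleSummary:
    stats: dict[str, StatResult]
    n_replicates: int
    seed: int
    replicate_values: dict[str, list[float]] = field(default_factory=dict)


def randomize(
    net: BigramNetwork, seed: int, swap_factor: float = 10.0
) -> BigramNetwork:
    """One degree-preserving randomization of ``net``.

    Attempts ``swap_factor * |E|`` successful double-edge swaps.
    Graphs whose degree sequence admits no swap (e.g. a star) are
    returned unchanged with a warning.  Deterministic for a given
    seed.  Edge counts are reset to 1: the null ensemble is purely
    topological.
    """
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    g.add_edges_from(net.graph.edges)
    m = g.number_of_edges()
    if m < 2:
        warnings.warn("fewer than 2 edges: no swap possible, returning a copy")
        nx.set_edge_attributes(g, 1, "count")
        return BigramNetwork(g, provenance=net.provenance)
    nswap = max(1, math.ceil(swap_factor * m))
    try:
        nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap, seed=seed)
    except nx.NetworkXException:
        # rigid degree sequence (or pathological rejection streak):
        # whatever swaps succeeded already preserved the degrees
        warnings.warn(
            "degree sequence admits no (further) swap; "
            "returning graph after partial randomization"
        )
    nx.set_edge_attributes(g, 1, "count")
    return BigramNetwork(g, provenance=net.provenance)


def ensemble_compare(
    net: BigramNetwork,
    n_replicates: int = 1000,
    statistics: Sequence[str] = ("average_clustering", "average_distance"),
    seed: int = 0,
    swap_factor: float = 10.0,
    registry: Mapping[str, Callable[[BigramNetwork], float]] | None = None,
    keep_replicates: bool = False,
) -> NullEnsembleSummary:
    """Observed statistics against a degree-preserving null ensemble.

    Replicate seeds are derived deterministically from the master seed
    (numpy ``SeedSequence`` spawning), so the ensemble is reproducible
    and individual replicates can be regenerated in isolation.
    z = (observed − null mean) / null sd; flagged degenerate when the
    ensemble has zero spread (rigid degree sequences).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    registry = dict(DEFAULT_STATISTICS if registry is None else registry)
    for name in statistics:
        if name not in registry:
            raise KeyError(f"statistic {name!r} is not registered")
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n_replicates)
    ]
    values: dict[str, list[float]] = {name: [] for name in statistics}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rigid graphs warn once per replicate
        for rep_seed in child_seeds:
            rep = randomize(net, seed=rep_seed, swap_factor=swap_factor)
            for name in statistics:
                values[name].append(registry[name](rep))
    stats: dict[str, StatResult] = {}
    for name in statistics:
        observed = registry[name](net)
        arr = np.asarray(values[name], dtype=float)
        mean, sd = float(arr.mean()), float(arr.std(ddof=1))
        degenerate = sd == 0.0
        z = None if degenerate else (observed - mean) / sd
        stats[name] = StatResult(observed, mean, sd, z, degenerate)
    return NullEnsembleSummary(
        stats,
        n_replicates=n_replicates,
        seed=seed,
        replicate_values=values if keep_replicates else {},
    )


def write_summary_json(summary: NullEnsembleSummary, path: str | Path) -> None:
    payload = {
        name: {
            "observed": r.observed,
            "null_mean": r.null_mean,
            "null_sd": r.null_sd,
            "z": r.z,
            "degenerate": r.degenerate,
        }
        for name, r in summary.stats.items()
    }
    payload["n_replicates"] = summary.n_replicates
    payload["seed"] = summary.seed
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
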