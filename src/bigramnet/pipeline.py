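"""End-to-end orchestration: config, staged runs, provenance, report.

Each ``run_*`` function is a thin, file-level wrapper over one library
stage: it reads its inputs, calls the library, writes the stage's
tables plus a provenance JSON (config hash, derived seed, package
version, input checksums), and removes partial outputs on failure.
Stage seeds are derived from the master seed by stable hashing of the
stage name, so any stage can be re-run in isolation and reproduce its
randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

import bigramnet
from bigramnet.assignments import (
    all_bigrams,
    parse_assignments,
    peripheral_domains,
    write_bigram_occurrences,
    write_edge_list,
)
from bigramnet.conservation import (
    compare_sets,
    read_family,
    summarize_family,
    write_family_table,
)
from bigramnet.graph import build_network, network_stats, write_summary, write_vertex_stats
from bigramnet.hierarchy import (
    DEFAULT_THRESHOLDS,
    module_hierarchy,
    to_newick,
    write_module_table,
)
from bigramnet.kcore import (
    build_group_network,
    compare_groups,
    decompose,
    write_core_comparison,
    write_shell_table,
)
from bigramnet.nullmodel import ensemble_compare, write_summary_json
from bigramnet import synthetic

log = logging.getLogger("bigramnet")

__all__ = ["RunConfig", "stage_seed"] + [
    f"run_{s}"
    for s in (
        "extract",
        "stats",
        "null",
        "kcore",
        "modules",
        "conservation",
        "simulate",
        "report",
    )
]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the analysis defaults.

    max_gap 30 residues, module-cut thresholds 0.95/0.9/0.7/0.5/0.3,
    1000 null replicates, "inclusive" distance convention, "ravasz" TOM.
    """

    assignments: str = ""
    grouping: str = ""
    alignments: list[str] = field(default_factory=list)
    core_families: list[str] = field(default_factory=list)
    peripheral_families: list[str] = field(default_factory=list)
    family_blocklist: list[str] = field(default_factory=list)
    max_gap: int = 30
    thresholds: list[float] = field(default_factory=lambda: list(DEFAULT_THRESHOLDS))
    n_random: int = 1000
    seed: int = 0
    distance_convention: str = "inclusive"
    tom_variant: str = "ravasz"
    outdir: str = "bigramnet_out"
    #: skip a stage whose provenance matches this config and whose
    #: outputs all exist
    resume: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def config_hash(self) -> str:
        # outdir/resume excluded: they locate and schedule outputs,
        # they do not define the analysis
        payload = {
            k: v for k, v in asdict(self).items() if k not in ("outdir", "resume")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (stable across runs/platforms)."""
    return (master_seed ^ zlib.crc32(stage.encode())) % (2**31)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _provenance(cfg: RunConfig, stage: str, inputs: Sequence[str | Path]) -> dict:
    return {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": stage_seed(cfg.seed, stage),
        "version": bigramnet.__version__,
        "inputs": {str(p): _checksum(p) for p in inputs if Path(p).exists()},
    }


def _stage(cfg: RunConfig, stage: str, inputs: Sequence[str | Path], outputs, fn):
    """Run one stage; on failure remove partial outputs and re-raise."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov_path = outdir / f"{stage}.provenance.json"
    prov = _provenance(cfg, stage, inputs)
    if cfg.resume and prov_path.exists() and all(Path(p).exists() for p in outputs):
        previous = json.loads(prov_path.read_text(encoding="utf-8"))
        if previous == prov:
            log.info("%s: up to date, skipped (--resume)", stage)
            return None
    try:
        result = fn()
    except Exception:
        for p in outputs:
            Path(p).unlink(missing_ok=True)
        raise
    prov_path.write_text(json.dumps(prov, indent=2) + "\n", encoding="utf-8")
    return result


def _load(cfg: RunConfig):
    by_genome = parse_assignments(cfg.assignments)
    archs = [a for genome in sorted(by_genome) for a in by_genome[genome]]
    return by_genome, archs


def _observed_network(cfg: RunConfig):
    _, archs = _load(cfg)
    periph = peripheral_domains(archs, cfg.max_gap)
    net = build_network(
        all_bigrams(archs, cfg.max_gap), include_isolated=periph, provenance="all"
    )
    return net, periph, archs


def run_extract(cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    outputs = [outdir / "bigrams.tsv", outdir / "edges.tsv", outdir / "peripheral.txt"]

    def fn():
        _, archs = _load(cfg)
        if not archs:
            log.warning("assignment file yielded no proteins; writing empty tables")
        write_bigram_occurrences(archs, outputs[0], cfg.max_gap)
        write_edge_list(archs, outputs[1], cfg.max_gap)
        periph = peripheral_domains(archs, cfg.max_gap)
        outputs[2].write_text("".join(f"{d}\n" for d in sorted(periph)))
        log.info("extract: %d proteins, %d peripheral domains", len(archs), len(periph))

    _stage(cfg, "extract", [cfg.assignments], outputs, fn)


def run_stats(cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    outputs = [outdir / "vertex_stats.tsv", outdir / "network_summary.json"]

    def fn():
        net, _, _ = _observed_network(cfg)
        stats = network_stats(net)
        write_vertex_stats(stats, outputs[0])
        write_summary(stats, outputs[1])
        log.info("stats: |V|=%d |E|=%d", stats.n_vertices, stats.n_edges)

    _stage(cfg, "stats", [cfg.assignments], outputs, fn)


def run_null(cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    outputs = [outdir / "null_summary.json"]

    def fn():
        net, periph, _ = _observed_network(cfg)
        # nulls are topological: drop isolated vertices' zero contribution?
        summary = ensemble_compare(
            net,
            n_replicates=cfg.n_random,
            seed=stage_seed(cfg.seed, "null"),
        )
        write_summary_json(summary, outputs[0])
        for name, r in summary.stats.items():
            log.info("null %s: observed=%.4f null=%.4f±%.4f", name, r.observed,
                     r.null_mean, r.null_sd)

    _stage(cfg, "null", [cfg.assignments], outputs, fn)


def run_kcore(cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    outputs = [outdir / "shells.tsv", outdir / "core_comparison.json"]

    def fn():
        by_genome, archs = _load(cfg)
        periph = peripheral_domains(archs, cfg.max_gap)
        net = build_network(all_bigrams(archs, cfg.max_gap), provenance="all")
        table = decompose(net, peripheral=periph, group="all")
        write_shell_table(table, net, outputs[0])
        log.info("kcore: max shell %d, %d nested cores", table.max_shell,
                 table.nested_core_count)
        if cfg.grouping:
            grouping = _read_grouping(cfg.grouping)
            nets = build_group_network(by_genome, grouping, cfg.max_gap)
            tables = [
                decompose(nets[g], group=g) for g in sorted(nets)
            ]
            if len(tables) >= 2:
                write_core_comparison(compare_groups(tables), outputs[1])
            with open(outdir / "shells_by_group.tsv", "w", encoding="utf-8") as out:
                out.write("group\tdomain_id\tshell\tdegree\n")
                for t in tables:
                    for dom in sorted(t.shells):
                        out.write(
                            f"{t.group}\t{dom}\t{t.shells[dom]}\t"
                            f"{nets[t.group].graph.degree(dom)}\n"
                        )

    _stage(cfg, "kcore", [cfg.assignments, cfg.grouping], outputs, fn)


def run_modules(cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    outputs = [outdir / "modules.tsv", outdir / "dendrogram.nwk"]

    def fn():
        net, _, _ = _observed_network(cfg)
        # isolated vertices carry no overlap signal; cluster the linked graph
        linked = net.subgraph([v for v in net.graph if net.graph.degree(v) > 0])
        hierarchy = module_hierarchy(
            linked, thresholds=cfg.thresholds, variant=cfg.tom_variant
        )
        write_module_table(hierarchy, outputs[0])
        outputs[1].write_text(to_newick(hierarchy.dendrogram) + "\n")
        for t in sorted(cfg.thresholds, reverse=True):
            log.info("modules at %.2f: %d (%d non-singleton)", t,
                     hierarchy.n_modules(t), hierarchy.n_modules(t, min_size=2))

    _stage(cfg, "modules", [cfg.assignments], outputs, fn)


def run_conservation(cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    outputs = [outdir / "conservation.tsv"]

    def fn():
        core = [summarize_family(read_family(p)) for p in cfg.core_families]
        periph = [summarize_family(read_family(p)) for p in cfg.peripheral_families]
        report = compare_sets(core, periph, blocklist=cfg.family_blocklist)
        write_family_table(report, outputs[0])
        log.info(
            "conservation: core mean %.1f%% vs peripheral mean %.1f%%",
            report.core_mean, report.peripheral_mean,
        )

    _stage(
        cfg, "conservation",
        list(cfg.core_families) + list(cfg.peripheral_families), outputs, fn,
    )


def run_simulate(cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    outputs = [outdir / "assignments.tsv", outdir / "grouping.tsv", outdir / "truth.json"]

    def fn():
        synthetic.simulate(
            outdir, plan=synthetic.GroupPlan(seed=stage_seed(cfg.seed, "simulate"))
        )
        log.info("simulate: wrote synthetic fixture to %s", outdir)

    _stage(cfg, "simulate", [], outputs, fn)


def run_report(cfg: RunConfig) -> None:
    """Join degree, shell, coarsest module id and peripheral flag per domain."""
    outdir = Path(cfg.outdir)
    outputs = [outdir / "report.tsv"]

    def fn():
        net, periph, archs = _observed_network(cfg)
        table = decompose(
            net.subgraph([v for v in net.graph if net.graph.degree(v) > 0]),
            peripheral=periph, group="all",
        )
        linked = net.subgraph([v for v in net.graph if net.graph.degree(v) > 0])
        module_of: dict[str, int] = {}
        if linked.n_vertices >= 2:
            hierarchy = module_hierarchy(linked, thresholds=cfg.thresholds,
                                         variant=cfg.tom_variant)
            coarsest = max(cfg.thresholds)
            for mid, module in enumerate(hierarchy.partitions[coarsest]):
                for dom in module:
                    module_of[dom] = mid
        with open(outputs[0], "w", encoding="utf-8") as out:
            out.write("domain_id\tdegree\tshell\tmodule\tperipheral\n")
            for dom in sorted(set(net.graph.nodes) | periph):
                deg = net.graph.degree(dom) if dom in net.graph else 0
                shell = table.shells.get(dom, 0)
                mod = module_of.get(dom, -1)
                flag = int(dom in periph)
                out.write(f"{dom}\t{deg}\t{shell}\t{mod}\t{flag}\n")

    _stage(cfg, "report", [cfg.assignments], outputs, fn)


def _read_grouping(path: str | Path) -> dict[str, str]:
    grouping = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("genome_id\t"):
                continue
            genome, group = line.split("\t")[:2]
            grouping[genome] = group
    return grouping
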