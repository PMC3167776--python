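"""Per-protein domain assignment tables and bigram extraction.

The input is a SUPERFAMILY-style tab-separated table: one row per
domain hit with genome id, protein id, domain (superfamily) id and a
region string.  Regions are 1-based inclusive residue coordinates;
discontinuous domains are written as comma-separated segments
("12-80,140-200") and are treated as a single unit whose envelope
spans from the first start to the last end.

Two domains in the same protein form a *bigram* when they are
consecutive along the sequence, of distinct types, and separated by a
gap of fewer than 30 residues.  Domains that never participate in any
bigram are *network peripheral domains*.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DomainHit",
    "ProteinArchitecture",
    "Bigram",
    "TableDialect",
    "AssignmentParseError",
    "parse_assignments",
    "write_assignments",
    "extract_bigrams",
    "peripheral_domains",
    "homo_pair_count",
    "write_bigram_occurrences",
    "write_edge_list",
]

#: Default adjacency rule: a bigram requires a gap strictly below this
#: many residues ("less than 30 amino acids").
DEFAULT_MAX_GAP = 30


class AssignmentParseError(ValueError):
    """Raised for malformed assignment rows; names the offending line."""


@dataclass(frozen=True)
class DomainHit:
    """One domain hit on a protein, possibly discontinuous.

    Parameters
    ----------
    domain_id : str
        Opaque domain (superfamily) identifier; non-empty.
    segments : tuple of (int, int)
        1-based inclusive residue coordinates, sorted by start.
    """

    domain_id: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.domain_id:
            raise ValueError("domain_id must be non-empty")
        if not self.segments:
            raise ValueError("DomainHit needs at least one segment")
        for start, end in self.segments:
            if start > end:
                raise ValueError(f"segment start {start} > end {end}")
        object.__setattr__(self, "segments", tuple(sorted(self.segments)))

    @property
    def start(self) -> int:
        """Envelope start: first residue of the first segment."""
        return self.segments[0][0]

    @property
    def end(self) -> int:
        """Envelope end: last residue of the last segment."""
        return self.segments[-1][1]


@dataclass
class ProteinArchitecture:
    """Ordered domain hits on one protein (N-terminal to C-terminal)."""

    protein_id: str
    genome_id: str
    hits: list[DomainHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hits = sorted(self.hits, key=lambda h: (h.start, h.end, h.domain_id))

    @property
    def domain_ids(self) -> list[str]:
        return [h.domain_id for h in self.hits]


@dataclass(frozen=True)
class Bigram:
    """One observed adjacent pair of distinct domains, N-side first.

    ``gap`` is the number of residues between the upstream envelope end
    and the downstream envelope start; negative for overlapping hits.
    """

    upstream: str
    downstream: str
    gap: int = 0

    def __post_init__(self) -> None:
        if self.upstream == self.downstream:
            raise ValueError("bigram endpoints must be distinct domains")

    @property
    def edge(self) -> tuple[str, str]:
        """Undirected edge key: endpoints sorted lexicographically."""
        a, b = self.upstream, self.downstream
        return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class TableDialect:
    """Describes the column layout of an assignment table.

    ``columns`` names the positions of the four required fields; extra
    columns are ignored.  Real SUPERFAMILY exports can be adapted by
    reordering without touching the parser.
    """

    columns: tuple[str, str, str, str] = (
        "genome_id",
        "protein_id",
        "domain_id",
        "region",
    )
    sep: str = "\t"
    comment: str = "#"


def _parse_region(region: str, lineno: int) -> tuple[tuple[int, int], ...]:
    segments = []
    for part in region.split(","):
        try:
            start_s, end_s = part.split("-")
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise AssignmentParseError(
                f"line {lineno}: malformed region {region!r}"
            ) from exc
        if end < start:
            raise AssignmentParseError(
                f"line {lineno}: region segment {part!r} has end < start"
            )
        segments.append((start, end))
    return tuple(segments)


def parse_assignments(
    path: str | Path | io.TextIOBase,
    dialect: TableDialect = TableDialect(),
) -> dict[str, list[ProteinArchitecture]]:
    """Read an assignment table into architectures grouped by genome.

    Returns a dict mapping genome id to a list of
    :class:`ProteinArchitecture`, hits sorted by envelope start.
    Comment lines (prefix ``dialect.comment``) and blank lines are
    skipped.  Malformed rows raise :class:`AssignmentParseError` naming
    the 1-based line number.
    """
    if isinstance(path, (str, Path)):
        handle = open(path, encoding="utf-8")
        close = True
    else:
        handle, close = path, False
    col = {name: i for i, name in enumerate(dialect.columns)}
    per_protein: dict[tuple[str, str], list[DomainHit]] = {}
    order: list[tuple[str, str]] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(dialect.comment):
                continue
            fields = line.split(dialect.sep)
            if len(fields) < len(dialect.columns):
                raise AssignmentParseError(
                    f"line {lineno}: expected {len(dialect.columns)} columns, "
                    f"got {len(fields)}"
                )
            genome = fields[col["genome_id"]].strip()
            protein = fields[col["protein_id"]].strip()
            domain = fields[col["domain_id"]].strip()
            region = fields[col["region"]].strip()
            if not (genome and protein and domain):
                raise AssignmentParseError(f"line {lineno}: empty identifier field")
            segments = _parse_region(region, lineno)
            key = (genome, protein)
            if key not in per_protein:
                per_protein[key] = []
                order.append(key)
            per_protein[key].append(DomainHit(domain, segments))
    finally:
        if close:
            handle.close()

    by_genome: dict[str, list[ProteinArchitecture]] = {}
    for genome, protein in order:
        arch = ProteinArchitecture(protein, genome, per_protein[(genome, protein)])
        by_genome.setdefault(genome, []).append(arch)
    return by_genome


def write_assignments(
    archs: Iterable[ProteinArchitecture],
    path: str | Path,
    dialect: TableDialect = TableDialect(),
) -> None:
    """Write architectures back to an assignment table (round-trippable)."""
    with open(path, "w", encoding="utf-8") as out:
        out.write(dialect.comment + dialect.sep.join(dialect.columns) + "\n")
        for arch in archs:
            for hit in arch.hits:
                region = ",".join(f"{s}-{e}" for s, e in hit.segments)
                row = {
                    "genome_id": arch.genome_id,
                    "protein_id": arch.protein_id,
                    "domain_id": hit.domain_id,
                    "region": region,
                }
                out.write(dialect.sep.join(row[c] for c in dialect.columns) + "\n")


def extract_bigrams(
    arch: ProteinArchitecture, max_gap: int = DEFAULT_MAX_GAP
) -> list[Bigram]:
    """Extract bigram occurrences from one architecture, N→C order.

    For each *consecutive* pair of hits, the gap is
    ``start(next) − end(prev) − 1`` residues.  A bigram is emitted iff
    the gap is strictly below ``max_gap`` and the domain types differ.
    Overlapping or nested hits (gap ≤ 0) count as adjacent.  Adjacent
    same-type pairs are never emitted (hetero-duplex rule); see
    :func:`homo_pair_count` for the diagnostic tally.
    """
    out: list[Bigram] = []
    for prev, nxt in zip(arch.hits, arch.hits[1:]):
        gap = nxt.start - prev.end - 1
        if gap < max_gap and prev.domain_id != nxt.domain_id:
            out.append(Bigram(prev.domain_id, nxt.domain_id, gap))
    return out


def homo_pair_count(
    archs: Iterable[ProteinArchitecture], max_gap: int = DEFAULT_MAX_GAP
) -> Counter:
    """Count adjacent same-type pairs within the gap rule, per domain.

    These tandem repeats satisfy the adjacency rule but are excluded
    from bigrams by the distinct-domain requirement; the counter is a
    diagnostic only.
    """
    counts: Counter = Counter()
    for arch in archs:
        for prev, nxt in zip(arch.hits, arch.hits[1:]):
            gap = nxt.start - prev.end - 1
            if gap < max_gap and prev.domain_id == nxt.domain_id:
                counts[prev.domain_id] += 1
    return counts


def peripheral_domains(
    archs: Iterable[ProteinArchitecture], max_gap: int = DEFAULT_MAX_GAP
) -> set[str]:
    """Domains that never participate in any bigram.

    Includes domains found only in single-domain proteins and domains
    that are always at least ``max_gap`` residues from any distinct
    neighbour.
    """
    seen: set[str] = set()
    linked: set[str] = set()
    for arch in archs:
        seen.update(arch.domain_ids)
        for bg in extract_bigrams(arch, max_gap=max_gap):
            linked.add(bg.upstream)
            linked.add(bg.downstream)
    return seen - linked


def write_bigram_occurrences(
    archs: Iterable[ProteinArchitecture],
    path: str | Path,
    max_gap: int = DEFAULT_MAX_GAP,
) -> None:
    """Write one row per bigram occurrence (genome, protein, pair, gap)."""
    with open(path, "w", encoding="utf-8") as out:
        out.write("genome_id\tprotein_id\tupstream\tdownstream\tgap\n")
        for arch in archs:
            for bg in extract_bigrams(arch, max_gap=max_gap):
                out.write(
                    f"{arch.genome_id}\t{arch.protein_id}\t"
                    f"{bg.upstream}\t{bg.downstream}\t{bg.gap}\n"
                )


def write_edge_list(
    archs: Iterable[ProteinArchitecture],
    path: str | Path,
    max_gap: int = DEFAULT_MAX_GAP,
) -> None:
    """Write the undirected edge list with occurrence counts.

    Endpoints are ordered lexicographically within a row and rows are
    sorted, so output is deterministic.
    """
    counts: Counter = Counter()
    for arch in archs:
        for bg in extract_bigrams(arch, max_gap=max_gap):
            counts[bg.edge] += 1
    with open(path, "w", encoding="utf-8") as out:
        out.write("domain_a\tdomain_b\tcount\n")
        for (a, b), n in sorted(counts.items()):
            out.write(f"{a}\t{b}\t{n}\n")


def all_bigrams(
    archs: Iterable[ProteinArchitecture], max_gap: int = DEFAULT_MAX_GAP
) -> list[Bigram]:
    """Concatenate bigram occurrences over a collection of architectures."""
    out: list[Bigram] = []
    for arch in archs:
        out.extend(extract_bigrams(arch, max_gap=max_gap))
    return out
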