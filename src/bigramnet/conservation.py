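"""Pairwise sequence identity within domain families.

Sequence conservation is the evolutionary counterpart of networking
versatility: families of highly versatile (core) domains tend to be
sequence-diverse, while peripheral domains stay conserved.  The
statistic is pairwise percent amino-acid identity within a family's
multiple sequence alignment: for each pair of aligned members,
100 × matches / columns where *both* members have a residue (columns
with a gap in either sequence are dropped from the denominator).
Alignments are precomputed inputs; this module never runs an aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO
from scipy import stats as _scipy_stats

__all__ = [
    "AlignmentFamily",
    "FamilySummary",
    "GroupComparison",
    "read_family",
    "pairwise_identity",
    "summarize_family",
    "compare_sets",
    "write_family_table",
]


@dataclass
class AlignmentFamily:
    """Aligned members of one domain family (equal-length rows)."""

    label: str
    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError(f"family {self.label!r} needs >= 2 aligned sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"family {self.label!r} has unequal sequence lengths")

    @property
    def n_members(self) -> int:
        return len(self.sequences)


@dataclass
class FamilySummary:
    family: str
    n_members: int
    mean_identity: float
    sd_identity: float
    n_pairs: int
    excluded_pairs: int  # pairs with no mutually ungapped column


@dataclass
class GroupComparison:
    """Descriptive rank comparison of two versatility classes."""

    core: list[FamilySummary]
    peripheral: list[FamilySummary]
    core_mean: float
    peripheral_mean: float
    rank_statistic: float | None  # Mann-Whitney U of family means
    rank_pvalue: float | None
    degenerate_variance: bool  # a group with < 2 families


def read_family(path: str | Path, label: str | None = None) -> AlignmentFamily:
    """Load one family from an aligned FASTA file."""
    aln = AlignIO.read(str(path), "fasta")
    return AlignmentFamily(
        label or Path(path).stem,
        [rec.id for rec in aln],
        [str(rec.seq).upper() for rec in aln],
    )


GAPS = frozenset("-.")


def _identity(a: str, b: str) -> float | None:
    compared = matches = 0
    for x, y in zip(a, b):
        if x in GAPS or y in GAPS:
            continue
        compared += 1
        if x == y:
            matches += 1
    if compared == 0:
        return None
    return 100.0 * matches / compared


def pairwise_identity(fam: AlignmentFamily) -> tuple[np.ndarray, FamilySummary]:
    """All-vs-all percent identity matrix plus the family summary.

    The matrix is symmetric with a 100% diagonal; entries for pairs
    with zero mutually ungapped columns are NaN and those pairs are
    excluded (and counted) in the summary.  The summary mean/SD is
    over the included distinct pairs.
    """
    n = fam.n_members
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 100.0)
    vals: list[float] = []
    excluded = 0
    for i in range(n):
        for j in range(i + 1, n):
            ident = _identity(fam.sequences[i], fam.sequences[j])
            if ident is None:
                excluded += 1
                continue
            mat[i, j] = mat[j, i] = ident
            vals.append(ident)
    arr = np.asarray(vals)
    summary = FamilySummary(
        family=fam.label,
        n_members=n,
        mean_identity=float(arr.mean()) if vals else float("nan"),
        sd_identity=float(arr.std(ddof=1)) if len(vals) > 1 else 0.0,
        n_pairs=len(vals),
        excluded_pairs=excluded,
    )
    return mat, summary


def summarize_family(fam: AlignmentFamily) -> FamilySummary:
    return pairwise_identity(fam)[1]


def compare_sets(
    core_families: Sequence[FamilySummary],
    peripheral_families: Sequence[FamilySummary],
    blocklist: Sequence[str] = (),
) -> GroupComparison:
    """Compare identity levels between core and peripheral families.

    ``blocklist`` drops named families before comparison (e.g. tandem
    short-repeat families whose identity statistic is uninformative).
    The location comparison is a two-sided Mann-Whitney U over the
    per-family mean identities, reported descriptively.
    """
    core = [f for f in core_families if f.family not in set(blocklist)]
    periph = [f for f in peripheral_families if f.family not in set(blocklist)]
    if not core or not periph:
        raise ValueError("both versatility classes need at least one family")
    core_means = [f.mean_identity for f in core]
    periph_means = [f.mean_identity for f in periph]
    degenerate = len(core) < 2 or len(periph) < 2
    res = _scipy_stats.mannwhitneyu(core_means, periph_means)
    stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        core=list(core),
        peripheral=list(periph),
        core_mean=float(np.mean(core_means)),
        peripheral_mean=float(np.mean(periph_means)),
        rank_statistic=stat,
        rank_pvalue=p,
        degenerate_variance=degenerate,
    )


def write_family_table(
    comparison: GroupComparison, path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("family\tn_members\tmean_identity\tsd_identity\tclass\n")
        for cls, fams in (("core", comparison.core), ("peripheral", comparison.peripheral)):
            for f in sorted(fams, key=lambda s: s.family):
                out.write(
                    f"{f.family}\t{f.n_members}\t{f.mean_identity:.3f}\t"
                    f"{f.sd_identity:.3f}\t{cls}\n"
                )
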