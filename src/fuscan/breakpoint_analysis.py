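"""Break-end annotation, DNA/RNA reconciliation and clustering QC.

A break end is classified against the gene models into exactly one of
EXONIC, INTRONIC or INTERGENIC. DNA-supported calls are retained only when
an RNA-supported call matches both break ends within a positional slack
*and* both orientations agree; retained calls keep the DNA positions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AnalysisError, ConfigurationError
from .io_formats import (
    RETAINED_LEFT,
    BreakEnd,
    GeneModel,
    Rearrangement,
    make_rearrangement,
)

EXONIC = "EXONIC"
INTRONIC = "INTRONIC"
INTERGENIC = "INTERGENIC"


@dataclass(frozen=True)
class BreakContext:
    category: str
    gene_id: str | None = None
    exon_index: int | None = None

    def __post_init__(self) -> None:
        if self.category not in (EXONIC, INTRONIC, INTERGENIC):
            raise ValueError(f"invalid category {self.category!r}")
        if (self.gene_id is None) != (self.category == INTERGENIC):
            raise ValueError("gene_id present iff not INTERGENIC")
        if (self.exon_index is None) != (self.category != EXONIC):
            raise ValueError("exon_index present iff EXONIC")


def annotate_breakend(
    be: BreakEnd, genes: Sequence[GeneModel]
) -> BreakContext:
    """Classify a break end as EXONIC / INTRONIC / INTERGENIC.

    A position exactly at an exon end (half-open) is intronic. If gene
    bodies overlap, the first gene in (chrom, start) order wins.
    """
    for g in sorted(genes, key=lambda g: (g.body.chrom, g.body.start)):
        if g.body.chrom == be.chrom and g.body.contains(be.pos):
            idx = g.exon_index_at(be.pos)
            if idx is not None:
                return BreakContext(EXONIC, g.gene_id, idx)
            return BreakContext(INTRONIC, g.gene_id)
    return BreakContext(INTERGENIC)


def _ends_match(a: Rearrangement, b: Rearrangement, slack: int) -> bool:
    return (
        a.end1.chrom == b.end1.chrom
        and a.end2.chrom == b.end2.chrom
        and abs(a.end1.pos - b.end1.pos) <= slack
        and abs(a.end2.pos - b.end2.pos) <= slack
        and a.end1.orientation == b.end1.orientation
        and a.end2.orientation == b.end2.orientation
    )


def reconcile(
    dna: Sequence[Rearrangement],
    rna: Sequence[Rearrangement],
    slack: int,
) -> list[Rearrangement]:
    """Keep DNA calls corroborated by an RNA call (positions from DNA).

    Both break-end positions must agree within ``slack`` bp and both
    orientations must be identical. Output is a subset of ``dna`` with
    evidence set to "both".
    """
    if slack < 0:
        raise ConfigurationError("reconciliation slack must be >= 0")
    out = []
    for d in dna:
        if any(_ends_match(d, r, slack) for r in rna):
            out.append(replace(d, evidence="both"))
    return out


def _segment_matches_end(
    chrom: str, start: int, end: int, be: BreakEnd, slack: int
) -> bool:
    """Does an aligned segment abut a break end on its retained side?"""
    if chrom != be.chrom:
        return False
    if be.orientation == RETAINED_LEFT:
        return abs(end - be.pos) <= slack
    return abs(start - be.pos) <= slack


def _segment_on_retained_side(
    chrom: str, start: int, end: int, be: BreakEnd, slack: int, window: int = 1_000
) -> bool:
    if chrom != be.chrom:
        return False
    if be.orientation == RETAINED_LEFT:
        return end <= be.pos + slack and start >= be.pos - window
    return start >= be.pos - slack and end <= be.pos + window


def count_supporting_reads(
    reads: pd.DataFrame, r: Rearrangement, slack: int
) -> tuple[int, int]:
    """(split_count, discordant_pair_count) for one junction.

    ``reads`` carries one row per aligned segment (read, mate, chrom,
    start, end). A split read has, within one mate, a segment ending at
    one break end and a segment starting at the other (orientation-aware).
    A discordant pair has its two mates lying wholly on the retained sides
    of the two break ends.
    """
    if reads.empty:
        return (0, 0)
    split = 0
    split_keys: set[tuple] = set()
    for key, grp in reads.groupby(["read", "mate"], sort=True):
        segs = list(grp.itertuples(index=False))
        if len(segs) < 2:
            continue
        hits1 = any(
            _segment_matches_end(s.chrom, s.start, s.end, r.end1, slack)
            for s in segs
        )
        hits2 = any(
            _segment_matches_end(s.chrom, s.start, s.end, r.end2, slack)
            for s in segs
        )
        if hits1 and hits2:
            split += 1
            split_keys.add(key[0])
    discordant = 0
    for read, grp in reads.groupby("read", sort=True):
        if read in split_keys:
            continue
        mates = {m: list(g.itertuples(index=False)) for m, g in grp.groupby("mate")}
        if len(mates) < 2:
            continue
        m1, m2 = (mates[k] for k in sorted(mates)[:2])

        def side(segs, be):
            return any(
                _segment_on_retained_side(s.chrom, s.start, s.end, be, slack)
                for s in segs
            )

        if (side(m1, r.end1) and side(m2, r.end2)) or (
            side(m1, r.end2) and side(m2, r.end1)
        ):
            discordant += 1
    return (split, discordant)


@dataclass(frozen=True)
class MonoallelicRecord:
    sample_id: str
    gene_id: str
    breakpoint_count: int
    flagged: bool
    positions: tuple[int, ...]


def _cluster_positions(positions: Sequence[int], slack: int) -> int:
    """Number of clusters after single-linkage merging within slack."""
    if not positions:
        return 0
    ordered = sorted(positions)
    clusters = 1
    for a, b in zip(ordered, ordered[1:]):
        if b - a > slack:
            clusters += 1
    return clusters


def check_monoallelic(
    calls: Sequence[Rearrangement],
    genes: Sequence[GeneModel],
    slack: int,
) -> list[MonoallelicRecord]:
    """Per (sample, gene) break-point count; flags genes with > 1 cluster.

    Break ends closer than ``slack`` are merged into a single break point.
    This is a QC report, not a filter.
    """
    grouped: dict[tuple[str, str], list[int]] = {}
    for call in calls:
        for be in (call.end1, call.end2):
            ctx = annotate_breakend(be, genes)
            if ctx.gene_id is not None:
                grouped.setdefault((call.sample_id, ctx.gene_id), []).append(be.pos)
    out = []
    for (sample, gene_id), positions in sorted(grouped.items()):
        n = _cluster_positions(positions, slack)
        out.append(
            MonoallelicRecord(
                sample_id=sample,
                gene_id=gene_id,
                breakpoint_count=n,
                flagged=n > 1,
                positions=tuple(sorted(positions)),
            )
        )
    return out


def minimal_cluster_window(positions: Sequence[int]) -> int:
    """Width of the smallest window containing all break positions."""
    if not positions:
        raise AnalysisError("no break ends supplied")
    return max(positions) - min(positions) + 1


__all__ = [
    "EXONIC",
    "INTRONIC",
    "INTERGENIC",
    "BreakContext",
    "MonoallelicRecord",
    "annotate_breakend",
    "reconcile",
    "count_supporting_reads",
    "check_monoallelic",
    "minimal_cluster_window",
]
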