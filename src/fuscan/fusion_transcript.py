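"""Fusion-transcript reconstruction, translation and frame classification.

The predicted mutant transcript is assembled from the 5' partner's spliced
exons up to the break (an intronic break extends the previous exon through
the retained intron — donor skip/exonisation), followed by any non-template
insert and the partner genomic sequence read in fusion orientation up to a
transcript end. Translation starts at the native start codon; the first
in-frame stop determines the classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import FusionError
from .io_formats import (
    RETAINED_LEFT,
    RETAINED_RIGHT,
    GeneModel,
    GenomicInterval,
    Parameters,
    Rearrangement,
    revcomp,
)

IN_FRAME_FUSION = "IN_FRAME_FUSION"
TRUNCATING = "TRUNCATING"
NON_CODING = "NON_CODING"
UNTERMINATED = "UNTERMINATED"

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class FusionSegment:
    interval: GenomicInterval
    source: str  # gene_id or "intergenic"
    sequence: str


@dataclass
class FusionTranscript:
    """Ordered sequence segments spanning a fusion junction.

    ``junction_offset`` is the transcript coordinate of the break (length of
    the 5'-partner portion); the insert sits immediately after it.
    ``retained_native_length`` is how much of the native *spliced* transcript
    survives 5' of the junction (exonised intron excluded), used for the
    NON_CODING check and regulatory-element loss.
    """

    segments: list[FusionSegment]
    junction_index: int  # number of 5'-partner segments
    insert: str
    gene_id: str
    cds_start: int
    retained_native_length: int
    classification: str | None = None
    stop_offset_codons: int | None = None

    @property
    def junction_offset(self) -> int:
        return sum(len(s.sequence) for s in self.segments[: self.junction_index])

    @property
    def sequence(self) -> str:
        five = "".join(s.sequence for s in self.segments[: self.junction_index])
        three = "".join(s.sequence for s in self.segments[self.junction_index:])
        return five + self.insert + three

    def __len__(self) -> int:
        return sum(len(s.sequence) for s in self.segments) + len(self.insert)


def five_prime_partner(
    r: Rearrangement, genes: Sequence[GeneModel]
) -> tuple[GeneModel, "BreakEnd", "BreakEnd"]:
    """Pick the break end lying in a gene whose promoter side is retained."""
    for be, other in ((r.end1, r.end2), (r.end2, r.end1)):
        for g in genes:
            if g.body.chrom != be.chrom or not g.body.contains(be.pos):
                continue
            promoter_side = RETAINED_LEFT if g.strand != "-" else RETAINED_RIGHT
            if be.orientation == promoter_side:
                return g, be, other
    raise FusionError(
        "neither break end lies in a gene with its promoter retained; "
        "not a transcribable fusion"
    )


def _five_prime_segments(
    gene: GeneModel, break_pos: int, genome: Mapping[str, str]
) -> tuple[list[FusionSegment], int]:
    """Spliced 5' segments up to the break; returns (segments, native bp kept).

    EXONIC break: the broken exon is truncated at the break. INTRONIC
    break: the previous exon is extended through the retained intron to the
    break (splice donor skipped).
    """
    chrom = gene.body.chrom
    seq = genome[chrom]
    fwd = gene.strand != "-"
    segments: list[FusionSegment] = []
    native_kept = 0

    def emit(start: int, end: int) -> None:
        s = seq[start:end]
        iv = GenomicInterval(chrom, start, end, gene.strand)
        segments.append(
            FusionSegment(iv, gene.gene_id, s if fwd else revcomp(s))
        )

    for exon in gene.exons:  # transcript order
        if fwd:
            upstream = exon.end <= break_pos
            inside = exon.contains(break_pos)
        else:
            upstream = exon.start >= break_pos + 1 and not exon.contains(break_pos)
            inside = exon.contains(break_pos)
        if upstream:
            emit(exon.start, exon.end)
            native_kept += len(exon)
        elif inside:
            if fwd:
                if break_pos > exon.start:
                    emit(exon.start, break_pos)
                native_kept += break_pos - exon.start
            else:
                if exon.end > break_pos:
                    emit(break_pos, exon.end)
                native_kept += exon.end - break_pos
            return segments, native_kept
        else:
            # First exon fully 3' of the break: intronic break — exonise the
            # intron between the last retained exon and the break.
            if fwd:
                intron_start = segments[-1].interval.end if segments else gene.body.start
                if break_pos > intron_start:
                    emit(intron_start, break_pos)
            else:
                intron_end = segments[-1].interval.start if segments else gene.body.end
                if intron_end > break_pos:
                    emit(break_pos, intron_end)
            return segments, native_kept
    return segments, native_kept


def build_fusion_transcript(
    r: Rearrangement,
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    transcript_end: int,
    params: Parameters | None = None,
) -> FusionTranscript:
    """Assemble the predicted mutant transcript across the junction.

    ``transcript_end`` is a genomic position at or 3' (in fusion
    orientation) of the partner-side break, typically the called
    polyadenylation cleavage site.
    """
    gene, gene_be, partner_be = five_prime_partner(r, genes)
    segments, native_kept = _five_prime_segments(gene, gene_be.pos, genome)
    junction_index = len(segments)

    pchrom = partner_be.chrom
    pseq = genome[pchrom]
    partner_gene = next(
        (
            g.gene_id
            for g in genes
            if g.body.chrom == pchrom and g.body.contains(partner_be.pos)
        ),
        "intergenic",
    )
    if partner_be.orientation == RETAINED_RIGHT:
        if transcript_end <= partner_be.pos:
            raise FusionError("transcript_end is 5' of the partner break end")
        end = min(transcript_end, len(pseq))
        iv = GenomicInterval(pchrom, partner_be.pos, end, "+")
        segments.append(FusionSegment(iv, partner_gene, pseq[iv.start:iv.end]))
    else:
        if transcript_end >= partner_be.pos:
            raise FusionError("transcript_end is 5' of the partner break end")
        start = max(transcript_end, 0)
        iv = GenomicInterval(pchrom, start, partner_be.pos, "-")
        segments.append(
            FusionSegment(iv, partner_gene, revcomp(pseq[iv.start:iv.end]))
        )

    return FusionTranscript(
        segments=segments,
        junction_index=junction_index,
        insert=r.non_template_insert,
        gene_id=gene.gene_id,
        cds_start=gene.cds_start,
        retained_native_length=native_kept,
    )


def translate_and_classify(
    ft: FusionTranscript, stop_proximity_codons: int = 10
) -> tuple[str, int | None]:
    """Classify the fusion by its first in-frame stop codon.

    Translation starts at the native start codon. TRUNCATING when the stop
    lies within ``stop_proximity_codons`` of the junction (including stops
    straddling or preceding it); IN_FRAME_FUSION when the frame runs
    further into partner sequence before stopping; NON_CODING when the
    break precedes the start codon; UNTERMINATED when no stop occurs
    before the transcript end. Updates ``ft`` in place and returns
    ``(classification, stop_offset_codons)``.
    """
    if ft.retained_native_length <= ft.cds_start:
        ft.classification = NON_CODING
        ft.stop_offset_codons = None
        return NON_CODING, None
    seq = ft.sequence
    junction = ft.junction_offset
    for pos in range(ft.cds_start, len(seq) - 2, 3):
        if seq[pos:pos + 3] in STOP_CODONS:
            offset = (pos - junction) // 3
            cls = TRUNCATING if offset <= stop_proximity_codons else IN_FRAME_FUSION
            ft.classification = cls
            ft.stop_offset_codons = offset
            return cls, offset
    ft.classification = UNTERMINATED
    ft.stop_offset_codons = None
    return UNTERMINATED, None


def frame_compatible(
    upstream_cds_len: int, insert_len: int, downstream_phase: int
) -> bool:
    """True iff the junction preserves the reading frame.

    ``upstream_cds_len`` is counted from the start codon to the junction;
    ``downstream_phase`` is the codon phase (0/1/2) of the first partner
    base in its own coding frame.
    """
    return (upstream_cds_len + insert_len - downstream_phase) % 3 == 0


def regulatory_loss(ft: FusionTranscript, gene: GeneModel) -> list[str]:
    """Labels of annotated transcript elements not fully retained 5' of
    the junction (straddling elements count as lost)."""
    lost = []
    for label, (start, end) in gene.regulatory_elements:
        if end > ft.retained_native_length:
            lost.append(label)
    return lost


__all__ = [
    "IN_FRAME_FUSION",
    "TRUNCATING",
    "NON_CODING",
    "UNTERMINATED",
    "STOP_CODONS",
    "FusionSegment",
    "FusionTranscript",
    "five_prime_partner",
    "build_fusion_transcript",
    "translate_and_classify",
    "frame_compatible",
    "regulatory_loss",
]
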