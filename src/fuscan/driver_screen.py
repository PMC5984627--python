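"""Driver-annotation rules against an established cancer-gene list.

Small variants, copy-number segments and rearrangement break ends are
screened with sharp, literal thresholds: deleterious coding variants in
tumour suppressors; hotspot mutations in oncogenes; focal (< 1 Mb,
strict) homozygous deletions of tumour suppressors; focal amplifications
to at least five total copies that contain the intact oncogene; and
disruptive break ends inside tumour suppressors. Events in genes absent
from the list are dropped by rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import GeneModel, GenomicInterval, Rearrangement

TSG_DELETERIOUS = "TSG_DELETERIOUS"
TSG_HOMDEL_FOCAL = "TSG_HOMDEL_FOCAL"
TSG_DISRUPTED_SV = "TSG_DISRUPTED_SV"
ONC_HOTSPOT = "ONC_HOTSPOT"
ONC_AMP_FOCAL = "ONC_AMP_FOCAL"

_TSG_ROLES = {"TSG", "both"}
_ONC_ROLES = {"oncogene", "both"}

# Consequence annotations accepted as functionally deleterious. The
# annotation itself is an input; this set only interprets it.
DELETERIOUS_CONSEQUENCES = {
    "nonsense",
    "stop_gained",
    "frameshift",
    "start_lost",
    "splice_donor",
    "splice_acceptor",
    "essential_splice",
    "deleterious_missense",
}


@dataclass(frozen=True)
class CopyNumberSegment:
    interval: GenomicInterval
    total_cn: int
    minor_cn: int
    sample_ploidy: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.minor_cn <= self.total_cn:
            raise ValueError("need 0 <= minor_cn <= total_cn")


@dataclass(frozen=True)
class DriverCall:
    gene: str
    rule: str
    evidence: str


def segments_from_table(df: pd.DataFrame) -> list[CopyNumberSegment]:
    """CopyNumberSegment records from a copy-number TSV table."""
    return [
        CopyNumberSegment(
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
            total_cn=int(row.total_cn),
            minor_cn=int(row.minor_cn),
        )
        for row in df.itertuples(index=False)
    ]


def screen_small_variants(
    variants: Sequence[dict], roles: Mapping[str, str]
) -> list[DriverCall]:
    """TSG + deleterious consequence, or oncogene + hotspot flag.

    ``variants`` are annotated records (io_formats.read_vcf) carrying
    gene, consequence and hotspot fields. Everything else is dropped.
    """
    calls = []
    for v in variants:
        gene = v.get("gene")
        role = roles.get(gene)
        if role is None:
            continue
        consequence = v.get("consequence") or ""
        evidence = f"{v.get('chrom')}:{v.get('pos')}:{consequence}"
        if role in _TSG_ROLES and consequence in DELETERIOUS_CONSEQUENCES:
            calls.append(DriverCall(gene, TSG_DELETERIOUS, evidence))
        if role in _ONC_ROLES and v.get("hotspot"):
            calls.append(DriverCall(gene, ONC_HOTSPOT, evidence))
    return calls


def screen_cnv(
    segments: Sequence[CopyNumberSegment],
    genes: Sequence[GeneModel],
    roles: Mapping[str, str],
    focal_max_span: int = 1_000_000,
    amp_min_total_cn: int = 5,
) -> list[DriverCall]:
    """Focal homozygous deletions of TSGs; focal whole-gene amplifications
    of oncogenes.

    "Focal" compares the *segment* span to the threshold and is strict
    (a segment of exactly focal_max_span never calls). Amplification
    requires the gene to be fully contained in the segment.
    """
    listed = [g for g in genes if g.gene_id in roles or g.name in roles]
    calls = []
    for seg in segments:
        focal = seg.interval.span < focal_max_span
        if not focal:
            continue
        for g in listed:
            role = roles.get(g.gene_id, roles.get(g.name))
            evidence = (
                f"{seg.interval.chrom}:{seg.interval.start}-{seg.interval.end}"
                f":cn{seg.total_cn}"
            )
            if (
                role in _TSG_ROLES
                and seg.total_cn == 0
                and seg.interval.overlaps(g.body)
            ):
                calls.append(DriverCall(g.gene_id, TSG_HOMDEL_FOCAL, evidence))
            if (
                role in _ONC_ROLES
                and seg.total_cn >= amp_min_total_cn
                and seg.interval.contains_interval(g.body)
            ):
                calls.append(DriverCall(g.gene_id, ONC_AMP_FOCAL, evidence))
    return calls


def screen_sv(
    rearrangements: Sequence[Rearrangement],
    genes: Sequence[GeneModel],
    roles: Mapping[str, str],
) -> list[DriverCall]:
    """Break ends falling inside a listed tumour suppressor body."""
    calls = []
    for r in rearrangements:
        for be in (r.end1, r.end2):
            for g in genes:
                role = roles.get(g.gene_id, roles.get(g.name))
                if role not in _TSG_ROLES:
                    continue
                if g.body.chrom == be.chrom and g.body.contains(be.pos):
                    calls.append(
                        DriverCall(
                            g.gene_id,
                            TSG_DISRUPTED_SV,
                            f"{be.chrom}:{be.pos}",
                        )
                    )
    return calls


def screen_all(
    variants: Sequence[dict],
    segments: Sequence[CopyNumberSegment],
    rearrangements: Sequence[Rearrangement],
    genes: Sequence[GeneModel],
    roles: Mapping[str, str],
    focal_max_span: int = 1_000_000,
    amp_min_total_cn: int = 5,
) -> list[DriverCall]:
    return (
        screen_small_variants(variants, roles)
        + screen_cnv(segments, genes, roles, focal_max_span, amp_min_total_cn)
        + screen_sv(rearrangements, genes, roles)
    )


__all__ = [
    "TSG_DELETERIOUS",
    "TSG_HOMDEL_FOCAL",
    "TSG_DISRUPTED_SV",
    "ONC_HOTSPOT",
    "ONC_AMP_FOCAL",
    "DELETERIOUS_CONSEQUENCES",
    "CopyNumberSegment",
    "DriverCall",
    "segments_from_table",
    "screen_small_variants",
    "screen_cnv",
    "screen_sv",
    "screen_all",
]
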