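"""Readers/writers for external formats and the shared coordinate model.

All internal coordinates are 0-based half-open on the forward genome strand.
GFF3 and VCF use 1-based closed coordinates on disk; the conversion happens
here and nowhere else (see :func:`to_gff_coords` / :func:`from_gff_coords`).

The module also hosts the canonical domain records shared by every analysis
stage: :class:`GenomicInterval`, :class:`GeneModel`, :class:`BreakEnd`,
:class:`Rearrangement`, :class:`CoverageTrack` and the global
:class:`Parameters` bundle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .errors import ConfigurationError, FormatError

STRANDS = frozenset({"+", "-", "."})

# Break-end orientation. "retained-left" means the retained (transcribed)
# segment lies to the left of the break position and ends at it; BEDPE
# strand "+" maps to retained-left, "-" to retained-right.
RETAINED_LEFT = "retained-left"
RETAINED_RIGHT = "retained-right"
ORIENT_TO_STRAND = {RETAINED_LEFT: "+", RETAINED_RIGHT: "-"}
STRAND_TO_ORIENT = {"+": RETAINED_LEFT, "-": RETAINED_RIGHT}

SVCLASSES = ("deletion", "tandem-duplication", "inversion", "translocation")

_ACGT_RE = re.compile(r"^[ACGT]*$")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_gff_coords(start: int, end: int) -> tuple[int, int]:
    """Convert an internal 0-based half-open interval to GFF3 1-based closed."""
    return start + 1, end


def from_gff_coords(start: int, end: int) -> tuple[int, int]:
    """Convert a GFF3 1-based closed interval to internal 0-based half-open."""
    return start - 1, end


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """Single-transcript gene model.

    ``exons`` are listed in transcript order (5'->3' of the mRNA); for a
    minus-strand gene that is descending genomic order. ``cds_start`` and
    ``cds_end`` are 0-based half-open offsets into the *spliced* transcript.
    ``regulatory_elements`` are ``(label, (start, end))`` pairs, again in
    spliced-transcript coordinates.
    """

    gene_id: str
    name: str
    body: GenomicInterval
    exons: list[GenomicInterval]
    cds_start: int
    cds_end: int
    role: str = "none"
    regulatory_elements: list[tuple[str, tuple[int, int]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for e in self.exons:
            if not self.body.contains_interval(e):
                raise ValueError(
                    f"gene {self.gene_id}: exon {e} outside gene body"
                )
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        expected = genomic if self.strand != "-" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(
                f"gene {self.gene_id}: exons not in transcript order"
            )
        if not (0 <= self.cds_start < self.cds_end <= self.transcript_length):
            raise ValueError(f"gene {self.gene_id}: CDS outside transcript")
        for label, (s, e) in self.regulatory_elements:
            if not (0 <= s < e <= self.transcript_length):
                raise ValueError(
                    f"gene {self.gene_id}: element {label} outside transcript"
                )

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def transcript_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def exon_offsets(self) -> list[int]:
        """Transcript-coordinate start offset of each exon."""
        offsets, acc = [], 0
        for e in self.exons:
            offsets.append(acc)
            acc += len(e)
        return offsets

    def exon_index_at(self, pos: int) -> int | None:
        """1-based exon ordinal (transcript order) containing a genomic pos."""
        for i, e in enumerate(self.exons, start=1):
            if e.contains(pos):
                return i
        return None

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Spliced-transcript offset of a genomic position, if exonic."""
        for off, e in zip(self.exon_offsets(), self.exons):
            if e.contains(pos):
                if self.strand == "-":
                    return off + (e.end - 1 - pos)
                return off + (pos - e.start)
        return None

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        chrom = genome[self.body.chrom]
        parts = []
        for e in self.exons:
            s = chrom[e.start:e.end]
            parts.append(revcomp(s) if self.strand == "-" else s)
        return "".join(parts)


@dataclass(frozen=True)
class Parameters:
    """All tunable analysis parameters with their defaults."""

    polya_motif: str = "AATAAA"
    drop_window: int = 200
    cleavage_offset_min: int = 10
    cleavage_offset_max: int = 30
    norm_scale: float = 1e3
    focal_max_span: int = 1_000_000
    amp_min_total_cn: int = 5
    reconciliation_slack: int = 10
    stop_proximity_codons: int = 10
    peak_fold_threshold: float = 5.0
    peak_background_floor: float = 1.0
    min_base_qual: int = 20
    min_map_qual: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cleavage_offset_min > self.cleavage_offset_max:
            raise ConfigurationError("cleavage_offset_min > cleavage_offset_max")
        positives = {
            "drop_window": self.drop_window,
            "cleavage_offset_min": self.cleavage_offset_min,
            "cleavage_offset_max": self.cleavage_offset_max,
            "norm_scale": self.norm_scale,
            "focal_max_span": self.focal_max_span,
            "amp_min_total_cn": self.amp_min_total_cn,
            "stop_proximity_codons": self.stop_proximity_codons,
            "peak_fold_threshold": self.peak_fold_threshold,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.reconciliation_slack < 0:
            raise ConfigurationError("reconciliation_slack must be >= 0")
        if not _ACGT_RE.match(self.polya_motif) or not self.polya_motif:
            raise ConfigurationError("polya_motif must be a non-empty ACGT string")


@dataclass(frozen=True)
class BreakEnd:
    """One oriented end of a rearrangement junction."""

    chrom: str
    pos: int
    orientation: str  # RETAINED_LEFT or RETAINED_RIGHT

    def __post_init__(self) -> None:
        if self.orientation not in (RETAINED_LEFT, RETAINED_RIGHT):
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if self.pos < 0:
            raise ValueError("negative break position")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def infer_svclass(end1: BreakEnd, end2: BreakEnd) -> str:
    """Structural-variant class implied by chromosomes and orientations."""
    if end1.chrom != end2.chrom:
        return "translocation"
    o1, o2 = end1.orientation, end2.orientation
    if o1 == RETAINED_LEFT and o2 == RETAINED_RIGHT:
        return "deletion"
    if o1 == RETAINED_RIGHT and o2 == RETAINED_LEFT:
        return "tandem-duplication"
    return "inversion"


@dataclass(frozen=True)
class Rearrangement:
    """A pair of oriented break ends, the central mutation record.

    ``end1 <= end2`` in (chrom, pos) ordering; use :func:`make_rearrangement`
    to construct records in canonical form.
    """

    end1: BreakEnd
    end2: BreakEnd
    non_template_insert: str = ""
    svclass: str = "translocation"
    sample_id: str = ""
    evidence: str = "DNA"  # DNA, RNA or both

    def __post_init__(self) -> None:
        if self.end1.key > self.end2.key:
            raise ValueError("break ends not in canonical order")
        if not _ACGT_RE.match(self.non_template_insert):
            raise FormatError(
                f"non-template insert {self.non_template_insert!r} "
                "contains non-ACGT characters"
            )
        if self.svclass not in SVCLASSES:
            raise ValueError(f"invalid svclass {self.svclass!r}")
        expected = infer_svclass(self.end1, self.end2)
        if self.svclass != expected:
            raise ValueError(
                f"svclass {self.svclass} inconsistent with break ends "
                f"(expected {expected})"
            )


def make_rearrangement(
    end1: BreakEnd,
    end2: BreakEnd,
    non_template_insert: str = "",
    sample_id: str = "",
    evidence: str = "DNA",
    svclass: str | None = None,
) -> Rearrangement:
    """Build a Rearrangement with canonical end ordering and inferred class."""
    if end1.key > end2.key:
        end1, end2 = end2, end1
    if svclass is None:
        svclass = infer_svclass(end1, end2)
    return Rearrangement(
        end1=end1,
        end2=end2,
        non_template_insert=non_template_insert,
        svclass=svclass,
        sample_id=sample_id,
        evidence=evidence,
    )


@dataclass
class CoverageTrack:
    """Dense per-base coverage over one region, with normalisation factor."""

    region: GenomicInterval
    values: np.ndarray
    norm_factor: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.region):
            raise ValueError("coverage length does not match region length")
        if np.any(self.values < 0):
            raise ValueError("negative coverage values")

    def index(self, pos: int) -> int:
        """Array index of a genomic position."""
        if not self.region.contains(pos):
            raise IndexError(f"position {pos} outside track region")
        return pos - self.region.start

    def slice_values(self, start: int, end: int) -> np.ndarray:
        """Values over a genomic sub-interval, clipped to the track."""
        s = max(start, self.region.start) - self.region.start
        e = min(end, self.region.end) - self.region.start
        return self.values[max(s, 0):max(e, 0)]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a name -> uppercase sequence mapping."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene annotation
# ---------------------------------------------------------------------------


def _format_elements(elements: Sequence[tuple[str, tuple[int, int]]]) -> str:
    return "|".join(f"{label}:{s}-{e}" for label, (s, e) in elements)


def _parse_elements(text: str) -> list[tuple[str, tuple[int, int]]]:
    out: list[tuple[str, tuple[int, int]]] = []
    if not text:
        return out
    for item in text.split("|"):
        label, span = item.split(":")
        s, e = span.split("-")
        out.append((label, (int(s), int(e))))
    return out


def write_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene -> mRNA -> exon hierarchy).

    Transcript-coordinate metadata (CDS offsets, regulatory elements, role)
    travels in attribute columns so that annotation round-trips losslessly.
    """
    lines = ["##gff-version 3"]
    for g in genes:
        gs, ge = to_gff_coords(g.body.start, g.body.end)
        attrs = f"ID={g.gene_id};Name={g.name};role={g.role}"
        if g.regulatory_elements:
            attrs += f";regulatory_elements={_format_elements(g.regulatory_elements)}"
        lines.append(
            f"{g.body.chrom}\tfuscan\tgene\t{gs}\t{ge}\t.\t{g.strand}\t.\t{attrs}"
        )
        tid = f"{g.gene_id}.t1"
        lines.append(
            f"{g.body.chrom}\tfuscan\tmRNA\t{gs}\t{ge}\t.\t{g.strand}\t.\t"
            f"ID={tid};Parent={g.gene_id};cds_start={g.cds_start};cds_end={g.cds_end}"
        )
        for e in sorted(g.exons, key=lambda x: x.start):
            es, ee = to_gff_coords(e.start, e.end)
            lines.append(
                f"{e.chrom}\tfuscan\texon\t{es}\t{ee}\t.\t{g.strand}\t.\tParent={tid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _check_gff_hierarchy(path: str | Path) -> None:
    """Raise FormatError naming the line of any orphaned Parent reference."""
    ids: set[str] = set()
    parents: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            if "ID" in attrs:
                ids.add(attrs["ID"])
            if "Parent" in attrs:
                parents.append((lineno, attrs["Parent"]))
    for lineno, parent in parents:
        if parent not in ids:
            raise FormatError(
                f"{path}: line {lineno}: Parent={parent} refers to an "
                "undefined feature"
            )


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into gene models.

    Coordinates are converted to 0-based half-open; minus-strand exon lists
    are returned in transcript (5'->3') order.
    """
    _check_gff_hierarchy(path)
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        bs, be = from_gff_coords(gf.start, gf.end)
        strand = gf.strand if gf.strand in ("+", "-") else "."
        body = GenomicInterval(gf.seqid, bs, be, strand)
        mrnas = list(db.children(gf, featuretype="mRNA"))
        if not mrnas:
            raise FormatError(f"gene {gf.id} has no mRNA child")
        mrna = mrnas[0]
        exon_feats = sorted(
            db.children(mrna, featuretype="exon"), key=lambda f: f.start
        )
        if not exon_feats:
            raise FormatError(f"mRNA {mrna.id} has no exon children")
        exons = []
        for ef in exon_feats:
            es, ee = from_gff_coords(ef.start, ef.end)
            exons.append(GenomicInterval(ef.seqid, es, ee, strand))
        if strand == "-":
            exons = exons[::-1]
        genes.append(
            GeneModel(
                gene_id=gf.id,
                name=gf.attributes.get("Name", [gf.id])[0],
                body=body,
                exons=exons,
                cds_start=int(mrna.attributes.get("cds_start", ["0"])[0]),
                cds_end=int(
                    mrna.attributes.get("cds_end", [str(sum(len(e) for e in exons))])[0]
                ),
                role=gf.attributes.get("role", ["none"])[0],
                regulatory_elements=_parse_elements(
                    gf.attributes.get("regulatory_elements", [""])[0]
                ),
            )
        )
    genes.sort(key=lambda g: (g.body.chrom, g.body.start))
    return genes


# ---------------------------------------------------------------------------
# BEDPE structural variants
# ---------------------------------------------------------------------------

BEDPE_HEADER = (
    "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
    "strand1\tstrand2\tsvclass\tinsert\tsample"
)


def write_bedpe(rearrangements: Iterable[Rearrangement], path: str | Path) -> None:
    lines = [BEDPE_HEADER]
    for i, r in enumerate(rearrangements):
        lines.append(
            "\t".join(
                [
                    r.end1.chrom,
                    str(r.end1.pos),
                    str(r.end1.pos + 1),
                    r.end2.chrom,
                    str(r.end2.pos),
                    str(r.end2.pos + 1),
                    f"sv{i + 1}",
                    ".",
                    ORIENT_TO_STRAND[r.end1.orientation],
                    ORIENT_TO_STRAND[r.end2.orientation],
                    r.svclass,
                    r.non_template_insert or ".",
                    r.sample_id or ".",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_bedpe(path: str | Path, evidence: str = "DNA") -> list[Rearrangement]:
    """Parse BEDPE into Rearrangement records.

    Requires >= 10 columns; column 11 (svclass), 12 (non-template insert,
    "." for empty) and 13 (sample) are optional extensions.
    """
    out: list[Rearrangement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError(
                    f"{path}: line {lineno}: BEDPE needs >= 10 columns"
                )
            try:
                end1 = BreakEnd(f[0], int(f[1]), STRAND_TO_ORIENT[f[8]])
                end2 = BreakEnd(f[3], int(f[4]), STRAND_TO_ORIENT[f[9]])
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            insert = f[11] if len(f) > 11 and f[11] != "." else ""
            if not _ACGT_RE.match(insert):
                raise FormatError(
                    f"{path}: line {lineno}: insert {insert!r} is not ACGT"
                )
            sample = f[12] if len(f) > 12 and f[12] != "." else ""
            out.append(
                make_rearrangement(
                    end1, end2, insert, sample_id=sample, evidence=evidence
                )
            )
    return out


# ---------------------------------------------------------------------------
# Per-base coverage (bedGraph / fixedStep wiggle)
# ---------------------------------------------------------------------------


def _fmt_value(v: float) -> str:
    """Shortest decimal representation that round-trips exactly."""
    return repr(float(v))


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, run-length encoded, zeros included."""
    lines = []
    r = track.region
    vals = track.values
    i = 0
    n = len(vals)
    while i < n:
        j = i
        while j < n and vals[j] == vals[i]:
            j += 1
        lines.append(
            f"{r.chrom}\t{r.start + i}\t{r.start + j}\t{_fmt_value(vals[i])}"
        )
        i = j
    Path(path).write_text("\n".join(lines) + "\n")


def read_coverage(path: str | Path) -> CoverageTrack:
    """Parse bedGraph or fixedStep wiggle into a dense CoverageTrack.

    Intervals must be sorted and non-overlapping; gaps inside the covered
    span are filled with zero.
    """
    intervals: list[tuple[str, int, int, float]] = []
    wig_chrom: str | None = None
    wig_pos = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=") for p in line.split()[1:])
                wig_chrom = kv["chrom"]
                wig_pos = int(kv["start"]) - 1  # wiggle is 1-based
                if int(kv.get("step", 1)) != 1 or int(kv.get("span", 1)) != 1:
                    raise FormatError(
                        f"{path}: line {lineno}: only step=1 span=1 supported"
                    )
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if wig_chrom is not None and len(fields) == 1:
                intervals.append((wig_chrom, wig_pos, wig_pos + 1, float(fields[0])))
                wig_pos += 1
                continue
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            intervals.append(
                (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
            )
    if not intervals:
        raise FormatError(f"{path}: empty coverage file")
    chroms = {c for c, *_ in intervals}
    if len(chroms) > 1:
        raise FormatError(f"{path}: coverage track spans multiple chromosomes")
    chrom = intervals[0][0]
    for (c1, s1, e1, _), (c2, s2, e2, _) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise FormatError(
                f"{path}: overlapping or unsorted intervals at {c2}:{s2}"
            )
    start = intervals[0][1]
    end = intervals[-1][2]
    values = np.zeros(end - start, dtype=float)
    for _, s, e, v in intervals:
        values[s - start:e - start] = v
    return CoverageTrack(GenomicInterval(chrom, start, end), values)


# ---------------------------------------------------------------------------
# VCF (small-variant genotypes)
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence annotation">
##INFO=<ID=HOTSPOT,Number=0,Type=Flag,Description="Known hotspot">
"""


def write_vcf(
    records: Sequence[dict],
    path: str | Path,
    sample: str = "GERMLINE",
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write simple single-sample VCF records.

    Each record dict: chrom, pos (0-based), ref, alt, gt, plus optional
    info keys gene, consequence, hotspot.
    """
    lines = _VCF_HEADER.splitlines()
    for chrom, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for rec in records:
        info_parts = []
        if rec.get("gene"):
            info_parts.append(f"GENE={rec['gene']}")
        if rec.get("consequence"):
            info_parts.append(f"CSQ={rec['consequence']}")
        if rec.get("hotspot"):
            info_parts.append("HOTSPOT")
        info = ";".join(info_parts) or "."
        lines.append(
            "\t".join(
                [
                    rec["chrom"],
                    str(rec["pos"] + 1),
                    ".",
                    rec["ref"],
                    rec["alt"],
                    ".",
                    "PASS",
                    info,
                    "GT",
                    rec.get("gt", "0/1"),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[dict]:
    """Read a VCF into plain records with 0-based positions.

    Returns dicts with chrom, pos, ref, alts, gt (tuple of allele indexes or
    None), gene, consequence, hotspot.
    """
    out: list[dict] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            gt = None
            if samples:
                gt = rec.samples[samples[0]].get("GT")
            out.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos - 1,
                    "ref": rec.ref,
                    "alts": tuple(rec.alts or ()),
                    "gt": gt,
                    "gene": rec.info.get("GENE"),
                    "consequence": rec.info.get("CSQ"),
                    "hotspot": bool(rec.info.get("HOTSPOT", False)),
                }
            )
    return out


# ---------------------------------------------------------------------------
# TSV tables (gene counts, copy number, cancer genes, pileup, read segments)
# ---------------------------------------------------------------------------


def read_gene_counts(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "count"}.issubset(df.columns):
        raise FormatError(f"{path}: gene counts need columns gene, count")
    return df.set_index("gene")["count"].astype(float)


def write_gene_counts(counts: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(counts.keys()), "count": list(counts.values())}
    ).to_csv(path, sep="\t", index=False)


def read_cn_segments(path: str | Path) -> pd.DataFrame:
    """Copy-number segments: chrom, start, end (0-based half-open),
    total_cn, minor_cn."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "total_cn", "minor_cn"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: CN table needs columns {sorted(required)}")
    return df


def write_cn_segments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cancer_genes(path: str | Path) -> dict[str, str]:
    """Cancer-gene list: columns gene, role -> {gene: role}."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "role"}.issubset(df.columns):
        raise FormatError(f"{path}: cancer-gene list needs columns gene, role")
    return dict(zip(df["gene"], df["role"]))


def write_cancer_genes(roles: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(roles.keys()), "role": list(roles.values())}
    ).to_csv(path, sep="\t", index=False)


PILEUP_COLUMNS = ["chrom", "pos", "base", "base_qual", "map_qual"]


def read_pileup(path: str | Path) -> pd.DataFrame:
    """Per-read pileup observations; pos is 0-based."""
    df = pd.read_csv(path, sep="\t")
    if not set(PILEUP_COLUMNS).issubset(df.columns):
        raise FormatError(f"{path}: pileup needs columns {PILEUP_COLUMNS}")
    return df


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


READS_COLUMNS = ["read", "mate", "chrom", "start", "end"]


def read_support_reads(path: str | Path) -> pd.DataFrame:
    """Aligned-segment records: read name, mate (1/2), chrom, start, end."""
    df = pd.read_csv(path, sep="\t")
    if not set(READS_COLUMNS).issubset(df.columns):
        raise FormatError(f"{path}: reads table needs columns {READS_COLUMNS}")
    return df


def write_support_reads(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Parameters",
    "BreakEnd",
    "Rearrangement",
    "CoverageTrack",
    "RETAINED_LEFT",
    "RETAINED_RIGHT",
    "make_rearrangement",
    "infer_svclass",
    "revcomp",
    "to_gff_coords",
    "from_gff_coords",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation",
    "read_bedpe",
    "write_bedpe",
    "read_coverage",
    "write_coverage",
    "read_vcf",
    "write_vcf",
    "read_gene_counts",
    "write_gene_counts",
    "read_cn_segments",
    "write_cn_segments",
    "read_cancer_genes",
    "write_cancer_genes",
    "read_pileup",
    "write_pileup",
    "read_support_reads",
    "write_support_reads",
]
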