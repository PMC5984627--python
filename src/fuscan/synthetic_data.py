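"""Toy genomes, spiked rearrangements and simulated read-outs with truth.

Everything here is deterministic under a fixed seed. The generators emit the
same external formats the analysis stages consume (FASTA, GFF3, BEDPE,
bedGraph, VCF, TSV) together with a ``SimulationTruth`` record, so every
downstream stage can be validated against known answers without external
data.

Scenario layout (``build_scenario``):

* ``fos-like``   — a 4-exon oncogene with an exonic break in exon 4, an
  intergenic fusion partner carrying a planted AATAAA signal, and a stop
  codon planted at the first in-frame codon past the junction (truncating).
* ``fosb-like``  — an intronic break 50 bp into intron 3 of a multi-exon
  gene (donor skipped, intron exonised), a 3-nt non-template insert, and a
  partner scrubbed of in-frame stops near the junction (in-frame fusion).
* ``negative``   — no spiked rearrangement anywhere.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_formats import (
    RETAINED_LEFT,
    RETAINED_RIGHT,
    BreakEnd,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Parameters,
    Rearrangement,
    make_rearrangement,
    revcomp,
    write_annotation,
    write_bedpe,
    write_cancer_genes,
    write_cn_segments,
    write_coverage,
    write_fasta,
    write_gene_counts,
    write_pileup,
    write_support_reads,
    write_vcf,
)

SCENARIOS = ("fos-like", "fosb-like", "negative")

_STOPS = {"TAA", "TAG", "TGA"}
# Codons that can never contain a stop nor contribute to an AATAAA motif
# run: none end in A (so no AAA run can form across codons) and TAG is
# excluded explicitly.
_SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "CGT"
    if a + b + c != "TAG"
]

# Transcript-coordinate window in exon 4 of the first (oncogene-like) gene
# into which exonic breaks are spiked.
FOS_BREAK_WINDOW_TX = (1100, 1300)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    genes: list[GeneModel]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id or g.name == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside every simulation."""

    rearrangements: list[Rearrangement] = field(default_factory=list)
    true_cleavage_site: dict[str, int] = field(default_factory=dict)
    true_frame_class: dict[str, str] = field(default_factory=dict)
    true_ase_ratio: dict[str, float] = field(default_factory=dict)
    true_cn_events: list[tuple[GenomicInterval, int]] = field(default_factory=list)
    planted_motifs: list[int] = field(default_factory=list)
    partner_region: GenomicInterval | None = None
    break_position: dict[str, int] = field(default_factory=dict)
    carrier: str | None = None

    def to_json(self, path: str | Path) -> None:
        def enc(r: Rearrangement) -> dict:
            return {
                "end1": asdict(r.end1),
                "end2": asdict(r.end2),
                "non_template_insert": r.non_template_insert,
                "svclass": r.svclass,
                "sample_id": r.sample_id,
                "evidence": r.evidence,
            }

        payload = {
            "rearrangements": [enc(r) for r in self.rearrangements],
            "true_cleavage_site": self.true_cleavage_site,
            "true_frame_class": self.true_frame_class,
            "true_ase_ratio": self.true_ase_ratio,
            "true_cn_events": [
                [asdict(iv), cn] for iv, cn in self.true_cn_events
            ],
            "planted_motifs": self.planted_motifs,
            "partner_region": (
                asdict(self.partner_region) if self.partner_region else None
            ),
            "break_position": self.break_position,
            "carrier": self.carrier,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        raw = json.loads(Path(path).read_text())

        def dec(d: dict) -> Rearrangement:
            return Rearrangement(
                end1=BreakEnd(**d["end1"]),
                end2=BreakEnd(**d["end2"]),
                non_template_insert=d["non_template_insert"],
                svclass=d["svclass"],
                sample_id=d["sample_id"],
                evidence=d["evidence"],
            )

        return cls(
            rearrangements=[dec(d) for d in raw["rearrangements"]],
            true_cleavage_site=raw["true_cleavage_site"],
            true_frame_class=raw["true_frame_class"],
            true_ase_ratio=raw["true_ase_ratio"],
            true_cn_events=[
                (GenomicInterval(**iv), cn) for iv, cn in raw["true_cn_events"]
            ],
            planted_motifs=raw["planted_motifs"],
            partner_region=(
                GenomicInterval(**raw["partner_region"])
                if raw["partner_region"]
                else None
            ),
            break_position=raw["break_position"],
            carrier=raw["carrier"],
        )


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

_FOS_TEMPLATE = dict(
    span=3600,
    exons=[(0, 300), (700, 1000), (1400, 1800), (2400, 3600)],
    cds=(150, 1650),
    elements=[("MCRD", (1400, 1460)), ("ARE", (1800, 1860))],
    role="oncogene",
    name="FOSL",
    design=True,
)
_PARTNER_TEMPLATE = dict(
    span=4000,
    exons=[(0, 400), (900, 1200), (1700, 2000), (2800, 4000)],
    cds=(100, 1900),
    elements=[],
    role="none",
    name="PRTL",
    design=True,
)


def _generic_template(index: int) -> dict:
    role = {2: "TSG", 3: "oncogene"}.get(index, "none")
    name = {2: "TSG1", 3: "ONC1"}.get(index, f"GEN{index + 1}")
    return dict(
        span=1500,
        exons=[(0, 400), (1100, 1500)],
        cds=(60, 660),
        elements=[],
        role=role,
        name=name,
        design=False,
    )


def transcript_to_genomic(gene: GeneModel, t: int) -> int:
    """Map a spliced-transcript offset to a genomic position (+ strand)."""
    if gene.strand == "-":
        raise ValueError("designed genes are forward-strand only")
    for off, e in zip(gene.exon_offsets(), gene.exons):
        if off <= t < off + len(e):
            return e.start + (t - off)
    raise ValueError(f"transcript offset {t} outside exons of {gene.gene_id}")


def exon_break_position(gene: GeneModel, exon_index: int, offset: int) -> int:
    """Genomic position ``offset`` bp into a 1-based exon ordinal."""
    exon = gene.exons[exon_index - 1]
    if not 0 <= offset < len(exon):
        raise ConfigurationError("break offset outside exon")
    return exon.start + offset


def _random_sequence(rng: np.random.Generator, length: int) -> bytearray:
    return bytearray(_BASE_BYTES[rng.integers(0, 4, size=length)].tobytes())


def _scrub_motifs(
    seqs: dict[str, bytearray],
    protected: dict[str, dict[int, tuple[int, int, int]]],
    motif: bytes = b"AATAAA",
) -> None:
    """Remove every motif occurrence without breaking designed CDS frames.

    Occurrences overlapping a protected coding codon are removed by
    rewriting that whole codon to CTG (safe, stop-free); elsewhere the
    central T is flipped to G. Neither edit can create a new occurrence.
    """
    changed = True
    while changed:
        changed = False
        for chrom, ba in seqs.items():
            prot = protected.get(chrom, {})
            i = ba.find(motif)
            while i != -1:
                changed = True
                hit = next((p for p in range(i, i + 6) if p in prot), None)
                if hit is not None:
                    for p, base in zip(prot[hit], b"CTG"):
                        ba[p] = base
                else:
                    ba[i + 2] = ord("G")
                i = ba.find(motif, i + 1)


def make_genome(
    seed: int,
    n_genes: int = 4,
    chrom_lengths: Sequence[int] = (50_000, 50_000),
) -> tuple[SyntheticGenome, SimulationTruth]:
    """Emit a toy genome, gene models and a truth skeleton.

    Deterministic for a fixed seed. The first gene is a 4-exon oncogene-like
    model with a stop-free, motif-free coding sequence and 3' regulatory
    elements; the second is a multi-exon fusion-partner-like gene. One
    AATAAA motif is planted in a reserved intergenic partner region on the
    last chromosome; the rest of the genome is scrubbed of the motif.
    """
    if n_genes < 2:
        raise ConfigurationError("need at least 2 genes")
    chrom_lengths = list(chrom_lengths)
    if not chrom_lengths or any(l < 10_000 for l in chrom_lengths):
        raise ConfigurationError("chromosome lengths must be >= 10 kb")

    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(len(chrom_lengths))]
    seqs = {c: _random_sequence(rng, l) for c, l in zip(chroms, chrom_lengths)}

    # Reserve an intergenic partner region at the end of the last chromosome.
    last = chroms[-1]
    last_len = chrom_lengths[-1]
    reserve = 10_000 if last_len >= 30_000 else last_len // 3
    partner_region = GenomicInterval(last, last_len - reserve - 2_000, last_len - 2_000)

    # Place genes round-robin across chromosomes.
    cursors = {c: 2_000 for c in chroms}
    limits = {c: l - 2_000 for c, l in zip(chroms, chrom_lengths)}
    limits[last] = min(limits[last], partner_region.start - 1_000)
    genes: list[GeneModel] = []
    for i in range(n_genes):
        if i == 0:
            tpl = _FOS_TEMPLATE
        elif i == 1:
            tpl = _PARTNER_TEMPLATE
        else:
            tpl = _generic_template(i)
        placed = False
        order = chroms[i % len(chroms):] + chroms[: i % len(chroms)]
        for c in order:
            start = cursors[c]
            if start + tpl["span"] <= limits[c]:
                body = GenomicInterval(c, start, start + tpl["span"], "+")
                exons = [
                    GenomicInterval(c, start + s, start + e, "+")
                    for s, e in tpl["exons"]
                ]
                genes.append(
                    GeneModel(
                        gene_id=f"g{i + 1}",
                        name=tpl["name"],
                        body=body,
                        exons=exons,
                        cds_start=tpl["cds"][0],
                        cds_end=tpl["cds"][1],
                        role=tpl["role"],
                        regulatory_elements=list(tpl["elements"]),
                    )
                )
                cursors[c] = start + tpl["span"] + 2_500
                placed = True
                break
        if not placed:
            raise ConfigurationError(
                f"chromosomes too small to place gene {i + 1} of {n_genes}"
            )

    # Overwrite designed coding sequences with safe codons and plant the
    # terminal stop codon; remember codon positions for motif scrubbing.
    protected: dict[str, dict[int, tuple[int, int, int]]] = {}
    for gene, tpl_design in zip(genes, [True, True] + [False] * (n_genes - 2)):
        if not tpl_design:
            continue
        chrom = gene.body.chrom
        prot = protected.setdefault(chrom, {})
        ba = seqs[chrom]
        for t in range(gene.cds_start, gene.cds_end - 3, 3):
            codon = _SAFE_CODONS[rng.integers(0, len(_SAFE_CODONS))]
            positions = tuple(transcript_to_genomic(gene, t + k) for k in range(3))
            for p, base in zip(positions, codon.encode()):
                ba[p] = base
            for p in positions:
                prot[p] = positions
        stop_positions = tuple(
            transcript_to_genomic(gene, gene.cds_end - 3 + k) for k in range(3)
        )
        for p, base in zip(stop_positions, b"TAA"):
            ba[p] = base
        for p in stop_positions:
            prot[p] = stop_positions

    _scrub_motifs(seqs, protected)

    # Plant one AATAAA in the partner region, guarded so exactly one
    # occurrence exists there.
    motif_pos = partner_region.start + 800
    ba = seqs[last]
    ba[motif_pos - 1] = ord("C")
    ba[motif_pos:motif_pos + 6] = b"AATAAA"
    ba[motif_pos + 6] = ord("C")

    genome = SyntheticGenome(
        sequences={c: seqs[c].decode("ascii") for c in chroms},
        genes=genes,
    )
    truth = SimulationTruth(
        planted_motifs=[motif_pos], partner_region=partner_region
    )
    return genome, truth


def _edit(genome: SyntheticGenome, chrom: str, pos: int, replacement: str) -> None:
    s = genome.sequences[chrom]
    genome.sequences[chrom] = (
        s[:pos] + replacement + s[pos + len(replacement):]
    )


# ---------------------------------------------------------------------------
# Spiking and simulation primitives
# ---------------------------------------------------------------------------


def spike_rearrangement(
    genome: SyntheticGenome,
    gene_id: str,
    break_pos: int,
    partner: GenomicInterval,
    insert: str = "",
    sample_id: str = "",
    seed: int = 0,
) -> tuple[Rearrangement, str]:
    """Join a gene at ``break_pos`` to a partner interval.

    Returns the rearrangement record and the derived tumour contig:
    5' reference sequence (gene-body start to break) + insert + partner
    sequence in fusion orientation.
    """
    gene = genome.gene(gene_id)
    if not gene.body.contains(break_pos):
        raise ConfigurationError(
            f"break {break_pos} outside gene {gene.gene_id} body"
        )
    # The partner may not re-use the retained 5' portion of the source gene
    # (a partner adjacent to the break is the legitimate identity case).
    if gene.strand == "-":
        retained = (break_pos, gene.body.end)
    else:
        retained = (gene.body.start, break_pos)
    if (
        partner.chrom == gene.body.chrom
        and partner.start < retained[1]
        and retained[0] < partner.end
    ):
        raise ConfigurationError(
            "partner interval overlaps the retained part of the source gene"
        )

    chrom_seq = genome.sequences[gene.body.chrom]
    if gene.strand == "-":
        gene_end = BreakEnd(gene.body.chrom, break_pos, RETAINED_RIGHT)
        five = revcomp(chrom_seq[break_pos:gene.body.end])
    else:
        gene_end = BreakEnd(gene.body.chrom, break_pos, RETAINED_LEFT)
        five = chrom_seq[gene.body.start:break_pos]

    partner_seq = genome.sequences[partner.chrom][partner.start:partner.end]
    if partner.strand == "-":
        partner_end = BreakEnd(partner.chrom, partner.end, RETAINED_LEFT)
        partner_seq = revcomp(partner_seq)
    else:
        partner_end = BreakEnd(partner.chrom, partner.start, RETAINED_RIGHT)

    r = make_rearrangement(
        gene_end, partner_end, insert, sample_id=sample_id, evidence="DNA"
    )
    return r, five + insert + partner_seq


def simulate_coverage(
    region: GenomicInterval,
    mean_depth: float,
    noise: float,
    seed: int,
    transcript: tuple[int, int] | None = None,
    background: float = 0.0,
    decay_bp: float = 1.5,
) -> CoverageTrack:
    """Per-base coverage over ``region``.

    ``transcript=(break_pos, cleavage_site)`` marks the transcribed span:
    expectation ``mean_depth`` on [break, cleavage), decaying exponentially
    to ~0 within ~5 bp past the cleavage site, ``background`` elsewhere.
    ``noise == 0`` returns the expectation exactly; otherwise counts are
    Poisson-distributed around it.
    """
    if mean_depth <= 0:
        raise ConfigurationError("mean_depth must be positive")
    expected = np.full(len(region), float(background))
    if transcript is not None:
        b, c = transcript
        if not (region.start <= b < c <= region.end):
            raise ConfigurationError("transcript span outside coverage region")
        expected[b - region.start:c - region.start] = mean_depth
        tail = np.arange(c, min(c + 40, region.end))
        if len(tail):
            expected[tail - region.start] = background + mean_depth * np.exp(
                -(tail - c + 1) / decay_bp
            )
    if noise == 0:
        values = expected
    else:
        rng = np.random.default_rng(seed)
        values = rng.poisson(expected).astype(float)
    return CoverageTrack(region, values)


def _snp_fields(snp) -> tuple[str, int, str, str]:
    if isinstance(snp, Mapping):
        return snp["chrom"], snp["pos"], snp["ref"], snp["alt"]
    return snp.chrom, snp.pos, snp.ref, snp.alt


def simulate_pileup(
    snps: Sequence,
    depth: int,
    ase_ratio: float,
    seed: int,
    base_qual: int = 35,
    map_qual: int = 60,
) -> pd.DataFrame:
    """Per-read pileup rows; alt counts ~ Binomial(depth, ase_ratio)."""
    if not 0.0 <= ase_ratio <= 1.0:
        raise ConfigurationError("ase_ratio must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for snp in snps:
        chrom, pos, ref, alt = _snp_fields(snp)
        n_alt = int(rng.binomial(depth, ase_ratio))
        for base, n in ((alt, n_alt), (ref, depth - n_alt)):
            for _ in range(n):
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "base": base,
                        "base_qual": base_qual,
                        "map_qual": map_qual,
                    }
                )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "base", "base_qual", "map_qual"]
    )


def simulate_cn(
    events: Sequence[tuple[GenomicInterval, int]],
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Diploid copy-number segments with spiked events carved out."""
    rows = []
    by_chrom: dict[str, list[tuple[GenomicInterval, int]]] = {}
    for iv, cn in events:
        by_chrom.setdefault(iv.chrom, []).append((iv, cn))
    for chrom, length in chrom_lengths.items():
        evs = sorted(by_chrom.get(chrom, []), key=lambda x: x[0].start)
        cursor = 0
        for iv, cn in evs:
            if iv.start > cursor:
                rows.append((chrom, cursor, iv.start, 2, 1))
            rows.append((chrom, iv.start, iv.end, cn, min(1, cn)))
            cursor = iv.end
        if cursor < length:
            rows.append((chrom, cursor, length, 2, 1))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "total_cn", "minor_cn"]
    )


def simulate_support_reads(
    r: Rearrangement,
    n_split: int,
    n_discordant: int,
    seed: int,
    read_len: int = 100,
) -> pd.DataFrame:
    """Aligned-segment records for reads supporting a junction.

    Split reads get two segments abutting the two break ends; discordant
    pairs get one mate on the retained side of each end, clear of the
    junction.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def junction_segment(end: BreakEnd, length: int) -> tuple[str, int, int]:
        if end.orientation == RETAINED_LEFT:
            return end.chrom, end.pos - length, end.pos
        return end.chrom, end.pos, end.pos + length

    def anchored_segment(end: BreakEnd, gap: int, length: int) -> tuple[str, int, int]:
        if end.orientation == RETAINED_LEFT:
            return end.chrom, end.pos - gap - length, end.pos - gap
        return end.chrom, end.pos + gap, end.pos + gap + length

    for k in range(n_split):
        left = int(rng.integers(40, read_len - 30))
        c1, s1, e1 = junction_segment(r.end1, left)
        c2, s2, e2 = junction_segment(r.end2, read_len - left)
        rows.append({"read": f"split{k + 1}", "mate": 1, "chrom": c1, "start": s1, "end": e1})
        rows.append({"read": f"split{k + 1}", "mate": 1, "chrom": c2, "start": s2, "end": e2})
    for k in range(n_discordant):
        gap = int(rng.integers(120, 250))
        c1, s1, e1 = anchored_segment(r.end1, gap, read_len)
        c2, s2, e2 = anchored_segment(r.end2, gap, read_len)
        rows.append({"read": f"disc{k + 1}", "mate": 1, "chrom": c1, "start": s1, "end": e1})
        rows.append({"read": f"disc{k + 1}", "mate": 2, "chrom": c2, "start": s2, "end": e2})
    return pd.DataFrame(rows, columns=["read", "mate", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Full scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioBundle:
    """In-memory materialisation of one simulation scenario."""

    scenario: str
    genome: SyntheticGenome
    truth: SimulationTruth
    samples: list[str]
    carrier: str | None
    dna_calls: dict[str, list[Rearrangement]]
    rna_calls: dict[str, list[Rearrangement]]
    tracks: dict[str, CoverageTrack]
    gene_counts: dict[str, dict[str, float]]
    snps: list[dict]
    pileups: dict[str, pd.DataFrame]
    cn: dict[str, pd.DataFrame]
    variants: dict[str, list[dict]]
    reads: dict[str, pd.DataFrame]
    cancer_roles: dict[str, str]
    contig: str | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)


def _plant_stop(genome: SyntheticGenome, chrom: str, pos: int) -> None:
    """Write TAA at pos with C guards so no AATAAA can form around it."""
    _edit(genome, chrom, pos - 1, "C")
    _edit(genome, chrom, pos, "TAA")
    _edit(genome, chrom, pos + 3, "C")


def _scrub_frame_stops(
    genome: SyntheticGenome,
    gene: GeneModel,
    break_pos: int,
    insert: str,
    partner: GenomicInterval,
    window_codons: int,
) -> None:
    """Remove in-frame stops near the junction of an intronic-break fusion.

    The reading frame is fixed by the gene's CDS start; offending codon
    bases falling in the exonised intron or the partner sequence are
    rewritten to C (the fixed insert is never edited).
    """
    last_exon_end = None
    for e in gene.exons:
        if e.end <= break_pos:
            last_exon_end = e.end
    if last_exon_end is None:
        raise ConfigurationError("intronic break precedes all exons")
    retained_tx = sum(
        len(e) for e in gene.exons if e.end <= break_pos
    )
    intron_len = break_pos - last_exon_end
    junction = retained_tx + intron_len  # fusion-transcript offset of break

    chrom_seq = genome.sequences[gene.body.chrom]
    partner_chrom = partner.chrom

    def build() -> str:
        five = "".join(
            genome.sequences[gene.body.chrom][e.start:e.end]
            for e in gene.exons
            if e.end <= break_pos
        )
        five += genome.sequences[gene.body.chrom][last_exon_end:break_pos]
        return five + insert + genome.sequences[partner_chrom][partner.start:partner.end]

    def to_genomic(fo: int) -> tuple[str, int] | None:
        """Map a fusion-transcript offset to an editable genomic base."""
        if retained_tx <= fo < junction:
            return gene.body.chrom, last_exon_end + (fo - retained_tx)
        if junction + len(insert) <= fo:
            return partner_chrom, partner.start + (fo - junction - len(insert))
        return None  # native exon or fixed insert: not editable

    # Scrub from the exonised-intron start (random sequence, so in-frame
    # stops are likely there too) through the window past the junction.
    lo = retained_tx - 3
    hi = junction + 3 * window_codons
    for _ in range(10):  # converges in one or two passes
        seq = build()
        dirty = False
        for fo in range(gene.cds_start, len(seq) - 2, 3):
            if fo < lo or fo > hi:
                continue
            if seq[fo:fo + 3] in _STOPS:
                for k in (1, 0, 2):  # prefer the middle base
                    target = to_genomic(fo + k)
                    if target is not None:
                        _edit(genome, target[0], target[1], "C")
                        dirty = True
                        break
                else:
                    raise ConfigurationError("stop codon has no editable base")
        if not dirty:
            return
    raise ConfigurationError("failed to scrub junction-frame stop codons")


def build_scenario(
    scenario: str,
    seed: int,
    mean_depth: float = 50.0,
    noise: float = 1.0,
    n_samples: int = 4,
    ase_ratio: float = 0.9,
    snp_depth: int = 500,
    params: Parameters | None = None,
) -> ScenarioBundle:
    """Materialise a complete multi-sample scenario in memory."""
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    if n_samples < 2:
        raise ConfigurationError("need at least 2 samples")
    params = params or Parameters()
    chrom_lengths_list = (50_000, 50_000)
    genome, truth = make_genome(seed, n_genes=4, chrom_lengths=chrom_lengths_list)
    chrom_lengths = {
        c: len(s) for c, s in genome.sequences.items()
    }
    rng = np.random.default_rng((seed, 1))

    samples = [f"S{i + 1}" for i in range(n_samples)]
    carrier = samples[0] if scenario != "negative" else None
    truth.carrier = carrier

    motif = truth.planted_motifs[0]
    partner_chrom = truth.partner_region.chrom
    p2 = motif - 300
    offset = int(10 + rng.integers(0, 21))
    cleavage = motif + 6 + offset
    partner = GenomicInterval(partner_chrom, p2, p2 + 1_000, "+")

    r = None
    contig = None
    if scenario == "fos-like":
        gene = genome.genes[0]
        t_break = int(
            FOS_BREAK_WINDOW_TX[0]
            + rng.integers(0, FOS_BREAK_WINDOW_TX[1] - FOS_BREAK_WINDOW_TX[0])
        )
        break_pos = transcript_to_genomic(gene, t_break)
        # First full in-frame codon past the junction becomes a stop.
        phase = (t_break - gene.cds_start) % 3
        first_codon = (3 - phase) % 3
        _plant_stop(genome, partner_chrom, p2 + first_codon)
        r, contig = spike_rearrangement(
            genome, gene.gene_id, break_pos, partner, "", carrier
        )
        truth.true_frame_class[carrier] = "TRUNCATING"
        target_gene = gene
    elif scenario == "fosb-like":
        gene = genome.genes[1]
        break_pos = gene.exons[2].end + 50  # 50 bp into intron 3
        insert = "TGC"
        _scrub_frame_stops(genome, gene, break_pos, insert, partner, 36)
        # Plant the eventual in-frame stop well past the proximity window.
        retained_tx = sum(len(e) for e in gene.exons[:3])
        junction = retained_tx + 50
        phase = (junction + len(insert) - gene.cds_start) % 3
        stop_fo = junction + len(insert) + ((3 - phase) % 3) + 3 * 40
        _plant_stop(
            genome, partner_chrom, partner.start + stop_fo - junction - len(insert)
        )
        r, contig = spike_rearrangement(
            genome, gene.gene_id, break_pos, partner, insert, carrier
        )
        truth.true_frame_class[carrier] = "IN_FRAME_FUSION"
        target_gene = gene
    else:
        target_gene = genome.genes[0]

    dna_calls: dict[str, list[Rearrangement]] = {s: [] for s in samples}
    rna_calls: dict[str, list[Rearrangement]] = {s: [] for s in samples}
    if r is not None:
        truth.rearrangements.append(r)
        truth.break_position[carrier] = (
            r.end1.pos if r.end1.chrom != partner_chrom else r.end2.pos
        )
        truth.true_cleavage_site[carrier] = cleavage
        dna_calls[carrier] = [r]
        jit1 = int(rng.integers(-3, 4))
        jit2 = int(rng.integers(-3, 4))
        rna_calls[carrier] = [
            make_rearrangement(
                BreakEnd(r.end1.chrom, r.end1.pos + jit1, r.end1.orientation),
                BreakEnd(r.end2.chrom, r.end2.pos + jit2, r.end2.orientation),
                r.non_template_insert,
                sample_id=carrier,
                evidence="RNA",
            )
        ]

    region = GenomicInterval(
        partner_chrom,
        p2 - 200,
        min(cleavage + 320, chrom_lengths[partner_chrom]),
    )
    tracks: dict[str, CoverageTrack] = {}
    for i, s in enumerate(samples):
        if s == carrier:
            tracks[s] = simulate_coverage(
                region,
                mean_depth,
                noise,
                seed=int(rng.integers(0, 2**31)),
                transcript=(p2, cleavage),
                background=0.2,
            )
        else:
            tracks[s] = simulate_coverage(
                region,
                mean_depth,
                noise,
                seed=int(rng.integers(0, 2**31)),
                transcript=None,
                background=0.2,
            )

    gene_counts = {
        s: {
            g.gene_id: float(np.round(rng.uniform(800, 1200), 1))
            for g in genome.genes
        }
        for s in samples
    }

    # Heterozygous SNPs inside the target gene's exons.
    snps: list[dict] = []
    chrom_seq = genome.sequences[target_gene.body.chrom]
    alt_of = {"A": "G", "C": "T", "G": "A", "T": "C"}
    for exon in (target_gene.exons[1], target_gene.exons[2]):
        for pos in (exon.start + 40, exon.start + 120):
            ref = chrom_seq[pos]
            snps.append(
                {
                    "chrom": target_gene.body.chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt_of[ref],
                    "gt": "0/1",
                }
            )
    pileups: dict[str, pd.DataFrame] = {}
    for s in samples:
        ratio = ase_ratio if s == carrier else 0.5
        pileups[s] = simulate_pileup(
            snps, snp_depth, ratio, seed=int(rng.integers(0, 2**31))
        )
        if s == carrier:
            for snp in snps:
                truth.true_ase_ratio[f"{snp['chrom']}:{snp['pos']}"] = ratio

    cn = {s: simulate_cn(truth.true_cn_events, chrom_lengths) for s in samples}

    # A couple of deliberately non-driver small variants for the carrier.
    variants: dict[str, list[dict]] = {s: [] for s in samples}
    if carrier is not None:
        g2 = genome.genes[1]
        g3 = genome.genes[2]
        variants[carrier] = [
            {
                "chrom": g2.body.chrom,
                "pos": g2.exons[0].start + 10,
                "ref": genome.sequences[g2.body.chrom][g2.exons[0].start + 10],
                "alt": "A"
                if genome.sequences[g2.body.chrom][g2.exons[0].start + 10] != "A"
                else "G",
                "gt": "0/1",
                "gene": g2.gene_id,
                "consequence": "missense",
            },
            {
                "chrom": g3.body.chrom,
                "pos": g3.exons[0].start + 10,
                "ref": genome.sequences[g3.body.chrom][g3.exons[0].start + 10],
                "alt": "A"
                if genome.sequences[g3.body.chrom][g3.exons[0].start + 10] != "A"
                else "G",
                "gt": "0/1",
                "gene": g3.gene_id,
                "consequence": "synonymous",
            },
        ]

    reads = {s: pd.DataFrame(columns=["read", "mate", "chrom", "start", "end"]) for s in samples}
    if r is not None:
        reads[carrier] = simulate_support_reads(
            r, 3, 2, seed=int(rng.integers(0, 2**31))
        )

    cancer_roles = {
        genome.genes[0].gene_id: "oncogene",
        genome.genes[2].gene_id: "TSG",
        genome.genes[3].gene_id: "oncogene",
    }

    return ScenarioBundle(
        scenario=scenario,
        genome=genome,
        truth=truth,
        samples=samples,
        carrier=carrier,
        dna_calls=dna_calls,
        rna_calls=rna_calls,
        tracks=tracks,
        gene_counts=gene_counts,
        snps=snps,
        pileups=pileups,
        cn=cn,
        variants=variants,
        reads=reads,
        cancer_roles=cancer_roles,
        contig=contig,
        chrom_lengths=chrom_lengths,
    )


def generate_scenario(
    scenario: str,
    seed: int,
    out_dir: str | Path,
    **kwargs,
) -> tuple[dict, SimulationTruth]:
    """Write a scenario to disk; returns file paths and the truth record.

    Also emits a ready-to-run pipeline config (``config.yaml``).
    """
    import yaml

    bundle = build_scenario(scenario, seed, **kwargs)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {"out_dir": str(out)}

    write_fasta(bundle.genome.sequences, out / "genome.fa")
    write_annotation(bundle.genome.genes, out / "annotation.gff3")
    write_cancer_genes(bundle.cancer_roles, out / "cancer_genes.tsv")
    write_vcf(
        bundle.snps, out / "germline.vcf", sample="GERMLINE",
        contigs=bundle.chrom_lengths,
    )
    bundle.truth.to_json(out / "truth.json")
    paths.update(
        genome=str(out / "genome.fa"),
        annotation=str(out / "annotation.gff3"),
        cancer_genes=str(out / "cancer_genes.tsv"),
        germline=str(out / "germline.vcf"),
        truth=str(out / "truth.json"),
    )

    sample_cfg = {}
    for s in bundle.samples:
        write_bedpe(bundle.dna_calls[s], out / f"{s}.dna.bedpe")
        write_bedpe(bundle.rna_calls[s], out / f"{s}.rna.bedpe")
        write_coverage(bundle.tracks[s], out / f"{s}.coverage.bedgraph")
        write_gene_counts(bundle.gene_counts[s], out / f"{s}.gene_counts.tsv")
        write_pileup(bundle.pileups[s], out / f"{s}.pileup.tsv")
        write_cn_segments(bundle.cn[s], out / f"{s}.cn.tsv")
        write_support_reads(bundle.reads[s], out / f"{s}.reads.tsv")
        write_vcf(
            bundle.variants[s], out / f"{s}.variants.vcf", sample=s,
            contigs=bundle.chrom_lengths,
        )
        sample_cfg[s] = {
            "dna_svs": str(out / f"{s}.dna.bedpe"),
            "rna_svs": str(out / f"{s}.rna.bedpe"),
            "coverage": str(out / f"{s}.coverage.bedgraph"),
            "gene_counts": str(out / f"{s}.gene_counts.tsv"),
            "pileup": str(out / f"{s}.pileup.tsv"),
            "copy_number": str(out / f"{s}.cn.tsv"),
            "reads": str(out / f"{s}.reads.tsv"),
            "variants": str(out / f"{s}.variants.vcf"),
        }
    config = {
        "genome": str(out / "genome.fa"),
        "annotation": str(out / "annotation.gff3"),
        "cancer_genes": str(out / "cancer_genes.tsv"),
        "genotypes": str(out / "germline.vcf"),
        "parameters": {},
        "samples": sample_cfg,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    paths["config"] = str(out / "config.yaml")
    paths["samples"] = sample_cfg
    return paths, bundle.truth


__all__ = [
    "SCENARIOS",
    "FOS_BREAK_WINDOW_TX",
    "SyntheticGenome",
    "SimulationTruth",
    "ScenarioBundle",
    "make_genome",
    "transcript_to_genomic",
    "exon_break_position",
    "spike_rearrangement",
    "simulate_coverage",
    "simulate_pileup",
    "simulate_cn",
    "simulate_support_reads",
    "build_scenario",
    "generate_scenario",
]
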