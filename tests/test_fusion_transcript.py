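import numpy as np
import pytest

from fuscan import breakpoint_analysis as bp
from fuscan import fusion_transcript as ftm
from fuscan import synthetic_data as sd
from fuscan.errors import FusionError
from fuscan.io_formats import (
    RETAINED_LEFT,
    RETAINED_RIGHT,
    BreakEnd,
    GeneModel,
    GenomicInterval,
    make_rearrangement,
)

STOPS = ("TAA", "TAG", "TGA")


def _mk_ft(five_seq, three_seq, insert="", cds_start=0, retained=None):
    """Hand-build a FusionTranscript with one segment per side."""
    segs = [
        ftm.FusionSegment(
            GenomicInterval("c5", 0, len(five_seq), "+"), "g5", five_seq
        ),
        ftm.FusionSegment(
            GenomicInterval("c3", 0, len(three_seq), "+"), "intergenic", three_seq
        ),
    ]
    return ftm.FusionTranscript(
        segments=segs,
        junction_index=1,
        insert=insert,
        gene_id="g5",
        cds_start=cds_start,
        retained_native_length=retained if retained is not None else len(five_seq),
    )


def _codon_scan_oracle(seq, cds_start, junction, retained_native, prox):
    """Independent naive 3-mer scanner over the assembled string."""
    if retained_native <= cds_start:
        return "NON_CODING", None
    i = cds_start
    while i + 3 <= len(seq):
        if seq[i:i + 3] in STOPS:
            off = (i - junction) // 3
            cls = "TRUNCATING" if off <= prox else "IN_FRAME_FUSION"
            return cls, off
        i += 3
    return "UNTERMINATED", None


class TestBuild:
    def test_exonic_break_truncates_exon(self, fos_bundle):
        b = fos_bundle
        r = b.truth.rearrangements[0]
        cleavage = b.truth.true_cleavage_site[b.carrier]
        ft = ftm.build_fusion_transcript(
            r, b.genome.genes, b.genome.sequences, cleavage
        )
        last5 = ft.segments[ft.junction_index - 1]
        assert last5.interval.end == r.end1.pos
        assert last5.source == b.genome.genes[0].gene_id

    def test_intronic_break_exonises_intron(self, fosb_bundle):
        b = fosb_bundle
        r = b.truth.rearrangements[0]
        gene = b.genome.genes[1]
        cleavage = b.truth.true_cleavage_site[b.carrier]
        ft = ftm.build_fusion_transcript(
            r, b.genome.genes, b.genome.sequences, cleavage
        )
        exonised = ft.segments[ft.junction_index - 1]
        assert exonised.interval.start == gene.exons[2].end
        assert len(exonised.sequence) == 50
        # native spliced length excludes the exonised intron
        assert ft.retained_native_length == sum(len(e) for e in gene.exons[:3])
        assert ft.junction_offset == ft.retained_native_length + 50

    def test_length_bookkeeping_random(self):
        genome, truth = sd.make_genome(21)
        rng = np.random.default_rng(21)
        g = genome.genes[0]
        region = truth.partner_region
        for _ in range(100):
            break_pos = int(rng.integers(g.body.start + 1, g.body.end - 1))
            ps = int(rng.integers(region.start, region.end - 800))
            partner = GenomicInterval(region.chrom, ps, ps + 700, "+")
            insert = "ACGT"[: int(rng.integers(0, 5))]
            r, _ = sd.spike_rearrangement(
                genome, g.gene_id, break_pos, partner, insert
            )
            end = ps + int(rng.integers(100, 650))
            ft = ftm.build_fusion_transcript(
                r, genome.genes, genome.sequences, end
            )
            assert len(ft) == sum(len(s.sequence) for s in ft.segments) + len(
                ft.insert
            )
            assert len(ft.sequence) == len(ft)

    def test_no_gene_end_raises(self, fos_bundle):
        genes = fos_bundle.genome.genes
        r = make_rearrangement(
            BreakEnd("chr1", 100, RETAINED_LEFT),
            BreakEnd("chr2", 45_000, RETAINED_RIGHT),
        )
        with pytest.raises(FusionError):
            ftm.build_fusion_transcript(
                r, genes, fos_bundle.genome.sequences, 45_600
            )

    def test_reassembly_from_tumour_contig(self, fos_bundle):
        """Splicing the simulator's contig reproduces the transcript."""
        b = fos_bundle
        r = b.truth.rearrangements[0]
        gene = b.genome.genes[0]
        break_pos = r.end1.pos
        p2 = r.end2.pos
        cleavage = b.truth.true_cleavage_site[b.carrier]
        gs = gene.body.start
        contig = b.contig
        expected = ""
        for e in gene.exons:
            if e.end <= break_pos:
                expected += contig[e.start - gs:e.end - gs]
            elif e.contains(break_pos):
                expected += contig[e.start - gs:break_pos - gs]
        junction = break_pos - gs
        expected += contig[junction:junction + (cleavage - p2)]
        ft = ftm.build_fusion_transcript(
            r, b.genome.genes, b.genome.sequences, cleavage
        )
        assert ft.sequence == expected


class TestClassify:
    def test_stop_codon_insert_at_junction(self):
        five = "ATG" + "GCT" * 9  # 30 nt of open frame
        ft = _mk_ft(five, "G" * 60, insert="TGA")
        cls, off = ftm.translate_and_classify(ft, 10)
        assert cls == ftm.TRUNCATING and off == 0

    def test_in_frame_three_nt_insert(self):
        five = "ATG" + "GCT" * 9
        three = "GGC" * 20 + "TAA" + "GGC" * 5
        ft = _mk_ft(five, three, insert="GCA")
        cls, off = ftm.translate_and_classify(ft, 10)
        assert cls == ftm.IN_FRAME_FUSION and off == 21

    def test_break_before_start_codon_non_coding(self):
        ft = _mk_ft("GGGG", "ATGTAA", cds_start=10, retained=4)
        cls, off = ftm.translate_and_classify(ft, 10)
        assert cls == ftm.NON_CODING and off is None

    def test_no_stop_unterminated(self):
        ft = _mk_ft("ATG" + "GCT" * 5, "GGC" * 10)
        cls, off = ftm.translate_and_classify(ft, 10)
        assert cls == ftm.UNTERMINATED and off is None

    def test_matches_codon_scan_oracle_random(self):
        rng = np.random.default_rng(5)
        letters = "ACGT"
        for _ in range(300):
            five = "".join(
                letters[i] for i in rng.integers(0, 4, size=rng.integers(6, 90))
            )
            three = "".join(
                letters[i] for i in rng.integers(0, 4, size=rng.integers(6, 90))
            )
            insert = "".join(
                letters[i] for i in rng.integers(0, 4, size=rng.integers(0, 6))
            )
            cds_start = int(rng.integers(0, max(1, len(five) - 3)))
            ft = _mk_ft(five, three, insert=insert, cds_start=cds_start)
            cls, off = ftm.translate_and_classify(ft, 10)
            exp_cls, exp_off = _codon_scan_oracle(
                five + insert + three, cds_start, len(five), len(five), 10
            )
            assert (cls, off) == (exp_cls, exp_off)

    def test_padding_partner_beyond_stop_is_invariant(self, fos_bundle):
        b = fos_bundle
        r = b.truth.rearrangements[0]
        cleavage = b.truth.true_cleavage_site[b.carrier]
        results = []
        for pad in (0, 120, 300):
            ft = ftm.build_fusion_transcript(
                r, b.genome.genes, b.genome.sequences, cleavage + pad
            )
            results.append(ftm.translate_and_classify(ft, 10))
        assert results[0] == results[1] == results[2]

    def test_scenario_truth_match(self, fos_bundle, fosb_bundle):
        for b in (fos_bundle, fosb_bundle):
            r = b.truth.rearrangements[0]
            cleavage = b.truth.true_cleavage_site[b.carrier]
            ft = ftm.build_fusion_transcript(
                r, b.genome.genes, b.genome.sequences, cleavage
            )
            cls, _ = ftm.translate_and_classify(ft, 10)
            assert cls == b.truth.true_frame_class[b.carrier]


class TestFrameCompatible:
    @pytest.mark.parametrize(
        "up,ins,phase,expected",
        [
            (300, 3, 0, True),
            (300, 1, 0, False),
            (299, 1, 0, True),
            (10, 2, 0, True),
            (10, 0, 1, True),
        ],
    )
    def test_examples(self, up, ins, phase, expected):
        assert ftm.frame_compatible(up, ins, phase) is expected


class TestRegulatoryLoss:
    def _gene(self):
        return GeneModel(
            gene_id="gR",
            name="gR",
            body=GenomicInterval("chr1", 0, 1000, "+"),
            exons=[GenomicInterval("chr1", 0, 1000, "+")],
            cds_start=0,
            cds_end=600,
            regulatory_elements=[("MCRD", (300, 360)), ("ARE", (700, 760))],
        )

    def test_break_upstream_of_both(self):
        ft = _mk_ft("A" * 100, "G" * 50, retained=100)
        assert ftm.regulatory_loss(ft, self._gene()) == ["MCRD", "ARE"]

    def test_break_downstream_of_all(self):
        ft = _mk_ft("A" * 900, "G" * 50, retained=900)
        assert ftm.regulatory_loss(ft, self._gene()) == []

    def test_straddling_element_lost(self):
        ft = _mk_ft("A" * 330, "G" * 50, retained=330)
        assert ftm.regulatory_loss(ft, self._gene()) == ["MCRD", "ARE"]

    def test_fos_scenario_loses_both_elements(self, fos_bundle):
        b = fos_bundle
        r = b.truth.rearrangements[0]
        gene = b.genome.genes[0]
        cleavage = b.truth.true_cleavage_site[b.carrier]
        ft = ftm.build_fusion_transcript(
            r, b.genome.genes, b.genome.sequences, cleavage
        )
        assert ftm.regulatory_loss(ft, gene) == ["MCRD", "ARE"]
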