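import numpy as np
import pandas as pd
import pytest

from fuscan import breakpoint_analysis as bp
from fuscan import synthetic_data as sd
from fuscan.errors import AnalysisError, ConfigurationError
from fuscan.io_formats import (
    RETAINED_LEFT,
    RETAINED_RIGHT,
    BreakEnd,
    GeneModel,
    GenomicInterval,
    make_rearrangement,
)


@pytest.fixture(scope="module")
def toy_gene():
    return GeneModel(
        gene_id="gT",
        name="gT",
        body=GenomicInterval("chr1", 1000, 2000, "+"),
        exons=[
            GenomicInterval("chr1", 1000, 1200, "+"),
            GenomicInterval("chr1", 1800, 2000, "+"),
        ],
        cds_start=0,
        cds_end=300,
    )


class TestAnnotate:
    def test_exonic(self, toy_gene):
        ctx = bp.annotate_breakend(
            BreakEnd("chr1", 1100, RETAINED_LEFT), [toy_gene]
        )
        assert (ctx.category, ctx.gene_id, ctx.exon_index) == ("EXONIC", "gT", 1)

    def test_intronic(self, toy_gene):
        ctx = bp.annotate_breakend(
            BreakEnd("chr1", 1500, RETAINED_LEFT), [toy_gene]
        )
        assert (ctx.category, ctx.gene_id, ctx.exon_index) == (
            "INTRONIC",
            "gT",
            None,
        )

    def test_intergenic(self, toy_gene):
        ctx = bp.annotate_breakend(
            BreakEnd("chr1", 5000, RETAINED_LEFT), [toy_gene]
        )
        assert ctx.category == "INTERGENIC"
        assert ctx.gene_id is None and ctx.exon_index is None

    def test_exon_boundary_is_intronic(self, toy_gene):
        # half-open: a position equal to an exon end is past the exon
        ctx = bp.annotate_breakend(
            BreakEnd("chr1", 1200, RETAINED_LEFT), [toy_gene]
        )
        assert ctx.category == "INTRONIC"

    def test_spiked_exon4_break(self, fos_bundle):
        b = fos_bundle
        r = b.truth.rearrangements[0]
        ctx = bp.annotate_breakend(r.end1, b.genome.genes)
        assert ctx.category == "EXONIC"
        assert ctx.exon_index == 4
        assert ctx.gene_id == b.genome.genes[0].gene_id

    def test_partition_property(self, fos_bundle):
        """Interval-arithmetic oracle over random positions."""
        genes = fos_bundle.genome.genes
        rng = np.random.default_rng(17)

        def oracle(chrom, pos):
            for g in sorted(genes, key=lambda g: (g.body.chrom, g.body.start)):
                if g.body.chrom != chrom:
                    continue
                if g.body.start <= pos < g.body.end:
                    for i, e in enumerate(g.exons, 1):
                        if e.start <= pos < e.end:
                            return ("EXONIC", g.gene_id, i)
                    return ("INTRONIC", g.gene_id, None)
            return ("INTERGENIC", None, None)

        for _ in range(2000):
            chrom = f"chr{int(rng.integers(1, 3))}"
            pos = int(rng.integers(0, 50_000))
            ctx = bp.annotate_breakend(BreakEnd(chrom, pos, RETAINED_LEFT), genes)
            assert (ctx.category, ctx.gene_id, ctx.exon_index) == oracle(
                chrom, pos
            )


def _pair(p1, p2, o1=RETAINED_LEFT, o2=RETAINED_RIGHT, evidence="DNA"):
    return make_rearrangement(
        BreakEnd("chrA", p1, o1), BreakEnd("chrB", p2, o2), evidence=evidence
    )


class TestReconcile:
    def test_identical_zero_slack(self):
        d = [_pair(100, 200)]
        r = [_pair(100, 200, evidence="RNA")]
        out = bp.reconcile(d, r, 0)
        assert len(out) == 1 and out[0].evidence == "both"
        assert (out[0].end1.pos, out[0].end2.pos) == (100, 200)

    def test_slack_sensitivity(self):
        d = [_pair(100, 200)]
        r = [_pair(105, 200, evidence="RNA")]
        assert len(bp.reconcile(d, r, 10)) == 1
        assert len(bp.reconcile(d, r, 2)) == 0

    def test_orientation_mismatch_dropped(self):
        d = [_pair(100, 200, RETAINED_LEFT, RETAINED_RIGHT)]
        r = [_pair(100, 200, RETAINED_LEFT, RETAINED_LEFT, evidence="RNA")]
        assert bp.reconcile(d, r, 10) == []

    def test_negative_slack_rejected(self):
        with pytest.raises(ConfigurationError):
            bp.reconcile([], [], -1)

    def test_self_reconcile_identity(self):
        x = [_pair(100, 200), _pair(5000, 9000)]
        out = bp.reconcile(x, x, 0)
        assert [(o.end1.pos, o.end2.pos) for o in out] == [
            (r.end1.pos, r.end2.pos) for r in x
        ]

    def test_idempotent_and_subset(self):
        rng = np.random.default_rng(3)
        dna = [
            _pair(int(p), int(p) + 5000)
            for p in rng.integers(0, 10**6, size=20)
        ]
        rna = [
            make_rearrangement(
                BreakEnd("chrA", d.end1.pos + int(rng.integers(-8, 9)), d.end1.orientation),
                BreakEnd("chrB", d.end2.pos + int(rng.integers(-8, 9)), d.end2.orientation),
                evidence="RNA",
            )
            for d in dna[:10]
        ]
        out = bp.reconcile(dna, rna, 10)
        again = bp.reconcile(out, rna, 10)
        assert [(o.end1.pos, o.end2.pos) for o in again] == [
            (o.end1.pos, o.end2.pos) for o in out
        ]
        dna_keys = {(d.end1.pos, d.end2.pos) for d in dna}
        assert all((o.end1.pos, o.end2.pos) in dna_keys for o in out)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            slack = int(rng.integers(0, 15))
            dna = [
                _pair(int(p), int(p) + 400)
                for p in rng.integers(0, 10**6, size=15)
            ]
            rna = [
                make_rearrangement(
                    BreakEnd(
                        "chrA",
                        max(0, d.end1.pos + int(rng.integers(-20, 21))),
                        d.end1.orientation,
                    ),
                    BreakEnd(
                        "chrB",
                        d.end2.pos + int(rng.integers(-20, 21)),
                        d.end2.orientation,
                    ),
                    evidence="RNA",
                )
                for d in dna
                if rng.random() < 0.7
            ]

            def brute(d):
                for r in rna:
                    if (
                        d.end1.chrom == r.end1.chrom
                        and d.end2.chrom == r.end2.chrom
                        and abs(d.end1.pos - r.end1.pos) <= slack
                        and abs(d.end2.pos - r.end2.pos) <= slack
                        and d.end1.orientation == r.end1.orientation
                        and d.end2.orientation == r.end2.orientation
                    ):
                        return True
                return False

            expected = [d for d in dna if brute(d)]
            out = bp.reconcile(dna, rna, slack)
            assert [(o.end1.pos, o.end2.pos) for o in out] == [
                (e.end1.pos, e.end2.pos) for e in expected
            ]


class TestReadSupport:
    def test_empty(self):
        r = _pair(1000, 2000)
        empty = pd.DataFrame(columns=["read", "mate", "chrom", "start", "end"])
        assert bp.count_supporting_reads(empty, r, 10) == (0, 0)

    def test_simulated_counts(self, fos_bundle):
        b = fos_bundle
        r = b.truth.rearrangements[0]
        reads = b.reads[b.carrier]
        assert bp.count_supporting_reads(reads, r, 10) == (3, 2)

    def test_distant_junction_gives_zero(self, fos_bundle):
        b = fos_bundle
        r = b.truth.rearrangements[0]
        shifted = make_rearrangement(
            BreakEnd(r.end1.chrom, r.end1.pos + 10_000, r.end1.orientation),
            BreakEnd(r.end2.chrom, r.end2.pos + 10_000, r.end2.orientation),
        )
        reads = b.reads[b.carrier]
        assert bp.count_supporting_reads(reads, shifted, 10) == (0, 0)


class TestMonoallelic:
    def test_single_call_not_flagged(self, fos_bundle):
        b = fos_bundle
        records = bp.check_monoallelic(
            b.truth.rearrangements, b.genome.genes, 10
        )
        (rec,) = records
        assert rec.breakpoint_count == 1 and not rec.flagged

    def test_nearby_calls_merged(self, toy_gene):
        calls = [
            _pair(1100, 500_000),
            _pair(1103, 600_000),
        ]
        calls = [
            make_rearrangement(
                BreakEnd("chr1", c.end1.pos, c.end1.orientation),
                BreakEnd("chr9", c.end2.pos, c.end2.orientation),
                sample_id="s1",
            )
            for c in calls
        ]
        (rec,) = bp.check_monoallelic(calls, [toy_gene], 10)
        assert rec.breakpoint_count == 1 and not rec.flagged

    def test_distant_calls_flagged(self, toy_gene):
        calls = [
            make_rearrangement(
                BreakEnd("chr1", p, RETAINED_LEFT),
                BreakEnd("chr9", 10_000, RETAINED_RIGHT),
                sample_id="s1",
            )
            for p in (1050, 1950)
        ]
        (rec,) = bp.check_monoallelic(calls, [toy_gene], 10)
        assert rec.breakpoint_count == 2 and rec.flagged


class TestClusterWindow:
    def test_single(self):
        assert bp.minimal_cluster_window([123]) == 1

    def test_arithmetic(self):
        assert bp.minimal_cluster_window([100, 150, 299]) == 200

    def test_empty_raises(self):
        with pytest.raises(AnalysisError):
            bp.minimal_cluster_window([])

    def test_simulated_exon4_cluster(self):
        """Breaks spiked uniformly in the 200-bp window stay within it."""
        positions = []
        for seed in range(6):
            b = sd.build_scenario("fos-like", 100 + seed)
            positions.append(b.truth.rearrangements[0].end1.pos)
        assert bp.minimal_cluster_window(positions) <= 200
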