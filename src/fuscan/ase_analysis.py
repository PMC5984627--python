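"""Allele-specific expression at heterozygous SNPs.

Heterozygous biallelic SNVs are taken from DNA genotype calls, RNA allele
counts are accumulated from quality-filtered pileup observations, and
allelic imbalance is tested per SNP with a two-sided exact binomial test
against 0.5, Benjamini-Hochberg adjusted across the run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel, GenomicInterval

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class HetSNP:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt or self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"invalid het SNP {self.ref}>{self.alt}")


@dataclass(frozen=True)
class AlleleCount:
    snp: HetSNP
    ref_count: int
    alt_count: int
    other_count: int
    low_coverage: bool = False
    imbalance_p: float | None = None
    imbalance_q: float | None = None

    @property
    def informative(self) -> int:
        return self.ref_count + self.alt_count


def select_het_snps(
    genotypes: Sequence[dict],
    regions: Sequence[GenomicInterval] | Sequence[GeneModel],
) -> list[HetSNP]:
    """Heterozygous biallelic SNVs falling in the target regions.

    ``genotypes`` are VCF records as returned by io_formats.read_vcf.
    Indels, multi-allelic sites and homozygous genotypes are excluded.
    """
    intervals = [
        r.body if isinstance(r, GeneModel) else r for r in regions
    ]
    out = []
    for rec in genotypes:
        if rec.get("gt") is None or set(rec["gt"]) != {0, 1}:
            continue
        alts = rec.get("alts") or ()
        if len(alts) != 1:
            continue
        ref, alt = rec["ref"], alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            continue
        if any(
            iv.chrom == rec["chrom"] and iv.contains(rec["pos"])
            for iv in intervals
        ):
            out.append(HetSNP(rec["chrom"], rec["pos"], ref, alt))
    return out


def count_alleles(
    pileup: pd.DataFrame,
    snps: Sequence[HetSNP],
    min_base_qual: int = 20,
    min_map_qual: int = 20,
) -> list[AlleleCount]:
    """Quality-filtered ref/alt/other counts per SNP.

    Reads below either quality threshold are discarded. An uncovered SNP
    yields a zero-count record flagged low-coverage.
    """
    if pileup.empty:
        filtered = pileup
    else:
        filtered = pileup[
            (pileup["base_qual"] >= min_base_qual)
            & (pileup["map_qual"] >= min_map_qual)
        ]
    out = []
    for snp in snps:
        if filtered.empty:
            rows = filtered
        else:
            rows = filtered[
                (filtered["chrom"] == snp.chrom) & (filtered["pos"] == snp.pos)
            ]
        ref_n = int((rows["base"] == snp.ref).sum()) if len(rows) else 0
        alt_n = int((rows["base"] == snp.alt).sum()) if len(rows) else 0
        other = int(len(rows)) - ref_n - alt_n
        out.append(
            AlleleCount(
                snp=snp,
                ref_count=ref_n,
                alt_count=alt_n,
                other_count=other,
                low_coverage=len(rows) == 0,
            )
        )
    return out


def test_imbalance(counts: Sequence[AlleleCount]) -> list[AlleleCount]:
    """Two-sided exact binomial test against 0.5 per SNP, BH-adjusted.

    SNPs with zero informative reads keep p = q = None and stay flagged;
    they do not enter the multiple-testing adjustment.
    """
    tested_idx = [i for i, c in enumerate(counts) if c.informative >= 1]
    pvals = []
    for i in tested_idx:
        c = counts[i]
        pvals.append(
            binomtest(c.alt_count, c.informative, 0.5, alternative="two-sided").pvalue
        )
    qvals = (
        multipletests(pvals, method="fdr_bh")[1] if pvals else []
    )
    out = list(counts)
    for i, p, q in zip(tested_idx, pvals, qvals):
        out[i] = replace(out[i], imbalance_p=float(p), imbalance_q=float(q))
    return out


__all__ = [
    "HetSNP",
    "AlleleCount",
    "select_het_snps",
    "count_alleles",
    "test_imbalance",
]
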