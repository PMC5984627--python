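# fuscan

Characterisation of oncogenic structural rearrangements from paired DNA and
RNA sequencing call sets, built around the analysis pattern of
promoter-preserving gene fusions that terminate at cryptic polyadenylation
sites:

* **Break-end annotation & reconciliation** — classify break ends as
  exonic / intronic / intergenic against a gene model, keep DNA calls
  corroborated by RNA calls (positions + orientations within a slack),
  count split-read / discordant-pair support, and QC the single-break-point
  (mono-allelic) expectation.
* **Fusion-transcript reconstruction** — assemble the predicted mutant
  transcript across the junction (including splice-donor skip /
  intron exonisation and non-template inserts), translate from the native
  start codon and classify the outcome as `TRUNCATING`,
  `IN_FRAME_FUSION`, `NON_CODING` or `UNTERMINATED`; report loss of
  annotated 3' regulatory elements.
* **Cryptic polyadenylation calling** — normalise per-base coverage by the
  mean of per-gene counts (×10³), flag tumour-specific expression peaks,
  scan the transcribed strand for the AATAAA signal, and place the
  cleavage site 10–30 bp downstream of a motif at the greatest coverage
  drop in the surrounding 200 bp.
* **Allele-specific expression** — quality-filtered allele counts at
  heterozygous SNPs with an exact binomial imbalance test (BH-adjusted).
* **Driver screen** — literal cancer-gene filtering rules: deleterious
  variants in tumour suppressors, oncogene hotspots, focal (<1 Mb)
  homozygous deletions, focal amplifications to ≥5 copies of the intact
  gene, and disruptive break ends in tumour suppressors.
* **Synthetic data** — deterministic toy genomes with spiked
  rearrangements, coverage tracks, pileups and copy-number profiles plus a
  machine-readable ground-truth record, so the whole pipeline is testable
  offline.

## CLI

```bash
# generate a synthetic scenario (fos-like | fosb-like | negative)
fuscan simulate --scenario fos-like --seed 1 --out-dir sim/

# run the full pipeline over the emitted config; one JSON report per sample
fuscan report --config sim/config.yaml --out-dir reports/

# individual stages
fuscan annotate-sv --annotation sim/annotation.gff3 \
    --dna sim/S1.dna.bedpe --rna sim/S1.rna.bedpe --out sv.tsv
fuscan call-polya --genome sim/genome.fa --coverage sim/S1.coverage.bedgraph \
    --gene-counts sim/S1.gene_counts.tsv --region chr2:38300-39100 --out polya.bed
fuscan ase --genotypes sim/germline.vcf --pileup sim/S1.pileup.tsv \
    --annotation sim/annotation.gff3 --genes g1 --out ase.tsv
fuscan drivers --annotation sim/annotation.gff3 --cancer-genes sim/cancer_genes.tsv \
    --variants sim/S1.variants.vcf --copy-number sim/S1.cn.tsv --out drivers.tsv

# cohort arithmetic (per-gene positive counts -> combined percent)
fuscan cohort --counts FOS=48,FOSB=1 --size 55 --out cohort.tsv
```

## Conventions

All internal coordinates are 0-based half-open; GFF3 and VCF are converted
at the I/O boundary (`io_formats.to_gff_coords` / `from_gff_coords`). BEDPE
strand `+` means the retained segment ends at the break position,
`-` that it starts there. Package-specific TSVs (pileup, copy-number,
read segments) use 0-based positions. A called `cleavage_site` is the
first position past the transcript end.
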