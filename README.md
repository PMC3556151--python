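# snpassay

Transcriptome-based SNP discovery and fixed-array genotyping assay design
for non-model diploids.

When no reference genome exists for a species, SNP markers for linkage
mapping are typically mined from short-read transcriptome data of the
mapping-population parents: reads are aligned to de novo contigs, variants
are called into consensus-pileup files, and surviving candidates are
submitted to a fixed-content genotyping chemistry (GoldenGate-style) that
interrogates each SNP through oligos hybridizing to its 50 bp flanks.
Two things silently kill such assays: an exon–intron boundary of the
(unknown) gene structure falling inside the oligo footprint, and
paralogous loci co-amplifying.  `snpassay` implements the full desk side
of this workflow for an interspecific hybrid cross:

* **pileup_io** — parse/write 10-column consensus pileups, decode the
  read-base grammar, and compute per-site allele accounts: reference,
  non-reference, major and minor allele frequencies (MAF).
* **refmerge** — merge two de novo assemblies into a non-redundant
  reference, keeping the longer contig of every orthologous pair
  (alignment ≥ 200 bp, identity > 90%).
* **snpfilter** — the staged candidate cascade: the six-rule base filter
  (mapping and SNP quality > 20, depth ≥ 10, ≥ 3 non-reference reads,
  exactly two alleles, MAF ≥ 5%, major+minor frequency ≥ 0.95), the
  stringency raise (SNP score ≥ 50 and MAF ≥ 8%), and per-individual
  score cutoffs; plus cross-individual dedup accounting.
* **consensus** — per-parent consensus tracks and the combined 4-parent
  consensus with heterozygous, interspecific and multi-allelic sites
  masked by IUPAC codes or N.
* **assaydesign** — 50+1+50 bp flank extraction, the flank-ambiguity
  filter (drop SNPs with > 4 ambiguity codes in the flanks), marker
  naming (`<contig>_<pos>`), the design submission CSV, and filtering by
  returned design scores (≥ 0.4).
* **genomeanno** — exon–intron boundary projection from a related
  reference genome's gene models through BLAST alignments (gap-aware
  column walk, both strands), flagging SNPs within 35 bp of a projected
  junction, and paralog detection (self-similarity > 90%, shared best
  hits, multi-transcript hits).
* **genoeval** — genotype-matrix classification (failed / monomorphic /
  interspecific / paralog-suspect / testcross / intercross, with
  chi-square segregation checks) and every panel statistic: assay
  success, conversion and validation rates, transferability, caller
  sensitivity and false-negative rate, germplasm polymorphism and MAF,
  replicate reproducibility.
* **synthfix** — a seeded synthetic-study generator (assemblies, planted
  SNPs, pileups, alignments, genotype matrices with known classes) so
  every stage is testable end to end with recorded ground truth.

Key rate definitions: *success* = successful assays / total assays,
*conversion* = polymorphic SNPs / total assays, *validation* =
polymorphic SNPs / successful assays, so conversion = validation ×
success holds exactly at count level.

## Worked example

Simulate a small study (12 genes, four parents, mean depth 30×) and run
every stage:

```python
from snpassay.cli import PipelineConfig, run_pipeline

cfg = PipelineConfig(workdir="demo", seed=7, n_genes=12, length_max=700)
run_pipeline(cfg)
```

This writes, among other artifacts, `design.csv` (the assay submission,
15 markers for this seed), `final_snps.tsv` (14 markers after boundary
and paralog screening), and `evaluation.json`:

```json
{
 "WD": {"n_total": 28, "n_successful": 28, "n_polymorphic": 7,
        "success_rate": 100.0, "conversion_rate": 25.0, "validation_rate": 25.0},
 "FL": {"n_total": 28, "n_successful": 28, "n_polymorphic": 8,
        "success_rate": 100.0, "conversion_rate": 28.6, "validation_rate": 28.6},
 "transferability_WD_to_FL": 0.0
}
```

Read: all 28 simulated assays produced calls in both mapping populations;
7 segregate in the WD cross and 8 in the FL cross (each planted
heterozygous SNP belongs to one parent, hence polymorphic in exactly one
population — which is also why no WD marker transfers to FL here).  A
design row looks like

```
AA_C0002_336,CATTAGCC...TCGCGTC[C/A]TTGTCCG...AGTGCTTCTC,SNP,hybrid,transcriptome
```

i.e. marker `AA_C0002_336` is the C/A SNP at position 336 of reference
contig `AA_C0002`, flanked by 50 consensus bases on each side.

The same stages are available as a CLI
(`snpassay simulate|refmerge|count|filter|consensus|design|evaluate|run`),
e.g. `snpassay run --config pipeline.yaml --seed 7`.

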