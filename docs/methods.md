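# Methods

## The procedure and its assumptions

The package models marker development for an F1 interspecific hybrid
cross with four diploid parents (two per species, one per species in each
of two mapping populations).  Discovery operates on consensus-pileup
files — one per parent, aligned against a merged non-redundant reference
built from two de novo transcriptome assemblies — and everything
downstream assumes:

* SNPs are substitution polymorphisms; indels are not modelled as
  markers (inserted/deleted sequences in the pileup are decoded but
  excluded from allele counts).
* The pileup's SNP quality column ("SNP score", phred-scaled) and RMS
  mapping quality are trusted as produced by the caller; the package
  never recomputes them.
* Strand is ignored in allele accounting (forward/reverse events are
  merged case-insensitively); base qualities do not weight counts.
* Genotype calls (AA/AB/BB/NC) are consumed as produced by the
  genotyping platform's clustering; the package classifies and rates
  them but does not cluster intensities.

## Filter cascade semantics

Threshold directions follow the wording they encode: "more than 20" is
strict (> 20) for mapping and SNP quality; "at least" bounds (depth ≥ 10,
≥ 3 non-reference reads, MAF ≥ 5%, major+minor ≥ 0.95) are inclusive.
The stringency raise is inclusive at score ≥ 50 and MAF ≥ 8% because the
weakest independently validated site (score 52, MAF exactly 8%) must
survive it; per-individual score cutoffs are inclusive by analogy.
"Bi-allelic" is operationalized as exactly two of A/C/G/T with count
≥ 1 — the preceding depth, non-reference and major+minor rules already
bound how much sequencing noise can reach this test.

Frequencies use the A+C+G+T substitution denominator; deletion events
(`*`) are tracked but excluded, since every filter reasons about
substitution alleles.  Consequently major+minor frequency equals 1
exactly when at most two alleles are observed, regardless of deletions.
An ambiguous reference base (N) defines reference-allele frequency 0.

The multi-individual total uses the published bookkeeping: sum of
per-individual counts minus the number of keys (contig, position,
unordered allele pair) present in ≥ 2 individuals.  This equals the exact
union size only when no key occurs in ≥ 3 individuals — it overcounts
otherwise — so the shared-key set is returned alongside the total and the
equivalence is property-tested.

## Consensus and ambiguity classification

Per-parent consensus over each reference contig: no coverage → N;
filtered SNP → two-base IUPAC code of its alleles; ≥ 3 observed alleles
→ N; reference allele absent with a single fixed alternate → that
alternate (this one rule covers both true fixed differences and assembly
base errors, which are observationally identical); otherwise the
reference base.  A covered site where the reference is absent but two
alternates segregate without having passed the filters is masked N
rather than silently assigned.

The combined track pools per-position base-set unions across parents,
with a parent's N contributing *no* evidence (treating N as "all bases"
would mask every site any parent failed to cover).  Four-base unions
emit N rather than the four-fold degeneracy code: downstream treats both
identically when counting flank ambiguities, and N additionally marks
the site itself as undesignable.  Flank ambiguity symbols are classified
secondary (any single parent heterozygous) before interspecific (each
species fixed, bases differing) — the two cannot co-occur, but partial
coverage cases resolve deterministically in that order — and N otherwise.

## Boundary projection

Exon junctions are represented by one coordinate: the contig position
aligned to the last base of a reference exon.  With aligned sequence
strings the projection walks alignment columns (query advances on
non-gap query characters, subject on non-gap subject characters, subject
direction reversed on minus-strand HSPs) and reports the query cursor
where the subject cursor hits the junction; if the junction falls in a
query deletion, the last consumed query base is reported.  Without
strings a linear within-HSP offset is used and documented as approximate
for gapped alignments.  Junctions outside every HSP are not reported.
The exclusion window around a SNP is ± 35 bp inclusive, in contig
coordinates; failed real-world assays have shown boundaries at exactly
35 bp from the SNP, so 35 sits inside the exclusion zone.

Paralog self-similarity requires > 90% identity *and* an HSP of ≥ 100 bp;
the length floor is this package's addition so that a trivial short
repeat cannot condemn a whole contig.

## Genotype classification

Segregation is tested with Pearson's chi-square (no continuity
correction) against 1:1 (testcross) or 1:2:1 (intercross) at α = 0.05 on
called progeny only; a heterozygous-parent SNP whose progeny reject the
ratio is demoted to monomorphic with a warning.  Replicated parent
samples are collapsed to one call and must agree; a missing or
discordant parent call is a classification error, not a silent default.
Interspecific SNPs (parents fixed for different alleles) count as
successful but not polymorphic in conversion/validation rates, and are
reported separately because they discriminate hybrids.  An all-
heterozygous profile including both parents is classified
paralog-suspect.  Percentages are presented half-up at one decimal; the
false-negative rate is defined as the complement of sensitivity so the
pair sums to 100.0 after rounding.

## The synthetic-data generator

`synthfix` emulates the study conditions, not the sequencing process:
per-site Poisson depth (default mean 30×, matching a realistic
transcriptome coverage for filter thresholds of depth ≥ 10), binomial
0.5 alternate fraction at heterozygous sites, species-fixed alleles at
interspecific sites, three-allele mixtures at planted collapsed-paralog
sites, and *per-site* errors at rate 0.005 showing one or two wrong-base
reads with SNP score ≤ 20 (planted variant sites score ≥ 100, the
observed score range of real panels being 20–228).  Assemblies are
full-length vs end-truncated copies; paralog pairs are substitution-only
duplicates at 92% identity sharing their template's reference
transcript, as duplicated genes do; ~30% of contigs are reverse-oriented
relative to the reference transcript to exercise minus-strand
projection.  Alignments emitted by the generator are exact and gap-free
(gapped projection is covered by randomized property tests instead), and
reads, mapping artifacts and base-quality structure are not simulated —
so passing tests demonstrate the correctness of the bookkeeping, masking,
projection and statistics on cleanly aligned data, not robustness to
mapper-specific artifacts.

Genotype matrices draw progeny from the exact segregation model
(binomial/multinomial), or deterministic idealized ratios when
``exact_ratios`` is set — used when reconstructing published panels whose
class counts are fixed, since a 5% chi-square demotion rate would
otherwise be built into any large planted panel.  All randomness derives
from a master seed with one independent stream per operation
(`op_rng(seed, tag)`), so every artifact regenerates byte-identically.

## Problem sizes and tolerances

The default test study uses 10–12 genes of 300–700 bp, four parents at
30× — about 2 × 10⁴ pileup records per parent — which the full pipeline
processes in a few seconds while still planting every SNP class, both
orientations and paralog pairs.  Panel reconstructions use the published
compositions verbatim (96 and 768 assays; 24 and 174 progeny per
population).  Stochastic recovery assertions carry a ±2% sampling
allowance; exact-arithmetic checks (rates from counts, projections on
exact alignments, round trips) use equality.

## Known limitations

* Boundary projection is only as good as the contig–transcript
  alignment; genes absent from the related reference genome cannot be
  screened (in the real study, 39.7% of failed assays had no reference
  hit).
* Paralog detection from transcriptome self-hits misses duplicates that
  were not assembled; the multi-transcript rule flags any second hit,
  which may over-flag genes with conserved domains.
* The dedup total is the published formula, not a union cardinality; the
  two diverge when a SNP recurs in three or more individuals.
* Oligo binding sites (~19–29 bp from the SNP) are represented only as
  the flank annotation window; oligo sequences are not generated.
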