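"""Synthetic study inputs with recorded ground truth.

Every pipeline stage is exercisable without any external download: this
module fabricates a small diploid study in the image of the real one —
two de novo assemblies of the same transcriptome (with truncated contig
copies), four parents from two species carrying planted heterozygous,
interspecific and tri-allelic sites, per-parent consensus pileups, exact
BLAST-style alignments of contigs against a related reference's spliced
transcripts (including reverse-orientation contigs and paralog pairs
diverged to a stated identity), and genotype matrices with known
per-population classes.  All randomness derives from a single master
seed, with one independent stream per operation, so regeneration is
byte-identical.

What the generator does not emulate: read-level sequencing (no FASTQ or
mapper artifacts), base-quality-dependent calling, indel polymorphism,
and alignment gaps in the reference projection (those are covered by
randomized gapped-alignment property tests instead).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .genomeanno import BlastHit, Hsp
from .pileup_io import PileupRecord
from . import iupac

__all__ = [
    "PlantedSnp",
    "SynthGene",
    "TruthSet",
    "PARENTS",
    "SPECIES_MAP",
    "op_rng",
    "make_transcriptome",
    "make_pileups",
    "make_blast_tables",
    "make_genotype_matrix",
    "write_fixture_dir",
]

# study layout mirrored by defaults: two species, two parents each,
# two mapping populations (one parent per species in each)
PARENTS = ("AA6", "AM20", "AA3", "AM22")
SPECIES_MAP = {"AA6": "AA", "AA3": "AA", "AM20": "AM", "AM22": "AM"}
POPULATION_PARENTS = {"WD": ("AA6", "AM20"), "FL": ("AA3", "AM22")}

_BASES = np.array(list("ACGT"))


def op_rng(seed: int, tag: str) -> np.random.Generator:
    """Independent, reproducible stream for one named operation."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(tag.encode())])


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]


@dataclass(frozen=True)
class PlantedSnp:
    contig_id: str
    pos: int                 # 1-based on the merged reference contig
    ref: str
    alt: str
    cls: str                 # "het" | "interspecific" | "triallelic"
    carrier: str             # parent id for het; alt-fixed species for
    #                          interspecific; "" for triallelic
    alt2: str | None = None  # third allele at tri-allelic sites


@dataclass
class SynthGene:
    gene_id: str
    transcript_id: str
    exon_lengths: tuple
    contig_id: str           # the merged-reference (longer) contig id
    seq: str                 # reference contig sequence (contig orientation)
    orientation: str         # contig vs reference transcript: "+" or "-"
    paralog_group: int | None = None

    @property
    def length(self) -> int:
        return len(self.seq)

    def true_boundaries(self) -> tuple:
        """Exon-junction positions in contig coordinates (projection
        convention: the contig base aligned to the last base of each
        reference exon)."""
        cum, out = 0, []
        for l in self.exon_lengths[:-1]:
            cum += l
            b = cum
            out.append(b if self.orientation == "+" else self.length - b + 1)
        return tuple(sorted(out))


@dataclass
class TruthSet:
    seed: int
    genes: list
    assembly_a: dict         # contig id -> sequence
    assembly_b: dict
    reference: dict          # merged reference: contig id -> sequence
    transcripts: dict        # reference-species transcript id -> sequence
    coords_rows: list        # alignment table rows (assembly A vs B)
    snps: list               # PlantedSnp
    paralog_groups: list     # list of contig-id tuples

    def snps_on(self, contig_id: str) -> list:
        return [s for s in self.snps if s.contig_id == contig_id]


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _split_exons(rng, total: int, n_exons: int, min_exon: int = 60) -> tuple:
    """Random composition of ``total`` into ``n_exons`` parts >= min_exon."""
    free = total - n_exons * min_exon
    cuts = np.sort(rng.integers(0, free + 1, n_exons - 1))
    parts = np.diff(np.concatenate(([0], cuts, [free])))
    return tuple(int(p) + min_exon for p in parts)


def make_transcriptome(
    n_genes: int = 50,
    length_range: tuple = (300, 1500),
    intron_rate: float = 0.4,
    paralog_rate: float = 0.1,
    identity: float = 0.92,
    reverse_rate: float = 0.3,
    snps_per_gene_mean: float = 2.0,
    seed: int = 0,
) -> TruthSet:
    """Build the study's sequence layer.

    Emits two assemblies (one full-length and one end-truncated copy per
    gene, the full copy randomly assigned to either assembly), reference-
    species gene models whose spliced transcripts align exactly to the
    contigs (a fraction in reverse orientation), paralog pairs diverged to
    ``identity``, and planted SNPs of the three classes.
    """
    lo, hi = length_range
    if lo < 220 or hi < lo:
        raise ValueError("length_range must be (lo, hi) with lo >= 220")
    if not (0 < identity < 1):
        raise ValueError("paralog identity must be in (0, 1)")
    rng = op_rng(seed, "transcriptome")

    genes: list[SynthGene] = []
    paralog_groups: list[tuple] = []
    raw: list[dict] = []
    for i in range(n_genes):
        total = int(rng.integers(lo, hi + 1))
        multi = rng.random() < intron_rate
        n_exons = int(rng.integers(2, 5)) if multi else 1
        exon_lengths = _split_exons(rng, total, n_exons) if multi else (total,)
        seq = _random_seq(rng, total)
        raw.append({"seq": seq, "exon_lengths": exon_lengths, "group": None,
                    "template_idx": None})
        if rng.random() < paralog_rate:
            # diverged duplicate sharing the template's gene structure and
            # (as for real duplicated genes) its reference transcript
            template_idx = len(raw) - 1
            raw[-1]["group"] = len(paralog_groups)
            arr = np.array(list(seq))
            n_sub = rng.binomial(total, 1.0 - identity)
            sites = rng.choice(total, size=n_sub, replace=False)
            for p in sites:
                choices = [b for b in "ACGT" if b != arr[p]]
                arr[p] = choices[rng.integers(0, 3)]
            raw.append({"seq": "".join(arr), "exon_lengths": exon_lengths,
                        "group": len(paralog_groups),
                        "template_idx": template_idx})
            paralog_groups.append(())

    assembly_a: dict[str, str] = {}
    assembly_b: dict[str, str] = {}
    reference: dict[str, str] = {}
    transcripts: dict[str, str] = {}
    coords_rows: list[str] = []
    group_members: dict[int, list[str]] = {}

    for i, spec in enumerate(raw):
        seq = spec["seq"]
        total = len(seq)
        a_id, b_id = f"AA_C{i:04d}", f"AM_C{i:04d}"
        # end-truncate one copy, keep the other full; the full copy is the
        # truth-longer contig the reference merge must recover
        t0 = int(rng.integers(10, max(11, total // 8)))
        t1 = int(rng.integers(10, max(11, total // 8)))
        truncated = seq[t0:total - t1]
        a_full = bool(rng.random() < 0.5)
        if a_full:
            assembly_a[a_id], assembly_b[b_id] = seq, truncated
            ref_id = a_id
            coords_rows.append(
                f"{t0 + 1}\t{total - t1}\t1\t{len(truncated)}\t"
                f"{len(truncated)}\t{len(truncated)}\t100.0\t{a_id}\t{b_id}")
        else:
            assembly_a[a_id], assembly_b[b_id] = truncated, seq
            ref_id = b_id
            coords_rows.append(
                f"1\t{len(truncated)}\t{t0 + 1}\t{total - t1}\t"
                f"{len(truncated)}\t{len(truncated)}\t100.0\t{a_id}\t{b_id}")
        reference[ref_id] = seq

        if spec["template_idx"] is not None:
            template = genes[spec["template_idx"]]
            orientation, tid = template.orientation, template.transcript_id
        else:
            orientation = "-" if rng.random() < reverse_rate else "+"
            tid = f"Mt_T{i:04d}"
            transcripts[tid] = _revcomp(seq) if orientation == "-" else seq
        gene = SynthGene(
            gene_id=f"g{i:04d}", transcript_id=tid,
            exon_lengths=spec["exon_lengths"], contig_id=ref_id,
            seq=seq, orientation=orientation, paralog_group=spec["group"])
        genes.append(gene)
        if spec["group"] is not None:
            group_members.setdefault(spec["group"], []).append(ref_id)

    paralog_groups = [tuple(v) for v in group_members.values() if len(v) >= 2]

    # plant SNPs on reference contigs, clear of contig ends so flanks exist
    snps: list[PlantedSnp] = []
    for gene in genes:
        n_snp = int(rng.poisson(snps_per_gene_mean))
        usable = np.arange(56, gene.length - 55)
        if n_snp == 0 or len(usable) == 0:
            continue
        taken: set[int] = set()
        positions = rng.choice(usable, size=min(n_snp, len(usable)), replace=False)
        for pos in sorted(int(p) for p in positions):
            if any(abs(pos - t) < 3 for t in taken):
                continue
            taken.add(pos)
            ref = gene.seq[pos - 1]
            others = [b for b in "ACGT" if b != ref]
            alt = others[rng.integers(0, 3)]
            u = rng.random()
            if u < 0.60:
                cls, carrier, alt2 = "het", PARENTS[rng.integers(0, 4)], None
            elif u < 0.85:
                cls, carrier, alt2 = "interspecific", ("AA", "AM")[rng.integers(0, 2)], None
            else:
                rest = [b for b in others if b != alt]
                cls, carrier, alt2 = "triallelic", "", rest[rng.integers(0, 2)]
            snps.append(PlantedSnp(gene.contig_id, pos, ref, alt, cls, carrier, alt2))

    return TruthSet(
        seed=seed, genes=genes, assembly_a=assembly_a, assembly_b=assembly_b,
        reference=reference, transcripts=transcripts, coords_rows=coords_rows,
        snps=snps, paralog_groups=paralog_groups)


def _parent_alleles(snp: PlantedSnp, parent: str) -> tuple:
    """Diploid allele pair of one parent at a planted site."""
    if snp.cls == "het":
        return (snp.ref, snp.alt) if parent == snp.carrier else (snp.ref, snp.ref)
    if snp.cls == "interspecific":
        fixed = snp.alt if SPECIES_MAP[parent] == snp.carrier else snp.ref
        return (fixed, fixed)
    return (snp.ref, snp.alt)  # triallelic: handled specially in pileups


def make_pileups(
    truth: TruthSet,
    depth_mean: float = 30.0,
    error_rate: float = 0.005,
    seed: int | None = None,
) -> dict:
    """Per-parent consensus-pileup records over the merged reference.

    Depth is Poisson(``depth_mean``).  At a parent's heterozygous site the
    alternate-read count is Binomial(depth, 0.5); interspecific sites are
    fixed per species; tri-allelic sites show three alleles in every
    parent (the signature of a collapsed paralog).  Sequencing error is
    modelled per *site*: each non-variant position independently becomes
    an error site with probability ``error_rate``, showing one or two
    reads of a random wrong base and a low (<= 20) SNP score; variant
    sites get a high (>= 100) score.
    """
    if seed is None:
        seed = truth.seed
    out: dict[str, list[PileupRecord]] = {}
    snp_at = {}
    for s in truth.snps:
        snp_at[(s.contig_id, s.pos)] = s
    for parent in PARENTS:
        rng = op_rng(seed, f"pileup:{parent}")
        records: list[PileupRecord] = []
        for cid in sorted(truth.reference):
            seq = truth.reference[cid]
            n = len(seq)
            depths = rng.poisson(depth_mean, n)
            err_site = rng.random(n) < error_rate
            for pos in range(1, n + 1):
                depth = int(depths[pos - 1])
                ref = seq[pos - 1]
                snp = snp_at.get((cid, pos))
                events: list[str] = []
                observed = {ref} if depth else set()
                snp_qual = 0
                if snp is not None and depth > 0:
                    if snp.cls == "triallelic":
                        k1 = rng.binomial(depth, 0.3)
                        k2 = rng.binomial(depth - k1, 0.3 / 0.7) if depth > k1 else 0
                        events = [snp.alt] * k1 + [snp.alt2] * k2 \
                            + ["."] * (depth - k1 - k2)
                        observed |= {snp.alt, snp.alt2}
                    else:
                        a1, a2 = _parent_alleles(snp, parent)
                        if a1 == a2:
                            events = ["."] * depth if a1 == ref else [a1] * depth
                            observed = {a1}
                        else:
                            k = rng.binomial(depth, 0.5)
                            alt = a2 if a1 == ref else a1
                            events = [alt] * k + ["."] * (depth - k)
                            observed = {ref, alt} if k else {ref}
                    if observed != {ref}:
                        snp_qual = int(100 + rng.integers(0, 129))
                elif depth > 0:
                    events = ["."] * depth
                    if err_site[pos - 1]:
                        n_err = min(depth, int(rng.integers(1, 3)))
                        wrong = [b for b in "ACGT" if b != ref][rng.integers(0, 3)]
                        for j in range(n_err):
                            events[j] = wrong
                        observed.add(wrong)
                        snp_qual = int(rng.integers(1, 21))
                cons = iupac.code_for(observed) if observed else "N"
                records.append(PileupRecord(
                    contig_id=cid, pos=pos, ref_base=ref,
                    consensus_base=cons, consensus_qual=30,
                    snp_qual=snp_qual, rms_mapq=60, depth=depth,
                    read_bases="".join(events), base_quals="I" * depth))
        out[parent] = records
    return out


def make_blast_tables(truth: TruthSet) -> tuple:
    """Exact alignment tables: contigs vs reference transcripts (cross)
    and contig self-hits for paralog pairs.  HSPs carry aligned strings,
    are full-length and gap-free; reverse-orientation contigs produce
    minus-strand HSPs."""
    cross: list[BlastHit] = []
    for gene in truth.genes:
        n = gene.length
        if gene.orientation == "+":
            s_start, s_end = 1, n
        else:
            s_start, s_end = n, 1
        transcript = truth.transcripts[gene.transcript_id]
        sseq = _revcomp(transcript) if gene.orientation == "-" else transcript
        matches = sum(1 for x, y in zip(gene.seq, sseq) if x == y)
        cross.append(BlastHit(gene.contig_id, gene.transcript_id, (Hsp(
            q_start=1, q_end=n, s_start=s_start, s_end=s_end,
            pct_identity=100.0 * matches / n, evalue=1e-180, bitscore=2.0 * n,
            qseq=gene.seq, sseq=sseq),)))

    by_contig = {g.contig_id: g for g in truth.genes}
    self_hits: list[BlastHit] = []
    for group in truth.paralog_groups:
        for qa in group:
            for qb in group:
                if qa == qb:
                    continue
                sa, sb = by_contig[qa].seq, by_contig[qb].seq
                n = min(len(sa), len(sb))
                matches = sum(1 for x, y in zip(sa[:n], sb[:n]) if x == y)
                self_hits.append(BlastHit(qa, qb, (Hsp(
                    q_start=1, q_end=n, s_start=1, s_end=n,
                    pct_identity=100.0 * matches / n,
                    evalue=1e-150, bitscore=1.5 * n,
                    qseq=sa[:n], sseq=sb[:n]),)))
    return self_hits, cross


def make_genotype_matrix(
    classes_per_snp: dict,
    n_progeny: int = 24,
    n_germplasm: int = 22,
    missing_rate: float = 0.02,
    seed: int = 0,
    duplicate_parents: tuple = ("AM20",),
    exact_ratios: bool = False,
):
    """Genotype matrix with known per-population classes.

    ``classes_per_snp`` maps SNP name to either one class string (applied
    to both populations) or a {population: class} dict; classes are
    failed, monomorphic, interspecific, paralog_suspect, testcross,
    intercross.  With ``exact_ratios`` progeny follow the idealized
    1:1 / 1:2:1 segregation deterministically instead of binomial /
    multinomial draws.  Returns (GenotypeMatrix, truth) where truth maps
    SNP -> population -> planted class.
    """
    import pandas as pd
    from .genoeval import GenotypeMatrix

    rng = op_rng(seed, "genotypes")
    populations = list(POPULATION_PARENTS)

    sample_rows = []
    for pop, (pa, pm) in POPULATION_PARENTS.items():
        for p in (pa, pm):
            sample_rows.append((p, "parent", pop, SPECIES_MAP[p], p))
            if p in duplicate_parents:
                sample_rows.append((f"{p}_rep2", "parent", pop, SPECIES_MAP[p], p))
        for j in range(n_progeny):
            sid = f"{pop}_p{j + 1:03d}"
            sample_rows.append((sid, "progeny", pop, "hybrid", sid))
    for sp, tag in (("AA", "AAg"), ("AM", "AMg")):
        for j in range(n_germplasm):
            sid = f"{tag}{j + 1:03d}"
            sample_rows.append((sid, "germplasm", "none", sp, sid))
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample", "role", "population", "species", "replicate_group"],
    ).set_index("sample")

    truth: dict[str, dict[str, str]] = {}
    columns: dict[str, list] = {}
    for snp, spec in classes_per_snp.items():
        per_pop = dict(spec) if isinstance(spec, dict) else {
            pop: spec for pop in populations}
        truth[snp] = per_pop
        calls = {}
        for pop in populations:
            cls = per_pop.get(pop, "monomorphic")
            pa, pm = POPULATION_PARENTS[pop]
            members = [s for s in samples.index
                       if samples.loc[s, "population"] == pop]
            if cls == "failed":
                for s in members:
                    calls[s] = "NC" if rng.random() < 0.75 else "AA"
                continue
            if cls == "monomorphic":
                parent_calls = {pa: "AA", pm: "AA"}
                draw = lambda: "AA"
            elif cls == "interspecific":
                parent_calls = {pa: "AA", pm: "BB"}
                draw = lambda: "AB"
            elif cls == "paralog_suspect":
                parent_calls = {pa: "AB", pm: "AB"}
                draw = lambda: "AB"
            elif cls == "testcross":
                parent_calls = {pa: "AB", pm: "AA"}
                if exact_ratios:
                    cycler = iter(("AB", "AA") * (n_progeny // 2 + 1))
                    draw = lambda: next(cycler)
                else:
                    draw = lambda: ("AB", "AA")[rng.integers(0, 2)]
            elif cls == "intercross":
                parent_calls = {pa: "AB", pm: "AB"}
                if exact_ratios:
                    cycler = iter(("AA", "AB", "AB", "BB") * (n_progeny // 4 + 1))
                    draw = lambda: next(cycler)
                else:
                    draw = lambda: ("AA", "AB", "AB", "BB")[rng.integers(0, 4)]
            else:
                raise ValueError(f"unknown planted class {cls!r} for {snp}")
            for s in members:
                role = samples.loc[s, "role"]
                if role == "parent":
                    calls[s] = parent_calls[samples.loc[s, "replicate_group"]]
                else:
                    c = draw()
                    if rng.random() < missing_rate:
                        c = "NC"
                    calls[s] = c
        # germplasm: species-fixed for interspecific, all-het for paralogs,
        # otherwise Hardy-Weinberg draws at a random allele frequency
        overall = next(iter(truth[snp].values()))
        for s in samples.index[samples["role"] == "germplasm"]:
            sp = samples.loc[s, "species"]
            if overall == "interspecific":
                calls[s] = "AA" if sp == "AA" else "BB"
            elif overall == "paralog_suspect":
                calls[s] = "AB"
            else:
                q = 0.05 + 0.45 * rng.random()
                u = rng.random()
                if u < (1 - q) ** 2:
                    calls[s] = "AA"
                elif u < (1 - q) ** 2 + 2 * q * (1 - q):
                    calls[s] = "AB"
                else:
                    calls[s] = "BB"
                if rng.random() < missing_rate:
                    calls[s] = "NC"
        columns[snp] = [calls[s] for s in samples.index]

    calls_df = pd.DataFrame(columns, index=samples.index)
    return GenotypeMatrix(calls=calls_df, samples=samples), truth


def write_fixture_dir(truth: TruthSet, outdir, depth_mean: float = 30.0,
                      error_rate: float = 0.005) -> dict:
    """Materialize a complete text fixture directory; returns a manifest
    of relative path -> description."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord
    from .pileup_io import write_pileup

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}

    def fasta(path, seqs):
        recs = [SeqRecord(Seq(s), id=i, description="") for i, s in sorted(seqs.items())]
        with open(outdir / path, "w") as fh:
            seqio_write(recs, fh, "fasta")
        manifest[path] = "FASTA"

    fasta("assembly_a.fasta", truth.assembly_a)
    fasta("assembly_b.fasta", truth.assembly_b)
    fasta("transcripts.fasta", truth.transcripts)

    (outdir / "coords.tsv").write_text("\n".join(truth.coords_rows) + "\n")
    manifest["coords.tsv"] = "assembly A vs B alignment table"

    with open(outdir / "gene_models.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        offset = 0
        for gene in truth.genes:
            chrom = "chr1"
            cursor = offset + 1
            for k, l in enumerate(gene.exon_lengths, start=1):
                fh.write("\t".join((
                    chrom, "synth", "exon", str(cursor), str(cursor + l - 1),
                    ".", "+", ".",
                    f"ID=exon:{gene.transcript_id}.{k};Parent={gene.transcript_id}",
                )) + "\n")
                cursor += l + 100     # fixed-size introns between exons
            offset = cursor + 400
    manifest["gene_models.gff3"] = "reference-species gene models"

    pileups = make_pileups(truth, depth_mean=depth_mean, error_rate=error_rate)
    for parent, records in pileups.items():
        path = f"{parent}.pileup"
        write_pileup(records, outdir / path)
        manifest[path] = f"consensus pileup for {parent}"

    self_hits, cross = make_blast_tables(truth)

    def blast_ext(path, hits):
        with open(outdir / path, "w") as fh:
            for hit in hits:
                for h in hit.hsps:
                    fh.write("\t".join(map(str, (
                        hit.query_id, hit.subject_id, h.q_start, h.q_end,
                        h.s_start, h.s_end, f"{h.pct_identity:.2f}",
                        h.evalue, h.bitscore, h.qseq, h.sseq))) + "\n")
        manifest[path] = "alignment hits with aligned strings"

    blast_ext("self_hits.tsv", self_hits)
    blast_ext("cross_hits.tsv", cross)

    truth_json = {
        "seed": truth.seed,
        "paralog_groups": [list(g) for g in truth.paralog_groups],
        "snps": [asdict(s) for s in truth.snps],
        "boundaries": {g.contig_id: list(g.true_boundaries())
                       for g in truth.genes},
        "orientation": {g.contig_id: g.orientation for g in truth.genes},
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1))
    manifest["truth.json"] = "planted ground truth"
    return manifest
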