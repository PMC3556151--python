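"""Exon-intron boundary projection and paralog detection via a related genome.

Markers discovered in transcriptome contigs are assayed on genomic DNA, so
an intron inside the oligo footprint breaks hybridization.  Lacking a
genome for the study species, exon-intron boundaries are projected from
gene models of a related reference species: each contig's best BLAST hit
against the reference transcripts carries the alignment through which the
transcript's exon junctions are mapped onto contig coordinates.  SNPs
within ``window`` bp of a projected junction are flagged.  Paralogous loci
(whose cross-hybridization corrupts genotype clusters) are flagged from
self-BLAST identity, shared best hits, and multi-transcript hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneModel",
    "Hsp",
    "BlastHit",
    "BoundaryAnnotation",
    "read_blast_tabular",
    "read_blast_extended",
    "read_gene_models_gff3",
    "best_hit",
    "transcript_boundaries",
    "project_boundaries",
    "flag_snps_near_boundary",
    "detect_paralogs",
    "filter3",
]

MAX_EVALUE = 1e-30


@dataclass(frozen=True)
class GeneModel:
    transcript_id: str
    exon_lengths: tuple     # ordered 5'->3' bp lengths

    def __post_init__(self):
        if not self.exon_lengths or any(l < 1 for l in self.exon_lengths):
            raise ValueError("exon lengths must be positive and non-empty")


@dataclass(frozen=True)
class Hsp:
    q_start: int
    q_end: int
    s_start: int            # s_start > s_end encodes minus strand
    s_end: int
    pct_identity: float
    evalue: float
    bitscore: float
    qseq: str | None = None     # aligned strings with '-' gaps, optional
    sseq: str | None = None

    @property
    def minus(self) -> bool:
        return self.s_start > self.s_end


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    hsps: tuple

    @property
    def min_evalue(self) -> float:
        return min(h.evalue for h in self.hsps)

    @property
    def max_bitscore(self) -> float:
        return max(h.bitscore for h in self.hsps)


@dataclass(frozen=True)
class BoundaryAnnotation:
    contig_id: str
    boundary_positions: tuple   # sorted unique contig coords (last exon base)
    provenance: tuple           # parallel (transcript_id, hsp index)


def _group_hits(rows) -> list[BlastHit]:
    grouped: dict[tuple[str, str], list[Hsp]] = {}
    order: list[tuple[str, str]] = []
    for qid, sid, hsp in rows:
        key = (qid, sid)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(hsp)
    return [BlastHit(q, s, tuple(grouped[(q, s)])) for q, s in order]


def read_blast_tabular(source) -> list[BlastHit]:
    """Read standard 12-column BLAST outfmt-6 (one HSP per row)."""
    import pandas as pd

    names = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
             "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(source, sep="\t", names=names, comment="#")
    rows = []
    for r in df.itertuples(index=False):
        rows.append((str(r.qseqid), str(r.sseqid), Hsp(
            q_start=int(r.qstart), q_end=int(r.qend),
            s_start=int(r.sstart), s_end=int(r.send),
            pct_identity=float(r.pident), evalue=float(r.evalue),
            bitscore=float(r.bitscore))))
    return _group_hits(rows)


def read_blast_extended(source) -> list[BlastHit]:
    """Read the extended format carrying aligned sequence strings.

    Columns: qseqid sseqid qstart qend sstart send pident evalue bitscore
    qseq sseq.
    """
    import pandas as pd

    names = ["qseqid", "sseqid", "qstart", "qend", "sstart", "send",
             "pident", "evalue", "bitscore", "qseq", "sseq"]
    df = pd.read_csv(source, sep="\t", names=names, comment="#")
    rows = []
    for r in df.itertuples(index=False):
        qseq, sseq = str(r.qseq), str(r.sseq)
        if len(qseq) != len(sseq):
            raise ValueError(
                f"aligned strings of unequal length for {r.qseqid}/{r.sseqid}")
        rows.append((str(r.qseqid), str(r.sseqid), Hsp(
            q_start=int(r.qstart), q_end=int(r.qend),
            s_start=int(r.sstart), s_end=int(r.send),
            pct_identity=float(r.pident), evalue=float(r.evalue),
            bitscore=float(r.bitscore), qseq=qseq, sseq=sseq)))
    return _group_hits(rows)


def read_gene_models_gff3(source) -> list[GeneModel]:
    """Collect exon features per transcript from a GFF3 file.

    Exon rows are grouped by their Parent attribute (falling back to ID),
    ordered along the transcript (reversed on the minus strand), and
    reduced to exon lengths.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    exons: dict[str, list[tuple[int, int]]] = {}
    strands: dict[str, str] = {}
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9 or parts[2].lower() != "exon":
            continue
        start, end, strand = int(parts[3]), int(parts[4]), parts[6]
        attrs = dict(
            kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
        )
        parent = attrs.get("Parent", attrs.get("ID"))
        if parent is None:
            raise ValueError(f"exon row without Parent/ID attribute: {line!r}")
        for tid in parent.split(","):
            exons.setdefault(tid, []).append((start, end))
            strands[tid] = strand
    models = []
    for tid in sorted(exons):
        spans = sorted(exons[tid])
        if strands[tid] == "-":
            spans = spans[::-1]
        models.append(GeneModel(
            transcript_id=tid,
            exon_lengths=tuple(e - s + 1 for s, e in spans)))
    return models


def best_hit(hits: Sequence[BlastHit], max_evalue: float = MAX_EVALUE) -> BlastHit | None:
    """Best hit for one contig: smallest E-value, then largest bitscore,
    then lexicographic subject id; None if no hit reaches ``max_evalue``."""
    eligible = [h for h in hits if h.min_evalue <= max_evalue]
    if not eligible:
        return None
    return min(eligible, key=lambda h: (h.min_evalue, -h.max_bitscore, h.subject_id))


def transcript_boundaries(gm: GeneModel) -> tuple:
    """Exon-junction coordinates on the transcript (last base of each exon,
    excluding the final exon)."""
    out, cum = [], 0
    for length in gm.exon_lengths[:-1]:
        cum += length
        out.append(cum)
    return tuple(out)


def _project_linear(hsp: Hsp, b: int) -> int | None:
    lo, hi = sorted((hsp.s_start, hsp.s_end))
    if not (lo <= b <= hi):
        return None
    if hsp.minus:
        return hsp.q_start + (hsp.s_start - b)
    return hsp.q_start + (b - hsp.s_start)


def _project_walk(hsp: Hsp, b: int) -> int | None:
    """Gap-aware projection: walk alignment columns until the subject
    cursor reaches ``b`` and report the query cursor there."""
    lo, hi = sorted((hsp.s_start, hsp.s_end))
    if not (lo <= b <= hi):
        return None
    step = -1 if hsp.minus else 1
    q_cur = hsp.q_start - 1
    s_cur = hsp.s_start - step
    for qc, sc in zip(hsp.qseq, hsp.sseq):
        if qc != "-":
            q_cur += 1
        if sc != "-":
            s_cur += step
            if s_cur == b:
                return q_cur if q_cur >= hsp.q_start else None
    return None


def project_boundaries(
    hit: BlastHit, tb: Sequence[int]
) -> BoundaryAnnotation:
    """Map transcript exon junctions onto contig coordinates through the
    hit's HSPs.  With aligned strings the projection is an exact column
    walk; without them a linear offset within the HSP is used (valid for
    ungapped alignments, approximate otherwise).  Junctions outside every
    HSP are not reported."""
    positions: list[int] = []
    provenance: list[tuple[str, int]] = []
    for idx, hsp in enumerate(hit.hsps):
        if hsp.qseq is not None and hsp.sseq is not None:
            if len(hsp.qseq) != len(hsp.sseq):
                raise ValueError("aligned strings of unequal length")
            project = _project_walk
        else:
            project = _project_linear
        for b in tb:
            q = project(hsp, b)
            if q is not None:
                positions.append(q)
                provenance.append((hit.subject_id, idx))
    order = sorted(range(len(positions)), key=lambda i: positions[i])
    uniq_pos, uniq_prov, seen = [], [], set()
    for i in order:
        if positions[i] not in seen:
            seen.add(positions[i])
            uniq_pos.append(positions[i])
            uniq_prov.append(provenance[i])
    return BoundaryAnnotation(
        contig_id=hit.query_id,
        boundary_positions=tuple(uniq_pos),
        provenance=tuple(uniq_prov),
    )


def flag_snps_near_boundary(
    snps: Iterable, ann: BoundaryAnnotation, window: int = 35
) -> list:
    """SNPs (objects with contig_id/pos) within ``window`` bp of any
    projected junction on the same contig (inclusive distance)."""
    flagged = []
    for snp in snps:
        if snp.contig_id != ann.contig_id:
            continue
        if any(abs(p - snp.pos) <= window for p in ann.boundary_positions):
            flagged.append(snp)
    return flagged


def detect_paralogs(
    self_hits: Sequence[BlastHit],
    cross_hits: Sequence[BlastHit],
    min_identity: float = 90.0,
    min_self_len: int = 100,
    max_evalue: float = MAX_EVALUE,
) -> dict[str, set]:
    """Flag contigs whose markers are unsafe due to gene duplication.

    Reasons per contig: ``self_similarity`` (an HSP to a different contig
    above ``min_identity`` percent over at least ``min_self_len`` bp;
    the length floor avoids flagging on trivial short repeats),
    ``shared_best_hit`` (two or more contigs best-hit the same reference
    transcript), ``multi_transcript`` (one contig hits two or more
    distinct reference transcripts at the E-value threshold).
    """
    flags: dict[str, set] = {}

    def add(cid: str, reason: str) -> None:
        flags.setdefault(cid, set()).add(reason)

    for hit in self_hits:
        if hit.query_id == hit.subject_id:
            continue
        for hsp in hit.hsps:
            aln_len = abs(hsp.q_end - hsp.q_start) + 1
            if (hsp.evalue <= max_evalue and hsp.pct_identity > min_identity
                    and aln_len >= min_self_len):
                add(hit.query_id, "self_similarity")
                add(hit.subject_id, "self_similarity")
                break

    by_query: dict[str, list[BlastHit]] = {}
    for hit in cross_hits:
        by_query.setdefault(hit.query_id, []).append(hit)
    best_by_subject: dict[str, list[str]] = {}
    for cid, hits in by_query.items():
        bh = best_hit(hits, max_evalue)
        if bh is not None:
            best_by_subject.setdefault(bh.subject_id, []).append(cid)
        subjects = {h.subject_id for h in hits if h.min_evalue <= max_evalue}
        if len(subjects) >= 2:
            add(cid, "multi_transcript")
    for sid, contigs in best_by_subject.items():
        if len(contigs) >= 2:
            for cid in contigs:
                add(cid, "shared_best_hit")
    return flags


def filter3(
    snps: Sequence,
    boundary_flagged: Iterable,
    paralog_flags: Mapping[str, set],
    score_cutoffs: Mapping[str, int],
) -> list:
    """Final stringency stage: drop boundary-flagged SNPs, every SNP on a
    paralog-flagged contig, and SNPs below the per-individual score cutoff."""
    from .snpfilter import score_cutoff

    flagged_keys = {(s.contig_id, s.pos) for s in boundary_flagged}
    survivors = [
        s for s in snps
        if (s.contig_id, s.pos) not in flagged_keys
        and s.contig_id not in paralog_flags
    ]
    return score_cutoff(survivors, score_cutoffs)
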