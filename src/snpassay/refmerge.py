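"""Build a non-redundant reference contig set from two de novo assemblies.

Two independent transcriptome assemblies of closely related parents are
reconciled into one reference: contig pairs that align over at least
``min_len`` bp at more than ``min_identity`` percent identity are treated
as the same transcript, and only the longer copy is kept.  Contigs with no
qualifying partner in the other assembly are excluded, so every reference
sequence is supported by both assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "ContigAlignment",
    "ReferenceSet",
    "read_coords_table",
    "select_orthologs",
    "write_reference_fasta",
]


@dataclass(frozen=True)
class ContigAlignment:
    query_id: str
    subject_id: str
    query_span: tuple[int, int]     # 1-based inclusive, normalized ascending
    subject_span: tuple[int, int]
    pct_identity: float
    aln_len: int
    reverse: bool = False


@dataclass
class ReferenceSet:
    contigs: dict           # id -> sequence
    provenance: dict        # id -> source assembly label


def read_coords_table(source) -> list[ContigAlignment]:
    """Read a nucmer show-coords style table.

    Expected columns per row: S1 E1 S2 E2 LEN1 LEN2 %IDY query subject.
    Subject spans given descending (E2 < S2) are normalized and flagged as
    reverse-strand.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    out: list[ContigAlignment] = []
    for idx, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 9:
            raise ValueError(f"coords row {idx}: expected 9 columns, got {len(parts)}")
        try:
            s1, e1, s2, e2 = (int(p) for p in parts[:4])
            len1 = int(parts[4])
            pid = float(parts[6])
        except ValueError:
            raise ValueError(f"coords row {idx}: non-numeric coordinate") from None
        reverse = e2 < s2
        out.append(ContigAlignment(
            query_id=parts[7], subject_id=parts[8],
            query_span=(min(s1, e1), max(s1, e1)),
            subject_span=(min(s2, e2), max(s2, e2)),
            pct_identity=pid, aln_len=len1, reverse=reverse,
        ))
    return out


def select_orthologs(
    alignments: Iterable[ContigAlignment],
    contigs_a: Mapping[str, str],
    contigs_b: Mapping[str, str],
    min_len: int = 200,
    min_identity: float = 90.0,
    label_a: str = "A",
    label_b: str = "B",
) -> ReferenceSet:
    """Keep the longer member of every qualifying orthologous contig pair.

    A pair qualifies if any single alignment block reaches ``min_len`` bp
    and exceeds ``min_identity`` percent identity.  A contig orthologous to
    several partners is resolved greedily by descending alignment length,
    so each contig participates in at most one kept pair.  Ties on contig
    length go to assembly A, then to the lexicographically smaller id.
    """
    qualifying: dict[tuple[str, str], int] = {}
    for aln in alignments:
        if aln.query_id not in contigs_a:
            raise KeyError(f"unknown assembly-A contig in alignment table: {aln.query_id}")
        if aln.subject_id not in contigs_b:
            raise KeyError(f"unknown assembly-B contig in alignment table: {aln.subject_id}")
        if aln.aln_len >= min_len and aln.pct_identity > min_identity:
            key = (aln.query_id, aln.subject_id)
            qualifying[key] = max(qualifying.get(key, 0), aln.aln_len)

    kept: dict[str, str] = {}
    prov: dict[str, str] = {}
    used_a: set[str] = set()
    used_b: set[str] = set()
    # greedy pairing by descending alignment length, deterministic tiebreak
    for (qa, qb), length in sorted(
        qualifying.items(), key=lambda kv: (-kv[1], kv[0])
    ):
        if qa in used_a or qb in used_b:
            continue
        used_a.add(qa)
        used_b.add(qb)
        seq_a, seq_b = contigs_a[qa], contigs_b[qb]
        if len(seq_a) > len(seq_b):
            winner, seq, label = qa, seq_a, label_a
        elif len(seq_b) > len(seq_a):
            winner, seq, label = qb, seq_b, label_b
        else:  # length tie: assembly A wins
            winner, seq, label = qa, seq_a, label_a
        kept[winner] = seq
        prov[winner] = label
    return ReferenceSet(contigs=kept, provenance=prov)


def write_reference_fasta(refset: ReferenceSet, sink) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=cid, description=f"source={refset.provenance[cid]}")
        for cid, seq in sorted(refset.contigs.items())
    ]
    seqio_write(records, sink, "fasta")
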