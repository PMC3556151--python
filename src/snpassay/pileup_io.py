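"""Consensus-pileup parsing, writing and per-site allele accounting.

The primary dialect is the 10-column "consensus" pileup emitted by early
samtools (``pileup -c``): chrom, position, reference base, consensus base,
consensus quality, SNP quality ("SNP score"), RMS mapping quality, depth,
read bases, base qualities.  A plain 6-column dialect (chrom, pos, ref,
depth, bases, quals) is also accepted with the consensus fields defaulted.

The read-base string uses the classic pileup grammar: ``.``/``,`` for a
match to the reference on the forward/reverse strand, ``ACGTN``/``acgtn``
for mismatches, ``*`` for a deletion placeholder, ``^X`` read-start (the
following character is the mapping quality and is not a base event),
``$`` read-end, and ``+n<seq>``/``-n<seq>`` for insertions/deletions
following the current base event.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from .iupac import BASES

__all__ = [
    "PileupRecord",
    "AlleleCounts",
    "PileupParseError",
    "PileupIntegrityError",
    "parse_pileup_line",
    "decode_read_bases",
    "count_alleles",
    "read_pileup",
    "write_pileup",
    "write_augmented_pileup",
]


class PileupParseError(ValueError):
    """Malformed pileup text; message carries the offending line number."""


class PileupIntegrityError(ValueError):
    """Decoded base events disagree with the declared depth."""


@dataclass(frozen=True)
class PileupRecord:
    contig_id: str
    pos: int                 # 1-based
    ref_base: str            # A/C/G/T/N
    consensus_base: str      # IUPAC symbol
    consensus_qual: int
    snp_qual: int            # phred-scaled SNP score
    rms_mapq: int
    depth: int
    read_bases: str
    base_quals: str


@dataclass(frozen=True)
class AlleleCounts:
    counts: dict              # base -> int over A,C,G,T
    deletions: int
    ref_allele: str
    major_allele: str | None
    minor_allele: str | None
    freq_ref: float
    freq_nonref: float
    freq_major: float
    freq_minor: float         # MAF

    @property
    def n_alleles_observed(self) -> int:
        return sum(1 for b in BASES if self.counts.get(b, 0) > 0)

    @property
    def denominator(self) -> int:
        return sum(self.counts.get(b, 0) for b in BASES)


def parse_pileup_line(line: str, lineno: int | None = None) -> PileupRecord:
    """Parse one pileup line (10-column consensus or 6-column plain)."""
    where = f" at line {lineno}" if lineno is not None else ""
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:  # tolerate space-separated text
        fields = line.split()
    if len(fields) == 10:
        (contig, pos, ref, cons, cq, sq, mq, depth, bases, quals) = fields
    elif len(fields) == 6:
        contig, pos, ref, depth, bases, quals = fields
        cons, cq, sq, mq = ref, "0", "0", "0"
    else:
        raise PileupParseError(
            f"expected 10 or 6 pileup columns, got {len(fields)}{where}"
        )
    try:
        pos_i, cq_i, sq_i, mq_i, depth_i = (
            int(pos), int(cq), int(sq), int(mq), int(depth)
        )
    except ValueError:
        raise PileupParseError(f"non-integer numeric field{where}") from None
    if pos_i < 1:
        raise PileupParseError(f"position must be >= 1, got {pos_i}{where}")
    if depth_i < 0 or sq_i < 0 or mq_i < 0:
        raise PileupParseError(f"negative quality or depth{where}")
    return PileupRecord(
        contig_id=contig, pos=pos_i, ref_base=ref.upper(),
        consensus_base=cons.upper(), consensus_qual=cq_i, snp_qual=sq_i,
        rms_mapq=mq_i, depth=depth_i, read_bases=bases, base_quals=quals,
    )


def decode_read_bases(encoded: str) -> tuple[list[str], list[tuple[str, str]]]:
    """Decode a read-base string into per-read base events and indel events.

    Returns ``(events, indels)`` where *events* holds one character per read
    covering the site (``.``/``,``/letters/``*``) and *indels* holds
    ``("+", seq)`` / ``("-", seq)`` tuples whose sequences never count as
    base events at this position.
    """
    events: list[str] = []
    indels: list[tuple[str, str]] = []
    i, n = 0, len(encoded)
    while i < n:
        c = encoded[i]
        if c == "^":        # read start; next char is encoded mapq
            i += 2
        elif c == "$":      # read end marker
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and encoded[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"indel without length near column {i}")
            length = int(encoded[i + 1:j])
            indels.append((c, encoded[j:j + length]))
            i = j + length
        else:
            events.append(c)
            i += 1
    return events, indels


def count_alleles(rec: PileupRecord) -> AlleleCounts:
    """Per-site allele account for a parsed record.

    ``.``/``,`` accrue to the reference base; mismatch letters are merged
    case-insensitively (strand is ignored); ``*`` counts as a deletion;
    inserted/deleted sequences are excluded.  Frequencies use the A+C+G+T
    substitution-allele denominator; a reference base of N yields
    freq_ref = 0 by definition.
    """
    events, _ = decode_read_bases(rec.read_bases)
    if len(events) != rec.depth:
        raise PileupIntegrityError(
            f"{rec.contig_id}:{rec.pos}: decoded {len(events)} base events "
            f"but depth column says {rec.depth}"
        )
    counts = {b: 0 for b in BASES}
    deletions = 0
    for ev in events:
        if ev in ".,":
            if rec.ref_base in counts:
                counts[rec.ref_base] += 1
        elif ev == "*":
            deletions += 1
        else:
            b = ev.upper()
            if b in counts:
                counts[b] += 1
            # N and reference-skip events carry no allele information
    denom = sum(counts.values())
    if denom == 0:
        return AlleleCounts(counts, deletions, rec.ref_base,
                            None, None, 0.0, 0.0, 0.0, 0.0)
    ranked = sorted(BASES, key=lambda b: (-counts[b], b))
    major = ranked[0]
    minor = ranked[1] if counts[ranked[1]] > 0 else None
    ref_count = counts.get(rec.ref_base, 0)
    freq_ref = ref_count / denom if rec.ref_base in counts else 0.0
    return AlleleCounts(
        counts=counts,
        deletions=deletions,
        ref_allele=rec.ref_base,
        major_allele=major,
        minor_allele=minor,
        freq_ref=freq_ref,
        freq_nonref=1.0 - freq_ref,
        freq_major=counts[major] / denom,
        freq_minor=(counts[minor] / denom) if minor else 0.0,
    )


def _open_text(path, mode: str = "rt") -> TextIO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_pileup(source) -> Iterator[PileupRecord]:
    """Yield records from a path (optionally .gz) or an open text handle."""
    if hasattr(source, "read"):
        handle, close = source, False
    else:
        handle, close = _open_text(source), True
    try:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                yield parse_pileup_line(line, lineno=lineno)
    finally:
        if close:
            handle.close()


def format_record(rec: PileupRecord) -> str:
    return "\t".join(
        (rec.contig_id, str(rec.pos), rec.ref_base, rec.consensus_base,
         str(rec.consensus_qual), str(rec.snp_qual), str(rec.rms_mapq),
         str(rec.depth), rec.read_bases, rec.base_quals)
    )


def write_pileup(records: Iterable[PileupRecord], sink) -> None:
    """Write 10-column pileup text; round-trips through parse_pileup_line."""
    if hasattr(sink, "write"):
        handle, close = sink, False
    else:
        handle, close = _open_text(sink, "wt"), True
    try:
        for rec in records:
            handle.write(format_record(rec) + "\n")
    finally:
        if close:
            handle.close()


def write_augmented_pileup(records: Iterable[PileupRecord], sink) -> None:
    """Pileup columns plus ref/non-ref/major/minor frequencies as a TSV."""
    if hasattr(sink, "write"):
        handle, close = sink, False
    else:
        handle, close = _open_text(sink, "wt"), True
    try:
        for rec in records:
            ac = count_alleles(rec)
            handle.write(
                format_record(rec)
                + "\t" + "\t".join(
                    f"{x:.6g}" for x in (ac.freq_ref, ac.freq_nonref,
                                         ac.freq_major, ac.freq_minor))
                + "\n"
            )
    finally:
        if close:
            handle.close()
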