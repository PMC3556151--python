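"""Flank extraction, ambiguity filtering and assay-submission output.

A fixed-array genotyping assay interrogates each SNP through oligos that
hybridize to its immediate flanks, so every submitted marker carries
exactly 50 bp upstream and 50 bp downstream of the target site taken from
the combined IUPAC-masked consensus.  SNPs closer than 50 bp to a contig
end are rejected, as are SNPs whose 100 flank bases carry more than
``max_ambiguous`` ambiguity symbols (secondary SNPs, interspecific fixed
differences or Ns), since ambiguous flank positions depress hybridization.
Returned design scores from the array vendor's design tool are consumed,
not computed: markers scoring below ``min_score`` are dropped.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from . import iupac
from .consensus import ConsensusTrack, classify_ambiguity

__all__ = [
    "FlankRecord",
    "FLANK_BP",
    "extract_flank",
    "annotate_ambiguities",
    "ambiguity_filter",
    "name_snp",
    "emit_design_csv",
    "parse_design_sequence",
    "read_score_table",
    "design_score_filter",
]

FLANK_BP = 50
DESIGN_COLUMNS = ["Locus_Name", "Sequence", "Target_Type", "Species", "Source"]

_BRACKET_RE = re.compile(r"^([A-Z]*)\[([A-Z])/([A-Z])\]([A-Z]*)$")


@dataclass(frozen=True)
class FlankRecord:
    snp_name: str
    contig_id: str
    pos: int
    allele_pair: tuple[str, str]     # (reference allele, alternate allele)
    upstream_seq: str                # exactly 50 characters
    downstream_seq: str              # exactly 50 characters
    n_secondary: int = 0
    n_interspecific: int = 0
    n_N: int = 0
    design_score: float | None = None

    @property
    def n_ambiguous(self) -> int:
        return self.n_secondary + self.n_interspecific + self.n_N


def name_snp(contig_id: str, pos: int) -> str:
    """Marker name: reference contig id, underscore, 1-based SNP position."""
    return f"{contig_id}_{pos}"


def extract_flank(
    combined: ConsensusTrack,
    contig_id: str,
    pos: int,
    allele_pair: tuple[str, str],
) -> FlankRecord | None:
    """Cut the 50+1+50 window centred on ``pos`` from the combined track.

    Returns None when fewer than 50 bp are available on either side or
    when the target alleles involve N (unassayable).
    """
    seq = combined.sequences[contig_id]
    if "N" in allele_pair:
        return None
    if pos - FLANK_BP < 1 or pos + FLANK_BP > len(seq):
        return None
    return FlankRecord(
        snp_name=name_snp(contig_id, pos),
        contig_id=contig_id,
        pos=pos,
        allele_pair=allele_pair,
        upstream_seq=seq[pos - 1 - FLANK_BP:pos - 1],
        downstream_seq=seq[pos:pos + FLANK_BP],
    )


def annotate_ambiguities(
    rec: FlankRecord,
    parent_tracks: Sequence[ConsensusTrack],
    species_map: Mapping[str, str],
) -> FlankRecord:
    """Count and classify the non-A/C/G/T symbols in the 100 flank bases."""
    counts = {"secondary": 0, "interspecific": 0, "N": 0}
    flank_positions = list(range(rec.pos - FLANK_BP, rec.pos)) + \
        list(range(rec.pos + 1, rec.pos + FLANK_BP + 1))
    flank_chars = rec.upstream_seq + rec.downstream_seq
    for p, ch in zip(flank_positions, flank_chars):
        if iupac.is_ambiguous(ch):
            kind = classify_ambiguity(rec.contig_id, p, parent_tracks, species_map)
            counts[kind] += 1
    return replace(rec, n_secondary=counts["secondary"],
                   n_interspecific=counts["interspecific"], n_N=counts["N"])


def ambiguity_filter(rec: FlankRecord, max_ambiguous: int = 4) -> bool:
    """Keep iff the flank carries at most ``max_ambiguous`` ambiguity codes."""
    return rec.n_ambiguous <= max_ambiguous


def design_sequence(rec: FlankRecord) -> str:
    ref, alt = rec.allele_pair
    return f"{rec.upstream_seq}[{ref}/{alt}]{rec.downstream_seq}"


def parse_design_sequence(s: str) -> tuple[str, tuple[str, str], str]:
    """Invert the bracket notation back to (upstream, alleles, downstream)."""
    m = _BRACKET_RE.match(s)
    if not m:
        raise ValueError(f"not a bracketed design sequence: {s!r}")
    up, ref, alt, down = m.groups()
    return up, (ref, alt), down


def emit_design_csv(
    records: Iterable[FlankRecord],
    sink,
    species: str = "hybrid",
    source: str = "transcriptome",
) -> None:
    """Write the assay-submission CSV (one row per kept marker)."""
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(DESIGN_COLUMNS)
    seen: set[str] = set()
    for rec in records:
        if rec.snp_name in seen:
            raise ValueError(f"duplicate marker name: {rec.snp_name}")
        seen.add(rec.snp_name)
        writer.writerow([rec.snp_name, design_sequence(rec), "SNP", species, source])


def read_score_table(source) -> dict[str, float]:
    """Read a Locus_Name / design_score TSV returned by the design tool."""
    import pandas as pd

    df = pd.read_csv(source, sep="\t")
    if not {"Locus_Name", "design_score"} <= set(df.columns):
        raise ValueError("score table needs Locus_Name and design_score columns")
    return dict(zip(df["Locus_Name"].astype(str), df["design_score"].astype(float)))


def design_score_filter(
    records: Sequence[FlankRecord],
    scores: Mapping[str, float],
    min_score: float = 0.4,
) -> list[FlankRecord]:
    """Keep markers whose returned design score is at least ``min_score``."""
    out = []
    for rec in records:
        if rec.snp_name not in scores:
            raise KeyError(f"no design score for marker {rec.snp_name}")
        if scores[rec.snp_name] >= min_score:
            out.append(replace(rec, design_score=scores[rec.snp_name]))
    return out
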