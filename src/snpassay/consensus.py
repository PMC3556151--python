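"""Per-parent and combined IUPAC-masked consensus tracks.

Each parent's consensus is rebuilt over the merged reference: uncovered
positions become N, filtered heterozygous SNPs become the two-base IUPAC
code of their alleles, positions where the reference allele is absent but
a single alternate is fixed are corrected to that alternate (this also
repairs assembly errors), and sites showing three or more alleles are
masked as N.  The four parent tracks are then pooled position-wise into a
combined track whose symbols encode the union of parental base sets; the
combined track is the substrate for flank extraction and the ambiguity
classification (secondary vs interspecific vs N) used by assay design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import iupac
from .pileup_io import PileupRecord, count_alleles
from .snpfilter import SnpCandidate

__all__ = [
    "ConsensusTrack",
    "build_parent_consensus",
    "combine_consensus",
    "classify_ambiguity",
    "write_consensus_fasta",
]


@dataclass
class ConsensusTrack:
    sequences: dict          # contig_id -> sequence string
    owner: str               # parent id or "combined"

    def symbol(self, contig_id: str, pos: int) -> str:
        return self.sequences[contig_id][pos - 1]


def build_parent_consensus(
    ref_contigs: Mapping[str, str],
    pileup_records: Iterable[PileupRecord],
    filtered_snps: Iterable[SnpCandidate],
    owner: str,
) -> ConsensusTrack:
    """Rebuild one parent's consensus over the reference contigs.

    Positions with no pileup evidence (no record, or zero A/C/G/T events)
    are N.  A position carried by ``filtered_snps`` becomes the IUPAC code
    of its allele pair.  Otherwise: three or more observed alleles mask to
    N; a site where the reference allele is absent and exactly one
    alternate is observed is replaced by that alternate; a site where the
    reference is absent but two alternates segregate (an unfiltered
    polymorphism with no reference support) is masked N; anything else
    keeps the reference base.
    """
    snp_at: dict[tuple[str, int], SnpCandidate] = {}
    for c in filtered_snps:
        snp_at[(c.contig_id, c.pos)] = c

    seqs = {cid: ["N"] * len(seq) for cid, seq in ref_contigs.items()}
    for rec in pileup_records:
        if rec.contig_id not in seqs:
            raise KeyError(f"pileup contig not in reference: {rec.contig_id}")
        if rec.pos > len(seqs[rec.contig_id]):
            raise IndexError(
                f"pileup position {rec.contig_id}:{rec.pos} beyond contig "
                f"length {len(seqs[rec.contig_id])}"
            )
        ac = count_alleles(rec)
        if ac.denominator == 0:
            symbol = "N"
        elif (rec.contig_id, rec.pos) in snp_at:
            c = snp_at[(rec.contig_id, rec.pos)]
            symbol = iupac.code_for({c.ref_allele, c.alt_allele})
        elif ac.n_alleles_observed >= 3:
            symbol = "N"
        elif ac.counts.get(rec.ref_base, 0) == 0:
            observed = [b for b in iupac.BASES if ac.counts[b] > 0]
            symbol = observed[0] if len(observed) == 1 else "N"
        else:
            symbol = rec.ref_base
        seqs[rec.contig_id][rec.pos - 1] = symbol
    return ConsensusTrack(
        sequences={cid: "".join(chars) for cid, chars in seqs.items()},
        owner=owner,
    )


def combine_consensus(tracks: Sequence[ConsensusTrack]) -> ConsensusTrack:
    """Pool parent tracks into one combined IUPAC-masked consensus.

    Per position the allele set is the union over parents of the base set
    implied by each parent's symbol (N contributes nothing).  A singleton
    union emits the base, two- or three-base unions emit the IUPAC code,
    and empty or four-base unions emit N.  The result is invariant under
    parent order.
    """
    if not tracks:
        raise ValueError("no parent tracks to combine")
    contig_ids = set(tracks[0].sequences)
    for t in tracks[1:]:
        if set(t.sequences) != contig_ids:
            raise ValueError("parent tracks cover different contig sets")
    combined: dict[str, str] = {}
    for cid in contig_ids:
        lengths = {len(t.sequences[cid]) for t in tracks}
        if len(lengths) != 1:
            raise ValueError(f"parent tracks disagree on length of {cid}")
        cols = zip(*(t.sequences[cid] for t in tracks))
        combined[cid] = "".join(
            iupac.code_for(frozenset().union(*(iupac.expand(s) for s in col)))
            for col in cols
        )
    return ConsensusTrack(sequences=combined, owner="combined")


def classify_ambiguity(
    contig_id: str,
    pos: int,
    parent_tracks: Sequence[ConsensusTrack],
    species_map: Mapping[str, str],
) -> str:
    """Classify a non-A/C/G/T combined symbol at one position.

    Returns ``"secondary"`` if any single parent is heterozygous there (a
    2- or 3-base IUPAC code in its own track), ``"interspecific"`` if each
    species' parents are fixed for a single base and the two species'
    bases differ, and ``"N"`` otherwise (uncovered or conflicting
    evidence).  ``species_map`` maps parent owner id to a species label.
    """
    symbols = {t.owner: t.symbol(contig_id, pos) for t in parent_tracks}
    for sym in symbols.values():
        if len(iupac.expand(sym)) >= 2:
            return "secondary"
    species_bases: dict[str, set[str]] = {}
    for owner, sym in symbols.items():
        sp = species_map[owner]
        species_bases.setdefault(sp, set()).update(iupac.expand(sym))
    fixed = {sp: next(iter(b)) for sp, b in species_bases.items() if len(b) == 1}
    if len(fixed) == len(species_bases) >= 2 and len(set(fixed.values())) >= 2:
        return "interspecific"
    return "N"


def write_consensus_fasta(track: ConsensusTrack, sink) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=cid, description=f"owner={track.owner}")
        for cid, seq in sorted(track.sequences.items())
    ]
    seqio_write(records, sink, "fasta")
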