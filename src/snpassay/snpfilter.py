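"""Staged candidate-SNP filtering and cross-individual bookkeeping.

Three stages are applied in sequence to per-individual candidate tables:

* the six-rule base filter (mapping and SNP quality above 20, depth of at
  least 10 reads, at least three non-reference alleles, exactly two
  observed alleles, MAF of at least 5%, major+minor allele frequency of at
  least 0.95);
* a stringency raise keeping SNP score >= 50 and MAF >= 8% (both bounds
  inclusive: the weakest independently validated site sits at score 52,
  MAF 8%);
* a per-individual SNP-score cutoff used when assembling large assay
  panels.

Every stage is a pure subset operation and reports per-rule rejection
counts, so threshold sweeps are monotone by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pileup_io import AlleleCounts, PileupRecord

__all__ = [
    "SnpCandidate",
    "FilterReport",
    "candidate_from_record",
    "base_filter",
    "filter1",
    "apply_stage",
    "score_cutoff",
    "dedupe_total",
    "snp_key",
    "read_candidates",
    "write_candidates",
]

CANDIDATE_COLUMNS = [
    "individual_id", "contig_id", "pos", "ref_allele", "alt_allele",
    "snp_score", "rms_mapq", "depth", "nonref_count", "maf",
    "freq_major_plus_minor", "n_alleles_observed",
]


@dataclass(frozen=True)
class SnpCandidate:
    individual_id: str
    contig_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    snp_score: int
    rms_mapq: int
    depth: int
    nonref_count: int
    maf: float
    freq_major_plus_minor: float
    n_alleles_observed: int


@dataclass
class FilterReport:
    stage: str
    n_in: int
    n_out: int
    rejections: dict    # rule name -> count; partitions n_in - n_out

    def as_row(self) -> dict:
        row = {"stage": self.stage, "input": self.n_in, "output": self.n_out}
        row.update(self.rejections)
        return row


def candidate_from_record(
    individual_id: str, rec: PileupRecord, counts: AlleleCounts
) -> SnpCandidate:
    """Assemble a candidate from a pileup record and its allele account.

    The alternate allele is the most frequent non-reference base (ties
    broken lexicographically); for sites where no non-reference base was
    observed it is recorded as the reference itself and the candidate can
    never pass the base filter.
    """
    nonref = {b: c for b, c in counts.counts.items() if b != rec.ref_base}
    alt = max(nonref, key=lambda b: (nonref[b], b), default=rec.ref_base)
    if nonref.get(alt, 0) == 0:
        alt = rec.ref_base
    return SnpCandidate(
        individual_id=individual_id,
        contig_id=rec.contig_id,
        pos=rec.pos,
        ref_allele=rec.ref_base,
        alt_allele=alt,
        snp_score=rec.snp_qual,
        rms_mapq=rec.rms_mapq,
        depth=rec.depth,
        nonref_count=sum(nonref.values()),
        maf=counts.freq_minor,
        freq_major_plus_minor=counts.freq_major + counts.freq_minor,
        n_alleles_observed=counts.n_alleles_observed,
    )


def base_filter(c: SnpCandidate) -> tuple[bool, list[str]]:
    """Six-rule base filter; returns (passed, failing rule names)."""
    failed = []
    if not (c.rms_mapq > 20 and c.snp_score > 20):
        failed.append("rule1_quality")
    if c.depth < 10:
        failed.append("rule2_depth")
    if c.nonref_count < 3:
        failed.append("rule3_nonref")
    if c.n_alleles_observed != 2:
        failed.append("rule4_biallelic")
    if c.maf < 0.05:
        failed.append("rule5_maf")
    if c.freq_major_plus_minor < 0.95:
        failed.append("rule6_major_minor")
    return (not failed, failed)


def filter1(c: SnpCandidate) -> bool:
    """Stringency raise after base filtering: score >= 50 and MAF >= 8%."""
    return c.snp_score >= 50 and c.maf >= 0.08


def apply_stage(
    candidates: Sequence[SnpCandidate], stage: str, **kwargs
) -> tuple[list[SnpCandidate], FilterReport]:
    """Run one named stage ('base', 'filter1' or 'score') with a report."""
    rejections: dict[str, int] = {}
    kept: list[SnpCandidate] = []
    if stage == "base":
        for c in candidates:
            ok, failed = base_filter(c)
            if ok:
                kept.append(c)
            else:
                # attribute the rejection to the first failing rule so the
                # counts partition the difference
                rejections[failed[0]] = rejections.get(failed[0], 0) + 1
    elif stage == "filter1":
        for c in candidates:
            if filter1(c):
                kept.append(c)
            else:
                rejections["score_or_maf"] = rejections.get("score_or_maf", 0) + 1
    elif stage == "score":
        kept = score_cutoff(candidates, kwargs["cutoff_per_individual"])
        rejections["below_cutoff"] = len(candidates) - len(kept)
    else:
        raise ValueError(f"unknown filter stage: {stage!r}")
    report = FilterReport(stage=stage, n_in=len(candidates),
                          n_out=len(kept), rejections=rejections)
    return kept, report


def score_cutoff(
    candidates: Sequence[SnpCandidate], cutoff_per_individual: Mapping[str, int]
) -> list[SnpCandidate]:
    """Keep candidates with snp_score >= the cutoff for their individual."""
    missing = {c.individual_id for c in candidates} - set(cutoff_per_individual)
    if missing:
        raise KeyError(f"no score cutoff for individual(s): {sorted(missing)}")
    return [c for c in candidates
            if c.snp_score >= cutoff_per_individual[c.individual_id]]


def snp_key(c: SnpCandidate) -> tuple[str, int, frozenset]:
    """Identity of a marker: contig, position and the unordered allele pair."""
    return (c.contig_id, c.pos, frozenset((c.ref_allele, c.alt_allele)))


def dedupe_total(sets_per_individual: Mapping[str, set]) -> tuple[int, set]:
    """Total unique SNPs = sum of per-individual counts minus the number of
    keys shared by at least two individuals.  Returns (total, shared keys).

    The formula equals the exact union cardinality whenever no key occurs
    in three or more individuals; the shared-key set is returned so callers
    can check that condition or report overlap directly.
    """
    from collections import Counter

    occurrence = Counter()
    for s in sets_per_individual.values():
        occurrence.update(s)
    shared = {k for k, n in occurrence.items() if n >= 2}
    total = sum(len(s) for s in sets_per_individual.values()) - len(shared)
    return total, shared


def write_candidates(candidates: Iterable[SnpCandidate], sink) -> None:
    df = pd.DataFrame([c.__dict__ for c in candidates], columns=CANDIDATE_COLUMNS)
    df.to_csv(sink, sep="\t", index=False)


def read_candidates(source) -> list[SnpCandidate]:
    df = pd.read_csv(source, sep="\t")
    missing = set(CANDIDATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(SnpCandidate(
            individual_id=str(d["individual_id"]),
            contig_id=str(d["contig_id"]),
            pos=int(d["pos"]),
            ref_allele=str(d["ref_allele"]),
            alt_allele=str(d["alt_allele"]),
            snp_score=int(d["snp_score"]),
            rms_mapq=int(d["rms_mapq"]),
            depth=int(d["depth"]),
            nonref_count=int(d["nonref_count"]),
            maf=float(d["maf"]),
            freq_major_plus_minor=float(d["freq_major_plus_minor"]),
            n_alleles_observed=int(d["n_alleles_observed"]),
        ))
    return out
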