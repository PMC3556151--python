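"""Genotype-matrix classification and assay statistics.

Calls come from a fixed-array genotyping run as AA/AB/BB/NC per sample and
SNP (NC = no call), with optional normalized signal intensity.  Within a
biparental F1 mapping population each SNP is classified from the parents'
calls and the progeny segregation:

* failed         — more than half the population uncalled, or median
                   intensity below 0.10;
* monomorphic    — parents share one homozygous genotype (or segregation
                   fails the Mendelian chi-square check);
* interspecific  — parents fixed for different alleles (AA x BB -> AB);
                   counted as monomorphic for conversion statistics but
                   reported separately (useful for hybrid discrimination);
* paralog_suspect — every called sample heterozygous, the signature of
                   co-amplifying duplicated loci;
* testcross      — one parent heterozygous, progeny segregating 1:1;
* intercross     — both parents heterozygous, progeny segregating 1:2:1.

From the classified set the module computes the assay success rate
(successful/total), conversion rate (polymorphic/total), validation rate
(polymorphic/successful), marker transferability between populations,
caller sensitivity / false-negative rate, germplasm polymorphism and MAF,
and replicate reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "SnpClass",
    "ClassificationError",
    "assay_failed",
    "classify_snp",
    "classify_population",
    "rates",
    "caller_comparison",
    "transferability",
    "germplasm_stats",
    "reproducibility",
    "cluster_profile_diff",
    "pct",
]

CALLS = ("AA", "AB", "BB", "NC")
POLYMORPHIC = ("testcross", "intercross")


class ClassificationError(ValueError):
    """A SNP cannot be classified (e.g. a parent call is missing)."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs call matrix with per-sample metadata.

    ``calls``: DataFrame indexed by sample id, columns = SNP names, values
    in {AA, AB, BB, NC}.  ``samples``: DataFrame indexed by sample id with
    columns role (parent/progeny/germplasm), population (WD/FL/none),
    species, replicate_group.  ``intensity``: optional DataFrame aligned
    with ``calls`` holding normalized signal intensities.
    """

    calls: pd.DataFrame
    samples: pd.DataFrame
    intensity: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.calls.index.equals(self.samples.index):
            raise ValueError("calls and sample metadata must share an index")
        bad = set(np.unique(self.calls.to_numpy())) - set(CALLS)
        if bad:
            raise ValueError(f"invalid genotype calls: {sorted(bad)}")

    @property
    def snps(self) -> list[str]:
        return list(self.calls.columns)

    def population_samples(self, population: str) -> pd.Index:
        mask = self.samples["population"] == population
        return self.samples.index[mask]

    def parents(self, population: str) -> pd.Index:
        mask = (self.samples["population"] == population) & \
            (self.samples["role"] == "parent")
        return self.samples.index[mask]

    def progeny(self, population: str) -> pd.Index:
        mask = (self.samples["population"] == population) & \
            (self.samples["role"] == "progeny")
        return self.samples.index[mask]

    def germplasm(self, species: str) -> pd.Index:
        mask = (self.samples["role"] == "germplasm") & \
            (self.samples["species"] == species)
        return self.samples.index[mask]

    def to_csv(self, sink) -> None:
        """Rows = SNPs, columns = samples, with four metadata header rows."""
        header = pd.DataFrame(
            {s: [self.samples.loc[s, c] for c in
                 ("role", "population", "species", "replicate_group")]
             for s in self.samples.index},
            index=["#role", "#population", "#species", "#replicate_group"],
        )
        body = self.calls.T
        body.index.name = "snp_name"
        out = pd.concat([header, body])
        out.to_csv(sink)

    @classmethod
    def from_csv(cls, source) -> "GenotypeMatrix":
        raw = pd.read_csv(source, index_col=0)
        meta_rows = ["#role", "#population", "#species", "#replicate_group"]
        missing = [r for r in meta_rows if r not in raw.index]
        if missing:
            raise ValueError(f"genotype CSV missing header rows: {missing}")
        samples = raw.loc[meta_rows].T
        samples.columns = [c.lstrip("#") for c in meta_rows]
        samples = samples.fillna("none")
        calls = raw.drop(index=meta_rows).T
        calls.index.name = None
        return cls(calls=calls, samples=samples)


@dataclass(frozen=True)
class SnpClass:
    snp_name: str
    population: str
    cls: str                      # failed/monomorphic/interspecific/
    #                               paralog_suspect/testcross/intercross
    p_value: float | None = None  # segregation GOF where applicable

    @property
    def polymorphic(self) -> bool:
        return self.cls in POLYMORPHIC

    @property
    def successful(self) -> bool:
        return self.cls != "failed"


def pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage with half-up rounding (presentation convention)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(str(100.0 * numerator / denominator))
    return float(q.quantize(Decimal(f"1.{'0' * decimals}") if decimals else
                            Decimal("1"), rounding=ROUND_HALF_UP))


def assay_failed(
    gm: GenotypeMatrix, snp: str, population: str
) -> bool:
    """Failed assay: more than half of one mapping population uncalled, or
    (when intensities are available) median intensity below 0.10."""
    members = gm.population_samples(population)
    if len(members) == 0:
        raise ValueError(f"population {population!r} has no samples")
    calls = gm.calls.loc[members, snp]
    if (calls == "NC").sum() > len(calls) / 2:
        return True
    if gm.intensity is not None:
        if float(gm.intensity.loc[members, snp].median()) < 0.10:
            return True
    return False


def _segregates(counts: Mapping[str, int], expected: Mapping[str, float],
                alpha: float) -> tuple[bool, float]:
    observed = np.array([counts.get(g, 0) for g in expected])
    if observed.sum() == 0:
        return False, 0.0
    exp = np.array(list(expected.values()), dtype=float)
    exp = exp / exp.sum() * observed.sum()
    chi2, p = stats.chisquare(observed, exp)
    return bool(p >= alpha), float(p)


def classify_snp(
    gm: GenotypeMatrix, snp: str, population: str, alpha: float = 0.05
) -> SnpClass:
    """Classify one SNP within one mapping population (see module doc)."""
    if assay_failed(gm, snp, population):
        return SnpClass(snp, population, "failed")
    parents = gm.parents(population)
    if len(parents) < 2:
        raise ClassificationError(
            f"population {population!r} needs two parents, found {len(parents)}")
    # collapse replicate parent samples to one call per parent line
    groups = gm.samples.loc[parents, "replicate_group"]
    parent_calls = []
    for grp in dict.fromkeys(groups):
        calls = set(gm.calls.loc[parents[groups == grp], snp]) - {"NC"}
        if not calls:
            raise ClassificationError(f"parent {grp} uncalled for {snp}")
        if len(calls) > 1:
            raise ClassificationError(
                f"parent {grp} replicates discordant for {snp}: {sorted(calls)}")
        parent_calls.append(calls.pop())
    if len(parent_calls) != 2:
        raise ClassificationError(
            f"population {population!r}: expected 2 parent lines, "
            f"found {len(parent_calls)}")
    p1, p2 = parent_calls
    prog = gm.calls.loc[gm.progeny(population), snp]
    prog = prog[prog != "NC"]
    counts = prog.value_counts().to_dict()

    all_calls = [p1, p2] + list(prog)
    if all_calls and all(c == "AB" for c in all_calls):
        return SnpClass(snp, population, "paralog_suspect")
    hom = {"AA", "BB"}
    if p1 in hom and p2 in hom:
        if p1 == p2:
            return SnpClass(snp, population, "monomorphic")
        return SnpClass(snp, population, "interspecific")
    if p1 == "AB" and p2 == "AB":
        ok, p = _segregates(counts, {"AA": 1, "AB": 2, "BB": 1}, alpha)
        if ok:
            return SnpClass(snp, population, "intercross", p_value=p)
        warnings.warn(
            f"{snp} ({population}): intercross parents but segregation "
            f"rejects 1:2:1 (p={p:.3g}); demoted to monomorphic")
        return SnpClass(snp, population, "monomorphic", p_value=p)
    # exactly one heterozygous parent: testcross against the hom genotype
    hom_call = p1 if p1 in hom else p2
    ok, p = _segregates(counts, {"AB": 1, hom_call: 1}, alpha)
    if ok:
        return SnpClass(snp, population, "testcross", p_value=p)
    warnings.warn(
        f"{snp} ({population}): testcross parents but segregation rejects "
        f"1:1 (p={p:.3g}); demoted to monomorphic")
    return SnpClass(snp, population, "monomorphic", p_value=p)


def classify_population(
    gm: GenotypeMatrix, population: str, alpha: float = 0.05
) -> list[SnpClass]:
    return [classify_snp(gm, snp, population, alpha=alpha) for snp in gm.snps]


def rates(classes: Sequence[SnpClass], n_total: int | None = None) -> dict:
    """Assay success, conversion and validation rates as percentages.

    success = successful/total; conversion = polymorphic/total;
    validation = polymorphic/successful.  Interspecific and
    paralog-suspect SNPs count as successful but not polymorphic.
    """
    if n_total is None:
        n_total = len(classes)
    if n_total == 0:
        raise ValueError("no assays to rate")
    n_success = sum(1 for c in classes if c.successful)
    n_poly = sum(1 for c in classes if c.polymorphic)
    return {
        "n_total": n_total,
        "n_successful": n_success,
        "n_polymorphic": n_poly,
        "success_rate": pct(n_success, n_total),
        "conversion_rate": pct(n_poly, n_total),
        "validation_rate": pct(n_poly, n_success) if n_success else 0.0,
    }


def caller_comparison(
    true_detected: int, total_detected: int, missed_true: int
) -> dict:
    """Cross-caller comparison for one individual.

    ``true_detected``: validated SNPs also found by the second caller;
    ``total_detected``: all panel SNPs the second caller found;
    ``missed_true``: validated SNPs the second caller missed.
    """
    if min(true_detected, total_detected, missed_true) < 0:
        raise ValueError("counts must be non-negative")
    n_true = true_detected + missed_true
    sens = pct(true_detected, n_true)
    return {
        "validation_rate_subset": pct(true_detected, total_detected),
        "sensitivity": sens,
        # defined as the complement, so the identity holds after rounding
        "false_negative_rate": round(100.0 - sens, 1),
    }


def transferability(poly_set_a: set, poly_set_b: set) -> float:
    """Share of markers polymorphic in A that are also polymorphic in B (%)."""
    if not poly_set_a:
        raise ValueError("source polymorphic set is empty")
    return pct(len(poly_set_a & poly_set_b), len(poly_set_a))


def germplasm_stats(calls: Iterable[str]) -> tuple[bool, float]:
    """Polymorphism flag and MAF for one SNP over germplasm samples.

    NC calls are ignored.  Polymorphic iff at least two distinct genotype
    classes are observed; MAF = minor-allele count / (2 x called samples).
    """
    called = [c for c in calls if c != "NC"]
    if not called:
        raise ValueError("no called germplasm samples")
    a = 2 * called.count("AA") + called.count("AB")
    b = 2 * called.count("BB") + called.count("AB")
    maf = min(a, b) / (a + b)
    return len(set(called)) >= 2, maf


def reproducibility(calls_rep1: Sequence[str], calls_rep2: Sequence[str]) -> float:
    """Concordance (%) between replicate call vectors, excluding any pair
    with an NC."""
    if len(calls_rep1) != len(calls_rep2):
        raise ValueError("replicate vectors differ in length")
    pairs = [(a, b) for a, b in zip(calls_rep1, calls_rep2)
             if a != "NC" and b != "NC"]
    if not pairs:
        raise ValueError("no comparable (both-called) pairs")
    concordant = sum(1 for a, b in pairs if a == b)
    return pct(concordant, len(pairs))


def cluster_profile_diff(
    classes_a: Mapping[str, str], classes_b: Mapping[str, str]
) -> set:
    """SNPs assessed in both populations whose class assignment differs."""
    shared = set(classes_a) & set(classes_b)
    return {s for s in shared if classes_a[s] != classes_b[s]}
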