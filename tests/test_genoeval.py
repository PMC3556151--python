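"""Genotype-matrix classification and assay statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snpassay import synthfix
from snpassay.genoeval import (
    ClassificationError, GenotypeMatrix, assay_failed, caller_comparison,
    classify_population, classify_snp, cluster_profile_diff, germplasm_stats,
    pct, rates, reproducibility, transferability,
)


def tiny_matrix(parent_calls, progeny_calls, population="WD"):
    """One-SNP matrix with the WD parents and given progeny calls."""
    pa, pm = synthfix.POPULATION_PARENTS[population]
    samples = [(pa, "parent"), (pm, "parent")] + [
        (f"{population}_p{i:03d}", "progeny") for i in range(len(progeny_calls))]
    meta = pd.DataFrame(
        [(sid, role, population, "x", sid) for sid, role in samples],
        columns=["sample", "role", "population", "species", "replicate_group"],
    ).set_index("sample")
    calls = pd.DataFrame(
        {"snp1": list(parent_calls) + list(progeny_calls)}, index=meta.index)
    return GenotypeMatrix(calls=calls, samples=meta)


class TestAssayFailed:
    def test_more_than_half_uncalled_fails(self):
        gm = tiny_matrix(("AA", "AA"), ["NC"] * 13 + ["AA"] * 9)   # 13/24 NC
        assert assay_failed(gm, "snp1", "WD")

    def test_exactly_half_does_not_fail(self):
        gm = tiny_matrix(("AA", "AA"), ["NC"] * 12 + ["AA"] * 10)  # 12/24
        assert not assay_failed(gm, "snp1", "WD")

    def test_low_median_intensity_fails(self):
        gm = tiny_matrix(("AA", "AA"), ["AA"] * 10)
        gm.intensity = pd.DataFrame(
            {"snp1": [0.05] * len(gm.calls)}, index=gm.calls.index)
        assert assay_failed(gm, "snp1", "WD")


class TestClassify:
    def test_interspecific(self):
        gm = tiny_matrix(("AA", "BB"), ["AB"] * 24)
        c = classify_snp(gm, "snp1", "WD")
        assert c.cls == "interspecific" and not c.polymorphic and c.successful

    def test_testcross_chi_square_oracle(self):
        # 11 AB vs 13 AA: chi2 = 2/12, p = 0.6831 by direct computation
        gm = tiny_matrix(("AB", "AA"), ["AB"] * 11 + ["AA"] * 13)
        c = classify_snp(gm, "snp1", "WD")
        expected_p = stats.chi2.sf((11 - 12) ** 2 / 12 + (13 - 12) ** 2 / 12, 1)
        assert c.cls == "testcross"
        assert c.p_value == pytest.approx(expected_p)
        assert c.p_value == pytest.approx(0.683, abs=5e-4)

    def test_all_heterozygous_is_paralog_suspect(self):
        gm = tiny_matrix(("AB", "AB"), ["AB"] * 24)
        assert classify_snp(gm, "snp1", "WD").cls == "paralog_suspect"

    def test_shared_homozygote_monomorphic(self):
        gm = tiny_matrix(("BB", "BB"), ["BB"] * 24)
        assert classify_snp(gm, "snp1", "WD").cls == "monomorphic"

    def test_intercross(self):
        gm = tiny_matrix(("AB", "AB"), ["AA"] * 6 + ["AB"] * 12 + ["BB"] * 6)
        c = classify_snp(gm, "snp1", "WD")
        assert c.cls == "intercross" and c.polymorphic

    def test_distorted_testcross_demoted(self):
        gm = tiny_matrix(("AB", "AA"), ["AB"] * 23 + ["AA"] * 1)
        with pytest.warns(UserWarning, match="demoted"):
            assert classify_snp(gm, "snp1", "WD").cls == "monomorphic"

    def test_missing_parent_call_raises(self):
        gm = tiny_matrix(("NC", "AA"), ["AA"] * 24)
        with pytest.raises(ClassificationError):
            classify_snp(gm, "snp1", "WD")

    def test_allele_relabeling_invariance(self):
        """Swapping A and B globally never changes the class."""
        swap = {"AA": "BB", "BB": "AA", "AB": "AB", "NC": "NC"}
        cases = [
            (("AA", "BB"), ["AB"] * 24),
            (("AB", "AA"), ["AB"] * 11 + ["AA"] * 13),
            (("AB", "AB"), ["AA"] * 6 + ["AB"] * 12 + ["BB"] * 6),
            (("AA", "AA"), ["AA"] * 24),
        ]
        for parents, progeny in cases:
            a = classify_snp(tiny_matrix(parents, progeny), "snp1", "WD")
            b = classify_snp(
                tiny_matrix(tuple(swap[p] for p in parents),
                            [swap[c] for c in progeny]), "snp1", "WD")
            assert a.cls == b.cls


class TestRates:
    def test_96_plex_printed_rates(self):
        from snpassay.genoeval import SnpClass
        classes = ([SnpClass(f"f{i}", "WD", "failed") for i in range(10)]
                   + [SnpClass(f"p{i}", "WD", "testcross") for i in range(36)]
                   + [SnpClass(f"m{i}", "WD", "monomorphic") for i in range(50)])
        r = rates(classes)
        assert r["success_rate"] == 89.6 and r["conversion_rate"] == 37.5

    def test_768_success(self):
        from snpassay.genoeval import SnpClass
        classes = ([SnpClass(f"f{i}", "WD", "failed") for i in range(58)]
                   + [SnpClass(f"s{i}", "WD", "monomorphic") for i in range(710)])
        assert rates(classes)["success_rate"] == 92.4

    def test_zero_polymorphic(self):
        from snpassay.genoeval import SnpClass
        classes = [SnpClass("a", "WD", "monomorphic")]
        r = rates(classes)
        assert r["conversion_rate"] == 0.0 and r["validation_rate"] == 0.0

    def test_conversion_identity(self):
        """conversion = validation x success at count level, for random
        classified sets."""
        from snpassay.genoeval import SnpClass
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(5, 400))
            kinds = rng.choice(
                ["failed", "monomorphic", "testcross", "intercross",
                 "interspecific", "paralog_suspect"], n)
            classes = [SnpClass(f"s{i}", "WD", k) for i, k in enumerate(kinds)]
            r = rates(classes)
            if r["n_successful"]:
                assert r["n_polymorphic"] / r["n_total"] == pytest.approx(
                    (r["n_polymorphic"] / r["n_successful"])
                    * (r["n_successful"] / r["n_total"]))


class TestCallerComparison:
    def test_published_am20_row(self):
        r = caller_comparison(true_detected=12, total_detected=17, missed_true=3)
        assert r["sensitivity"] == 80.0 and r["false_negative_rate"] == 20.0

    def test_published_aa6_subset_validation(self):
        r = caller_comparison(true_detected=14, total_detected=18, missed_true=5)
        assert r["validation_rate_subset"] == 77.8

    def test_nothing_missed(self):
        r = caller_comparison(5, 9, 0)
        assert r["sensitivity"] == 100.0 and r["false_negative_rate"] == 0.0

    def test_sensitivity_fnr_complement(self):
        for td, mt in [(12, 3), (5, 11), (1, 0)]:
            r = caller_comparison(td, td + mt, mt)
            assert r["sensitivity"] + r["false_negative_rate"] == pytest.approx(100.0)


class TestSetStatistics:
    def test_published_transferability(self):
        a = {f"s{i}" for i in range(426)}
        b = {f"s{i}" for i in range(140)} | {f"x{i}" for i in range(5)}
        assert transferability(a, b) == 32.9

    def test_superset_and_disjoint(self):
        a = {"x", "y"}
        assert transferability(a, a | {"z"}) == 100.0
        assert transferability(a, {"q"}) == 0.0

    def test_cluster_profile_diff(self):
        ca = {f"s{i}": "testcross" for i in range(130)}
        cb = dict(ca)
        for i in range(4):
            cb[f"s{i}"] = "intercross"
        diff = cluster_profile_diff(ca, cb)
        assert len(diff) == 4 and pct(len(diff), 130) == 3.1


class TestGermplasm:
    def test_polymorphic_with_maf(self):
        poly, maf = germplasm_stats(["AB"] * 3 + ["AA"] * 9)
        assert poly and maf == pytest.approx(3 / 24)

    def test_monomorphic(self):
        poly, maf = germplasm_stats(["AA"] * 8)
        assert not poly and maf == 0.0

    def test_nc_excluded_from_denominator(self):
        # direct allele tally: 20 A + 2 B over 11 called samples
        poly, maf = germplasm_stats(["AA"] * 10 + ["BB", "NC"])
        assert poly and maf == pytest.approx(2 / 22)


class TestReproducibility:
    def test_identical_with_missing_excluded(self):
        a = ["AA", "AB", "NC", "BB", "AA", "NC"]
        b = ["AA", "AB", "AA", "BB", "AA", "BB"]
        assert reproducibility(a, b) == 100.0

    def test_one_discordant_of_fifty(self):
        a = ["AA"] * 50
        b = ["AA"] * 49 + ["AB"]
        assert reproducibility(a, b) == 98.0


class TestSyntheticRecovery:
    def test_planted_classes_recovered(self):
        classes = {}
        rng_classes = ["testcross", "intercross", "interspecific",
                       "monomorphic", "paralog_suspect", "failed"]
        for i, cls in enumerate(rng_classes * 8):
            classes[f"s{i:03d}"] = cls
        gm, truth = synthfix.make_genotype_matrix(
            classes, n_progeny=180, missing_rate=0.0, seed=11)
        got = classify_population(gm, "WD")
        agreements = sum(1 for c in got if c.cls == truth[c.snp_name]["WD"])
        # chi-square at alpha=0.05 demotes ~5% of true segregants by design
        assert agreements >= 0.90 * len(got)

    def test_distorted_ratio_rejected_with_power(self):
        """A 3:1 ratio planted under a testcross configuration is demoted
        in more than 80% of simulations at n=180 progeny."""
        import warnings

        rng = np.random.default_rng(5)
        demoted = 0
        n_sim = 60
        for _ in range(n_sim):
            k = rng.binomial(180, 0.75)
            progeny = ["AB"] * k + ["AA"] * (180 - k)
            gm = tiny_matrix(("AB", "AA"), progeny)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c = classify_snp(gm, "snp1", "WD")
            if c.cls == "monomorphic":
                demoted += 1
        assert demoted / n_sim > 0.8


def test_matrix_csv_round_trip(tmp_path):
    gm, _ = synthfix.make_genotype_matrix(
        {"s1": "testcross", "s2": "interspecific"}, n_progeny=8,
        n_germplasm=4, seed=3)
    path = tmp_path / "m.csv"
    with open(path, "w") as fh:
        gm.to_csv(fh)
    with open(path) as fh:
        back = GenotypeMatrix.from_csv(fh)
    assert back.calls.equals(gm.calls)
    assert list(back.samples["role"]) == list(gm.samples["role"])
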