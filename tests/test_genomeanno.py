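"""Exon-intron boundary projection and paralog detection."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snpassay.genomeanno import (
    BlastHit, GeneModel, Hsp, best_hit, detect_paralogs, filter3,
    flag_snps_near_boundary, project_boundaries, read_blast_extended,
    read_blast_tabular, read_gene_models_gff3, transcript_boundaries,
)
from snpassay.snpfilter import SnpCandidate


def hit(q="c1", s="t1", evalue=1e-50, bitscore=400.0, **kw):
    defaults = dict(q_start=1, q_end=400, s_start=101, s_end=500,
                    pct_identity=98.0, evalue=evalue, bitscore=bitscore)
    defaults.update(kw)
    return BlastHit(q, s, (Hsp(**defaults),))


def snp(contig="c1", pos=100, score=250, individual="AA6"):
    return SnpCandidate(individual, contig, pos, "A", "G", score, 60, 30,
                        15, 0.5, 1.0, 2)


class TestBestHit:
    def test_smallest_evalue_wins(self):
        assert best_hit([hit(s="a", evalue=1e-40),
                         hit(s="b", evalue=1e-50)]).subject_id == "b"

    def test_bitscore_breaks_evalue_tie(self):
        assert best_hit([hit(s="a", bitscore=380.0),
                         hit(s="b", bitscore=400.0)]).subject_id == "b"

    def test_subject_id_breaks_full_tie(self):
        assert best_hit([hit(s="b"), hit(s="a")]).subject_id == "a"

    def test_no_hit_under_threshold(self):
        assert best_hit([hit(evalue=1e-20)]) is None


class TestTranscriptBoundaries:
    @pytest.mark.parametrize("lengths,expected", [
        ((100, 200, 50), (100, 300)),
        ((500,), ()),               # intronless
        ((1, 1), (1,)),
    ])
    def test_cumulative_sums_drop_last(self, lengths, expected):
        assert transcript_boundaries(GeneModel("t", lengths)) == expected


class TestProjection:
    def test_plus_strand_linear(self):
        ann = project_boundaries(hit(), (300,))
        assert ann.boundary_positions == (200,)

    def test_minus_strand_linear(self):
        h = hit(s_start=500, s_end=101)
        ann = project_boundaries(h, (300,))
        # oracle: reverse-complement the subject and recompute on plus gives
        # the same contig coordinate, 201
        assert ann.boundary_positions == (201,)

    def test_boundary_outside_hsp_not_reported(self):
        assert project_boundaries(hit(), (600,)).boundary_positions == ()

    def test_gapped_projection_shifts_by_insertion_length(self):
        # 3-bp query insertion before the boundary: q 1..13 vs s 1..10
        qseq = "AAAAA" + "GGG" + "CCCCC"
        sseq = "AAAAA" + "---" + "CCCCC"
        h = BlastHit("c", "t", (Hsp(1, 13, 1, 10, 90.0, 1e-60, 50.0,
                                    qseq=qseq, sseq=sseq),))
        linear = BlastHit("c", "t", (Hsp(1, 13, 1, 10, 90.0, 1e-60, 50.0),))
        b = (7,)
        gapped = project_boundaries(h, b).boundary_positions[0]
        ungapped = project_boundaries(linear, b).boundary_positions[0]
        assert gapped == ungapped + 3


def random_gapped_alignment(rng):
    """Random gapped HSP plus an independently built column map s->q."""
    n_cols = int(rng.integers(10, 60))
    q_start = int(rng.integers(1, 50))
    s_start = int(rng.integers(1, 50))
    minus = bool(rng.random() < 0.5)
    cols = []
    for _ in range(n_cols):
        r = rng.random()
        cols.append(("M" if r < 0.7 else "I" if r < 0.85 else "D"))
    # ensure aligned ends (no terminal gaps)
    cols[0] = cols[-1] = "M"
    qseq, sseq = [], []
    q_cur = q_start - 1
    step = -1 if minus else 1
    s_cur = s_start - step
    smap = {}
    for kind in cols:
        if kind == "M":
            q_cur += 1
            s_cur += step
            qseq.append("A")
            sseq.append("A")
            smap[s_cur] = q_cur
        elif kind == "I":        # query insertion
            q_cur += 1
            qseq.append("G")
            sseq.append("-")
        else:                    # query deletion (subject-only column)
            s_cur += step
            qseq.append("-")
            sseq.append("C")
            smap[s_cur] = q_cur  # convention: last consumed query base
    hsp = Hsp(q_start, q_cur, s_start, s_cur, 90.0, 1e-60, 99.0,
              qseq="".join(qseq), sseq="".join(sseq))
    return hsp, smap


def test_gap_aware_projection_matches_column_walk_oracle():
    rng = np.random.default_rng(42)
    checked = 0
    for _ in range(1200):
        hsp, smap = random_gapped_alignment(rng)
        h = BlastHit("c", "t", (hsp,))
        lo, hi = sorted((hsp.s_start, hsp.s_end))
        for b in smap:
            assert lo <= b <= hi
            got = project_boundaries(h, (b,)).boundary_positions
            expect = smap[b]
            if expect < hsp.q_start:   # boundary before any query base
                assert got == ()
            else:
                assert got == (expect,)
            checked += 1
    assert checked >= 1000


class TestFlagging:
    ann_positions = (100,)

    def ann(self):
        from snpassay.genomeanno import BoundaryAnnotation
        return BoundaryAnnotation("c1", self.ann_positions, (("t1", 0),))

    @pytest.mark.parametrize("pos,flagged", [
        (135, True),     # boundary at pos-35: inclusive
        (136, False),    # 36 bp away
        (100, True),     # boundary at the SNP itself
        (65, True), (64, False),
    ])
    def test_window_inclusive_and_symmetric(self, pos, flagged):
        got = flag_snps_near_boundary([snp(pos=pos)], self.ann())
        assert bool(got) is flagged

    def test_widening_window_is_monotone(self):
        snps = [snp(pos=p) for p in range(60, 140, 3)]
        sizes = [len(flag_snps_near_boundary(snps, self.ann(), window=w))
                 for w in range(0, 60, 5)]
        assert sizes == sorted(sizes)


class TestParalogs:
    def test_high_identity_pair_both_flagged(self):
        h = BlastHit("c1", "c2", (Hsp(1, 300, 1, 300, 92.0, 1e-60, 400.0),))
        flags = detect_paralogs([h], [])
        assert flags["c1"] == flags["c2"] == {"self_similarity"}

    def test_short_repeat_not_flagged(self):
        h = BlastHit("c1", "c2", (Hsp(1, 20, 1, 20, 95.0, 1e-40, 40.0),))
        assert detect_paralogs([h], []) == {}

    def test_shared_best_hit(self):
        flags = detect_paralogs([], [hit(q="c1", s="T"), hit(q="c2", s="T")])
        assert flags["c1"] == flags["c2"] == {"shared_best_hit"}

    def test_multi_transcript(self):
        flags = detect_paralogs([], [hit(q="c1", s="T1"), hit(q="c1", s="T2")])
        assert "multi_transcript" in flags["c1"]

    def test_identical_contigs_flagged_both_ways(self, truth, blast_tables):
        self_hits, cross = blast_tables
        flags = detect_paralogs(self_hits, cross)
        for group in truth.paralog_groups:
            for cid in group:
                assert "self_similarity" in flags[cid]
                assert "shared_best_hit" in flags[cid]


class TestFilter3:
    CUTOFFS = {"AA6": 100}

    def test_paralog_contig_removed_despite_score(self):
        out = filter3([snp(contig="p", score=250)], [], {"p": {"x"}}, self.CUTOFFS)
        assert out == []

    def test_unflagged_above_cutoff_retained(self):
        s = snp()
        assert filter3([s], [], {}, self.CUTOFFS) == [s]

    def test_boundary_flagged_removed(self):
        s = snp()
        assert filter3([s], [s], {}, self.CUTOFFS) == []


class TestReaders:
    def test_tabular_twelve_columns(self):
        text = "c1\tt1\t98.5\t400\t5\t1\t1\t400\t101\t500\t1e-50\t390\n"
        (h,) = read_blast_tabular(io.StringIO(text))
        hsp = h.hsps[0]
        assert (hsp.q_start, hsp.s_end) == (1, 500)
        assert hsp.evalue == pytest.approx(1e-50)

    def test_extended_with_strings(self):
        text = "c1\tt1\t1\t4\t1\t4\t100.0\t1e-60\t20\tACGT\tACGT\n"
        (h,) = read_blast_extended(io.StringIO(text))
        assert h.hsps[0].qseq == "ACGT"

    def test_gff3_exons_grouped_and_strand_aware(self):
        gff = (
            "##gff-version 3\n"
            "chr1\tx\texon\t1\t100\t.\t+\t.\tID=e1;Parent=tA\n"
            "chr1\tx\texon\t201\t400\t.\t+\t.\tID=e2;Parent=tA\n"
            "chr1\tx\texon\t500\t549\t.\t-\t.\tID=e3;Parent=tB\n"
            "chr1\tx\texon\t600\t699\t.\t-\t.\tID=e4;Parent=tB\n"
        )
        models = {m.transcript_id: m for m in read_gene_models_gff3(io.StringIO(gff))}
        assert models["tA"].exon_lengths == (100, 200)
        # minus strand: downstream-most genomic exon comes first
        assert models["tB"].exon_lengths == (100, 50)


def test_exact_boundary_recovery_on_synthetic_genes(truth, blast_tables):
    """Projected junctions equal the planted ones for every multi-exon
    gene, on both orientations."""
    _, cross = blast_tables
    by_query = {h.query_id: h for h in cross}
    models = {g.transcript_id: GeneModel(g.transcript_id, g.exon_lengths)
              for g in truth.genes}
    n_multi = 0
    for gene in truth.genes:
        h = by_query[gene.contig_id]
        tb = transcript_boundaries(models[gene.transcript_id])
        ann = project_boundaries(h, tb)
        assert ann.boundary_positions == gene.true_boundaries()
        if len(gene.exon_lengths) > 1:
            n_multi += 1
    assert n_multi >= 2      # both strands exercised by the fixture
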