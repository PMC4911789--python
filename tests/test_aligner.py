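import numpy as np
import pytest
from Bio import Align

from anikit.genome_io import CDSRecord, Genome, reverse_complement
from anikit.aligner import (
    AlignmentHit,
    ScoringScheme,
    align_cds,
    build_seed_index,
    hits_to_tabular,
    smith_waterman,
)
from tests.conftest import mutate, random_seq

SC = ScoringScheme()


def brute_force_best_score(a: str, b: str, sc: ScoringScheme = SC) -> int:
    """Exhaustively enumerate every local alignment path of a vs b.

    Exponential; only usable for very short strings. Gap of length L costs
    gap_open + L * gap_extend, matching the package's convention.
    """
    n, m = len(a), len(b)
    best = 0

    def extend(i, j, score, last):
        nonlocal best
        if score > best:
            best = score
        if i < n and j < m:
            s = sc.match_reward if a[i] == b[j] else sc.mismatch_penalty
            extend(i + 1, j + 1, score + s, "M")
        if i < n:
            cost = sc.gap_extend + (0 if last == "U" else sc.gap_open)
            extend(i + 1, j, score - cost, "U")
        if j < m:
            cost = sc.gap_extend + (0 if last == "L" else sc.gap_open)
            extend(i, j + 1, score - cost, "L")

    for i0 in range(n):
        for j0 in range(m):
            extend(i0, j0, 0, "M")
    return best


def biopython_local_score(a: str, b: str, sc: ScoringScheme = SC) -> float:
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=sc.match_reward,
        mismatch_score=sc.mismatch_penalty,
        open_gap_score=-(sc.gap_open + sc.gap_extend),
        extend_gap_score=-sc.gap_extend,
    )
    return aligner.score(a, b)


class TestSmithWaterman:
    def test_perfect_match_score(self):
        h = smith_waterman("ACGTACGT", "ACGTACGT")
        assert h.score == 16
        assert h.identity_pct == 100.0
        assert h.alignment_length == 8

    def test_all_mismatch_yields_empty_alignment(self):
        h = smith_waterman("AAAA", "TTTT")
        assert h.score == 0
        assert h.alignment_length == 0

    def test_repeat_pair_optimum(self):
        # ACGT occurs twice in each string; the best local alignment is the
        # ungapped TACGT run (5 matches, score 10), which beats bridging the
        # TT insertion with a gap (8 matches - gap cost 9 = 7).
        h = smith_waterman("ACGTTTACGT", "ACGTACGT")
        assert h.score == 10
        assert h.aligned_query == "TACGT"
        assert h.score == biopython_local_score("ACGTTTACGT", "ACGTACGT")

    @pytest.mark.parametrize(
        "a,b",
        [
            ("ACGT", "ACGT"),
            ("ACGTT", "ACG"),
            ("AACGT", "CGTAA"),
            ("ATATA", "TATAT"),
            ("GGCGC", "GCGCG"),
            ("ACGTA", "TGCAT"),
        ],
    )
    def test_matches_exhaustive_enumeration_on_tiny_pairs(self, a, b):
        assert smith_waterman(a, b).score == brute_force_best_score(a, b)

    def test_matches_independent_dp_up_to_60bp(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n, m = int(rng.integers(5, 61)), int(rng.integers(5, 61))
            a, b = random_seq(rng, n), random_seq(rng, m)
            assert smith_waterman(a, b).score == biopython_local_score(a, b)

    def test_related_pairs_match_independent_dp(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            a = random_seq(rng, int(rng.integers(30, 61)))
            b = mutate(rng, a, 0.1)
            assert smith_waterman(a, b).score == biopython_local_score(a, b)

    def test_score_recomputable_from_columns(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            a = random_seq(rng, 80)
            b = mutate(rng, a, 0.15)
            h = smith_waterman(a, b)
            assert h.recompute_score(SC) == h.score
            assert 0 <= h.identical_sites <= h.alignment_length

    def test_n_never_counts_as_identical(self):
        h = smith_waterman("ACGTNACGT" + "ACGTACGTACGT", "ACGTNACGT" + "ACGTACGTACGT")
        assert h.identical_sites < h.alignment_length or "N" not in h.aligned_query


class TestSeedIndex:
    def test_kmer_positions_by_inspection(self):
        g = Genome("t", (("c1", "ACGTACGT"),))
        idx = build_seed_index(g, 4)
        code = 0
        for c in "ACGT":
            code = code * 4 + "ACGT".index(c)
        assert list(idx.lookup(code)) == [0, 4]

    def test_all_n_target_gives_empty_index(self):
        g = Genome("t", (("c1", "N" * 50),))
        idx = build_seed_index(g, 4)
        assert idx._index == {}

    def test_absent_kmer_lookup_is_empty(self):
        g = Genome("t", (("c1", "AAAAAAAA"),))
        idx = build_seed_index(g, 4)
        assert len(idx.lookup(123)) == 0


def _cds_from(seq: str, cds_id="q") -> CDSRecord:
    return CDSRecord(cds_id, "qg", "qc", 0, len(seq), "+", seq)


class TestAlignCds:
    def test_exact_embedded_match(self):
        rng = np.random.default_rng(7)
        cds_seq = random_seq(rng, 600)
        target = random_seq(rng, 300) + cds_seq + random_seq(rng, 300)
        idx = build_seed_index(Genome("t", (("c1", target),)), SC.word_size)
        hits = align_cds(_cds_from(cds_seq), idx, SC)
        best = hits[0]
        assert best.identity_pct == 100.0
        assert best.alignment_length == 600
        assert best.identical_sites == 600
        assert best.target_span == (300, 900)
        assert best.target_strand == "+"

    def test_reverse_complement_match(self):
        rng = np.random.default_rng(9)
        cds_seq = random_seq(rng, 450)
        target = random_seq(rng, 100) + reverse_complement(cds_seq) + random_seq(rng, 100)
        idx = build_seed_index(Genome("t", (("c1", target),)), SC.word_size)
        hits = align_cds(_cds_from(cds_seq), idx, SC)
        assert hits[0].target_strand == "-"
        assert hits[0].identity_pct == 100.0

    def test_scattered_substitutions_match_oracle(self):
        rng = np.random.default_rng(11)
        cds_seq = random_seq(rng, 300)
        diverged = list(cds_seq)
        for pos in rng.choice(300, size=15, replace=False):
            diverged[pos] = "ACGT"[("ACGT".index(diverged[pos]) + 1) % 4]
        target = random_seq(rng, 200) + "".join(diverged) + random_seq(rng, 200)
        idx = build_seed_index(Genome("t", (("c1", target),)), SC.word_size)
        best = align_cds(_cds_from(cds_seq), idx, SC)[0]
        oracle = smith_waterman(cds_seq, target, SC)
        assert best.score == oracle.score
        assert best.identity_pct == pytest.approx(oracle.identity_pct)
        # the optimal local alignment trims score-losing terminal mismatches,
        # so 2 of the 15 substitutions (and 5 end bases) fall outside it:
        # 283/295 identical, verified against the exact-DP oracle above
        assert (best.identical_sites, best.alignment_length) == (
            oracle.identical_sites,
            oracle.alignment_length,
        ) == (283, 295)
        assert best.identity_pct == pytest.approx(95.93, abs=0.01)

    def test_unrelated_sequences_produce_no_keepable_hit(self):
        rng = np.random.default_rng(13)
        cds_seq = random_seq(rng, 300)
        target = random_seq(rng, 300)
        idx = build_seed_index(Genome("t", (("c1", target),)), SC.word_size)
        hits = align_cds(_cds_from(cds_seq), idx, SC)
        oracle = smith_waterman(cds_seq, target, SC)
        for h in hits + [oracle]:
            span = h.query_span[1] - h.query_span[0]
            assert not (h.identity_pct >= 60 and span > 0.7 * 300)

    def test_revcomp_target_flips_strand_only(self):
        rng = np.random.default_rng(15)
        cds_seq = random_seq(rng, 500)
        target = random_seq(rng, 150) + mutate(rng, cds_seq, 0.05) + random_seq(rng, 150)
        g = Genome("t", (("c1", target),))
        fwd = align_cds(_cds_from(cds_seq), build_seed_index(g, SC.word_size), SC)[0]
        rev = align_cds(
            _cds_from(cds_seq),
            build_seed_index(g.reverse_complemented(), SC.word_size),
            SC,
        )[0]
        assert fwd.target_strand != rev.target_strand
        assert fwd.identity_pct == pytest.approx(rev.identity_pct)
        assert fwd.identical_sites == rev.identical_sites
        assert fwd.alignment_length == rev.alignment_length

    def test_hits_disjoint_on_query_beyond_word_size(self):
        rng = np.random.default_rng(19)
        cds_seq = random_seq(rng, 600)
        # two separated copies in the target -> two hits allowed, but they
        # must not overlap on the query by more than word_size
        target = cds_seq + random_seq(rng, 500) + cds_seq
        idx = build_seed_index(Genome("t", (("c1", target),)), SC.word_size)
        hits = align_cds(_cds_from(cds_seq), idx, SC)
        for i, a in enumerate(hits):
            for b in hits[i + 1 :]:
                ov = min(a.query_span[1], b.query_span[1]) - max(
                    a.query_span[0], b.query_span[0]
                )
                assert ov <= SC.word_size

    def test_score_consistency_of_emitted_hits(self):
        rng = np.random.default_rng(21)
        cds_seq = random_seq(rng, 400)
        target = random_seq(rng, 100) + mutate(rng, cds_seq, 0.1) + random_seq(rng, 100)
        idx = build_seed_index(Genome("t", (("c1", target),)), SC.word_size)
        for h in align_cds(_cds_from(cds_seq), idx, SC):
            assert h.recompute_score(SC) == h.score


class TestHeuristicFidelity:
    def test_identity_within_one_point_of_oracle(self):
        """Planted-homology pairs: best heuristic hit tracks the exact DP."""
        rng = np.random.default_rng(37)
        for _ in range(60):
            n = int(rng.integers(300, 1501))
            q = random_seq(rng, n)
            t = random_seq(rng, 150) + mutate(rng, q, rng.uniform(0, 0.2)) + random_seq(rng, 150)
            idx = build_seed_index(Genome("t", (("c1", t),)), SC.word_size)
            hits = align_cds(_cds_from(q), idx, SC)
            oracle = smith_waterman(q, t, SC)
            assert hits, "heuristic missed a >=80%-identity homolog"
            best = hits[0]
            assert abs(best.identity_pct - oracle.identity_pct) <= 1.0
            ospan = oracle.query_span[1] - oracle.query_span[0]
            inter = min(best.query_span[1], oracle.query_span[1]) - max(
                best.query_span[0], oracle.query_span[0]
            )
            assert inter >= 0.95 * ospan


class TestTabularOutput:
    def test_outfmt6_like_row(self):
        rng = np.random.default_rng(25)
        cds_seq = random_seq(rng, 300)
        target = random_seq(rng, 50) + cds_seq + random_seq(rng, 50)
        idx = build_seed_index(Genome("t", (("c1", target),)), SC.word_size)
        hits = align_cds(_cds_from(cds_seq, "q1"), idx, SC)
        row = hits_to_tabular(hits).splitlines()[0].split("\t")
        assert row[0] == "q1" and row[1] == "c1"
        assert float(row[2]) == 100.0
        assert (int(row[6]), int(row[7])) == (1, 300)  # 1-based inclusive
        assert row[11] == "NA"
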