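"""bda_align: exact global alignment, similarity statistics, cluster MSA."""

import numpy as np
import pytest
from helpers import brute_force_alignment_score
from hypothesis import given, settings
from hypothesis import strategies as st

from bdakit.bda_align import (
    UnknownTokenError,
    align_cluster,
    align_pair,
    alignment_from_pairs,
    all_pairs,
    count_misaligned,
)
from bdakit.bgc_io import BDA
from bdakit.hmm_scoring import ScoringMatrix
from conftest import random_bda

TOKENS = st.sampled_from(
    ["Cond_LCL", "Cond_DCL", "AMP_binding", "PCP", "ACP", "PP_bind", "TE", "Itr_KS"]
)

# module-level matrix for the hypothesis tests (function-scoped fixtures and
# @given do not mix)
from bdakit.synthetic_fixtures import homology_matrix

BLOCK_MATRIX = homology_matrix()


class TestAlignPair:
    def test_worked_example_similarity(self, worked_example, toy_matrix):
        candidate, reference = worked_example
        aln = align_pair(candidate, reference, toy_matrix)
        assert (aln.M, aln.N) == (6, 7)
        assert aln.similarity == pytest.approx(6 / 7)
        assert aln.misaligned == 0
        assert aln.p_distance == pytest.approx(1 / 7)

    def test_identical_bdas(self, toy_matrix):
        b = BDA("x", ("Cond_LCL", "AMP_binding", "PCP", "Cond_DCL", "TE"))
        aln = align_pair(b, b, toy_matrix)
        assert (aln.M, aln.N, aln.similarity, aln.misaligned) == (5, 5, 1.0, 0)

    def test_disjoint_alphabets_all_gap(self, toy_matrix):
        a = BDA("a", ("Cond_LCL", "Cond_DCL"))
        b = BDA("b", ("TE", "TE", "TE"))
        aln = align_pair(a, b, toy_matrix)
        assert aln.score == 0.0
        assert (aln.M, aln.N, aln.similarity) == (0, 5, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_dp_score_equals_enumeration(self, seed, toy_matrix, fixture_vocabulary):
        rng = np.random.default_rng(seed)
        a = random_bda(rng, int(rng.integers(1, 5)), fixture_vocabulary, "a")
        b = random_bda(rng, int(rng.integers(1, 5)), fixture_vocabulary, "b")
        aln = align_pair(a, b, toy_matrix)
        expected = brute_force_alignment_score(a.tokens, b.tokens, toy_matrix.score)
        assert aln.score == pytest.approx(expected)

    def test_unknown_token_strict_names_token(self, toy_matrix):
        a = BDA("a", ("Cond_LCL", "mystery"))
        b = BDA("b", ("Cond_LCL",))
        with pytest.raises(UnknownTokenError, match="mystery"):
            align_pair(a, b, toy_matrix)

    def test_unknown_as_mismatch_scores_minus_one(self, toy_matrix):
        a = BDA("a", ("Cond_LCL", "mystery"))
        b = BDA("b", ("Cond_LCL",))
        aln = align_pair(a, b, toy_matrix, unknown="mismatch")
        assert aln.M == 1  # the mystery token is gapped, not misaligned
        assert aln.misaligned == 0


class TestMisalignment:
    @pytest.mark.parametrize("seed", range(20))
    def test_optimal_alignments_contain_no_negative_columns(
        self, seed, toy_matrix, fixture_vocabulary
    ):
        rng = np.random.default_rng(1000 + seed)
        a = random_bda(rng, int(rng.integers(1, 9)), fixture_vocabulary, "a")
        b = random_bda(rng, int(rng.integers(1, 9)), fixture_vocabulary, "b")
        aln = align_pair(a, b, toy_matrix)
        count, rate = count_misaligned(aln, toy_matrix)
        assert count == 0 and rate == 0.0

    def test_forced_pairing_counts_negative_columns(self, toy_matrix):
        a = BDA("a", ("Cond_LCL", "TE"))
        b = BDA("b", ("PCP", "TE"))
        forced = alignment_from_pairs(a, b, [(0, 0), (1, 1)], toy_matrix)
        count, rate = count_misaligned(forced, toy_matrix)
        assert count == 1
        assert rate == pytest.approx(0.5)

    def test_zero_match_rate_is_zero(self, toy_matrix):
        a = BDA("a", ("Cond_LCL",))
        b = BDA("b", ("TE",))
        aln = align_pair(a, b, toy_matrix)
        assert aln.M == 0
        assert count_misaligned(aln, toy_matrix) == (0, 0.0)


class TestAllPairs:
    def test_pair_counts(self, toy_matrix):
        bdas = [BDA(f"c{i}", ("Cond_LCL", "AMP_binding", "PCP")) for i in range(3)]
        assert len(all_pairs(bdas, toy_matrix)) == 3
        refs = [BDA(f"r{i}", ("Cond_LCL", "AMP_binding", "PCP")) for i in range(2)]
        assert len(all_pairs(bdas[:2], toy_matrix, refs)) == 1 + 4

    def test_similarities_invariant_under_reordering(self, toy_matrix, fixture_vocabulary):
        rng = np.random.default_rng(7)
        bdas = [random_bda(rng, 4, fixture_vocabulary, f"c{i}") for i in range(4)]
        t1 = all_pairs(bdas, toy_matrix)
        t2 = all_pairs(bdas[::-1], toy_matrix)
        sims1 = {frozenset((r.id_a, r.id_b)): r.similarity for r in t1.itertuples()}
        sims2 = {frozenset((r.id_a, r.id_b)): r.similarity for r in t2.itertuples()}
        assert sims1 == sims2


class TestProperties:
    @given(tokens=st.lists(TOKENS, min_size=1, max_size=8))
    @settings(max_examples=40, deadline=None)
    def test_self_similarity_is_one(self, tokens):
        b = BDA("x", tuple(tokens))
        assert align_pair(b, b, BLOCK_MATRIX).similarity == 1.0

    @given(
        ta=st.lists(TOKENS, min_size=1, max_size=6),
        tb=st.lists(TOKENS, min_size=1, max_size=6),
    )
    @settings(max_examples=40, deadline=None)
    def test_similarity_symmetric(self, ta, tb):
        a, b = BDA("a", tuple(ta)), BDA("b", tuple(tb))
        assert align_pair(a, b, BLOCK_MATRIX).similarity == pytest.approx(
            align_pair(b, a, BLOCK_MATRIX).similarity
        )

    @given(
        ta=st.lists(TOKENS, min_size=1, max_size=5),
        tb=st.lists(TOKENS, min_size=1, max_size=5),
        extra=TOKENS,
    )
    @settings(max_examples=40, deadline=None)
    def test_appending_shared_token_never_decreases_similarity(self, ta, tb, extra):
        before = align_pair(BDA("a", tuple(ta)), BDA("b", tuple(tb)), BLOCK_MATRIX)
        after = align_pair(
            BDA("a", tuple(ta) + (extra,)), BDA("b", tuple(tb) + (extra,)), BLOCK_MATRIX
        )
        assert after.similarity >= before.similarity - 1e-12

    def test_dp_beats_any_hand_alignment(self, toy_matrix, fixture_vocabulary):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = random_bda(rng, int(rng.integers(1, 7)), fixture_vocabulary, "a")
            b = random_bda(rng, int(rng.integers(1, 7)), fixture_vocabulary, "b")
            opt = align_pair(a, b, toy_matrix).score
            k = int(rng.integers(0, min(len(a), len(b)) + 1))
            ia = sorted(rng.choice(len(a.tokens), size=k, replace=False))
            ib = sorted(rng.choice(len(b.tokens), size=k, replace=False))
            hand = alignment_from_pairs(a, b, list(zip(ia, ib)), toy_matrix)
            assert opt >= hand.score - 1e-12


class TestClusterAlignment:
    def test_two_bdas_match_pairwise_layout(self, worked_example, toy_matrix):
        candidate, reference = worked_example
        msa = align_cluster([candidate, reference], toy_matrix)
        pair = align_pair(candidate, reference, toy_matrix)
        rows = pair.rows()
        assert msa[candidate.bgc_id] == rows[0]
        assert msa[reference.bgc_id] == rows[1]

    def test_identical_bdas_align_without_gaps(self, toy_matrix):
        bdas = [BDA(f"b{i}", ("Cond_LCL", "AMP_binding", "PCP")) for i in range(3)]
        msa = align_cluster(bdas, toy_matrix)
        assert all("-" not in row for row in msa.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_gap_strip_recovers_inputs(self, seed, toy_matrix, fixture_vocabulary):
        rng = np.random.default_rng(seed)
        bdas = [
            random_bda(rng, int(rng.integers(2, 7)), fixture_vocabulary, f"b{i}")
            for i in range(4)
        ]
        msa = align_cluster(bdas, toy_matrix)
        lengths = {len(row) for row in msa.values()}
        assert len(lengths) == 1
        for b in bdas:
            assert tuple(t for t in msa[b.bgc_id] if t != "-") == b.tokens
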