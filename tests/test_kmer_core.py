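import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rna_cosmos import (
    KmerCountVector,
    StructureArray,
    SynthConfig,
    cosine_similarity,
    count_vector,
    extract_kmers,
    length_penalty,
    pair_vocabulary,
    score_matrix,
    score_pair,
    weighted_score,
)
from rna_cosmos.annotate import annotate
from rna_cosmos.synthetic import random_structure

A = StructureArray("a", "LLLHHHRRR")
B = StructureArray("b", "LLLLHHHHRRRR")


def naive_score(codes_a, codes_b, k):
    """Independent reference: dictionary tally and explicit loops."""
    la = [codes_a[i : i + k] for i in range(len(codes_a) - k + 1)]
    lb = [codes_b[i : i + k] for i in range(len(codes_b) - k + 1)]
    vocab = []
    for w in la + lb:
        if w not in vocab:
            vocab.append(w)
    ca = {w: 0 for w in vocab}
    cb = {w: 0 for w in vocab}
    for w in la:
        ca[w] += 1
    for w in lb:
        cb[w] += 1
    dot = sum(ca[w] * cb[w] for w in vocab)
    na = math.sqrt(sum(c * c for c in ca.values()))
    nb = math.sqrt(sum(c * c for c in cb.values()))
    cos = dot / (na * nb)
    D = 2.0 * abs(len(codes_a) - len(codes_b)) / (len(codes_a) + len(codes_b))
    return cos, D, cos * (1.0 - D)


class TestExtraction:
    def test_sliding_windows(self):
        assert extract_kmers(A, 3) == ["LLL", "LLH", "LHH", "HHH", "HHR", "HRR", "RRR"]

    def test_repeated_window(self):
        assert extract_kmers(StructureArray("t", "LLLL"), 3) == ["LLL", "LLL"]

    def test_k_equals_length(self):
        assert extract_kmers(StructureArray("t", "HHH"), 3) == ["HHH"]

    def test_count_is_l_minus_k_plus_one(self):
        assert len(extract_kmers(A, 3)) == 9 - 3 + 1

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError, match="lower k or skip"):
            extract_kmers(A, 10)

    def test_vocabulary_first_appearance_order(self):
        assert pair_vocabulary(["LLL", "LLH"], ["LLH", "HHH"]) == ("LLL", "LLH", "HHH")

    def test_count_vector_tally(self):
        vocab = pair_vocabulary(extract_kmers(A, 3), extract_kmers(B, 3))
        va = count_vector(extract_kmers(A, 3), vocab)
        vb = count_vector(extract_kmers(B, 3), vocab)
        assert va.counts.tolist() == [1, 1, 1, 1, 1, 1, 1]
        assert vb.counts.tolist() == [2, 1, 1, 2, 1, 1, 2]

    def test_absent_kmer_counts_zero(self):
        v = count_vector(["LLL"], ("LLL", "HHH"))
        assert v.counts.tolist() == [1, 0]


class TestCosine:
    def test_self_similarity(self):
        v = count_vector(extract_kmers(A, 3), tuple(extract_kmers(A, 3)))
        assert cosine_similarity(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_is_zero(self):
        v1 = KmerCountVector(1, ("L", "H"), np.array([1.0, 0.0]))
        v2 = KmerCountVector(1, ("L", "H"), np.array([0.0, 1.0]))
        assert cosine_similarity(v1, v2) == 0.0

    def test_hand_worked_value(self):
        v1 = KmerCountVector(3, tuple("abcdefg"), np.ones(7))
        v2 = KmerCountVector(3, tuple("abcdefg"), np.array([2, 1, 1, 2, 1, 1, 2.0]))
        assert cosine_similarity(v1, v2) == pytest.approx(10 / (4 * math.sqrt(7)), abs=1e-9)

    def test_zero_norm_raises(self):
        v = KmerCountVector(1, ("L",), np.array([0.0]))
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_similarity(v, v)

    def test_mismatched_vocabulary_raises(self):
        v1 = KmerCountVector(1, ("L",), np.array([1.0]))
        v2 = KmerCountVector(1, ("H",), np.array([1.0]))
        with pytest.raises(ValueError):
            cosine_similarity(v1, v2)


class TestLengthWeighting:
    @pytest.mark.parametrize(
        "L1,L2,expected",
        [(100, 100, 0.0), (50, 150, 1.0), (9, 12, 6 / 21)],
    )
    def test_penalty_values(self, L1, L2, expected):
        assert length_penalty(L1, L2) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            length_penalty(0, 5)

    @pytest.mark.parametrize(
        "cos,L1,L2,expected",
        [(0.8, 200, 200, 0.8), (0.5, 90, 110, 0.4), (10 / (4 * math.sqrt(7)), 9, 12, 0.674936)],
    )
    def test_weighted_score(self, cos, L1, L2, expected):
        assert weighted_score(cos, L1, L2) == pytest.approx(expected, abs=1e-6)

    def test_negative_score_beyond_3to1_ratio(self):
        assert weighted_score(1.0, 10, 100) < 0

    @given(st.integers(1, 500), st.integers(1, 500))
    @settings(deadline=None, max_examples=100)
    def test_penalty_symmetric_and_bounded(self, L1, L2):
        d = length_penalty(L1, L2)
        assert d == length_penalty(L2, L1)
        assert 0.0 <= d < 2.0
        assert (d == 0.0) == (L1 == L2)


class TestScorePair:
    def test_worked_toy_pipeline(self):
        rec = score_pair(A, B, 3)
        assert rec.cosine == pytest.approx(0.944911, abs=1e-6)
        assert rec.penalty == pytest.approx(0.285714, abs=1e-6)
        assert rec.score == pytest.approx(0.674936, abs=1e-6)
        assert rec.score == pytest.approx(rec.cosine * (1 - rec.penalty), abs=1e-12)

    def test_identical_arrays(self):
        rec = score_pair(A, A, 4)
        assert rec.cosine == pytest.approx(1.0, abs=1e-12)
        assert rec.penalty == 0.0
        assert rec.score == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_vocabularies_score_zero(self):
        a = StructureArray("a", "H" * 12)
        b = StructureArray("b", "L" * 12)
        rec = score_pair(a, b, 10)
        assert rec.cosine == 0.0
        assert rec.score == 0.0

    def test_symmetry_exact(self):
        r1 = score_pair(A, B, 3)
        r2 = score_pair(B, A, 3)
        assert r1.cosine == r2.cosine
        assert r1.score == r2.score

    def test_no_length_weight_flag(self):
        rec = score_pair(A, B, 3, length_weight=False)
        assert rec.penalty == 0.0
        assert rec.score == rec.cosine

    def test_scale_invariance_of_cosine(self):
        vocab = pair_vocabulary(extract_kmers(A, 3), extract_kmers(B, 3))
        va = count_vector(extract_kmers(A, 3), vocab)
        vb = count_vector(extract_kmers(B, 3), vocab)
        scaled = KmerCountVector(3, vocab, va.counts * 7.5)
        assert cosine_similarity(va, vb) == pytest.approx(
            cosine_similarity(scaled, vb), abs=1e-12
        )

    def test_monotone_penalty_at_fixed_total_length(self):
        # fixed L1+L2 = 200, fixed cosine: S non-increasing in |L1-L2|
        scores = [weighted_score(0.9, 100 - d, 100 + d) for d in range(0, 100, 5)]
        assert all(s1 >= s2 for s1, s2 in zip(scores, scores[1:]))

    def test_counts_conservation(self):
        cfg = SynthConfig(seed=3)
        rng = np.random.default_rng(3)
        for i in range(20):
            arr = annotate(random_structure(cfg, rng, name=f"s{i}"))
            kmers = extract_kmers(arr, 10)
            v = count_vector(kmers, tuple(dict.fromkeys(kmers)))
            assert v.counts.sum() == len(arr) - 10 + 1


def test_oracle_equivalence_on_random_pairs():
    """score_pair matches a naive dictionary-and-loops reference to 1e-12
    on 100 random synthetic structure pairs."""
    cfg = SynthConfig(seed=5, base_length_range=(40, 100))
    rng = np.random.default_rng(5)
    arrays = [annotate(random_structure(cfg, rng, name=f"s{i}")) for i in range(40)]
    pairs = [(arrays[int(rng.integers(40))], arrays[int(rng.integers(40))]) for _ in range(100)]
    for a, b in pairs:
        k = int(rng.integers(3, 11))
        rec = score_pair(a, b, k)
        cos, D, S = naive_score(a.codes, b.codes, k)
        assert rec.cosine == pytest.approx(cos, abs=1e-12)
        assert rec.penalty == pytest.approx(D, abs=1e-12)
        assert rec.score == pytest.approx(S, abs=1e-12)


def test_score_matrix_skips_short_records():
    arrays = [A, B, StructureArray("short", "LHR")]
    with pytest.warns(UserWarning, match="short"):
        ids, mat, records = score_matrix(arrays, 5)
    assert ids == ["a", "b"]
    assert mat.shape == (2, 2)
    assert np.allclose(mat, mat.T)
    assert np.allclose(np.diag(mat), 1.0)
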