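"""The affine-gap alignment engine."""

import random

import pytest

from dnastore.align import OP_A, OP_B, OP_DIAG, Alignment, Scoring, aligned_strings, pairwise_align


def brute_force_affine(a: str, b: str, sc: Scoring) -> int:
    """Reference Gotoh score by plain dynamic programming."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [row[:] for row in H]
    F = [row[:] for row in H]
    H[0][0] = 0
    for i in range(1, n + 1):
        E[i][0] = sc.gap_open + sc.gap_extend * (i - 1)
        H[i][0] = E[i][0]
    for j in range(1, m + 1):
        F[0][j] = sc.gap_open + sc.gap_extend * (j - 1)
        H[0][j] = F[0][j]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            E[i][j] = max(H[i - 1][j] + sc.gap_open, E[i - 1][j] + sc.gap_extend)
            F[i][j] = max(H[i][j - 1] + sc.gap_open, F[i][j - 1] + sc.gap_extend)
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return H[n][m]


SC = Scoring(2, -4, -4, -2)


class TestGlobal:
    def test_matches_brute_force_on_random_pairs(self):
        rng = random.Random(0)
        for _ in range(150):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 14)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 14)))
            got = pairwise_align(a, b, SC, "global").score
            assert got == brute_force_affine(a, b, SC), (a, b)

    def test_ops_reconstruct_inputs(self):
        rng = random.Random(1)
        for _ in range(50):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 20)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 20)))
            ra, rb = aligned_strings(a, b, pairwise_align(a, b, SC).ops)
            assert ra.replace("-", "") == a
            assert rb.replace("-", "") == b

    def test_identical_sequences_all_diagonal(self):
        al = pairwise_align("ACGTACGT", "ACGTACGT", SC)
        assert all(op == OP_DIAG for op in al.ops)
        assert al.score == 16


class TestOverlap:
    def test_free_end_gaps_not_penalized(self):
        al = pairwise_align("CGT", "AACGTAA", SC, mode="overlap")
        assert al.score == 6  # three matches, flanks free

    def test_empty_sequence_handled(self):
        al = pairwise_align("", "ACGT", SC, mode="overlap")
        assert list(al.ops) == [OP_B] * 4


class TestBanded:
    def test_band_matches_full_on_similar_sequences(self):
        rng = random.Random(2)
        base = "".join(rng.choice("ACGT") for _ in range(600))
        mut = list(base)
        for p in rng.sample(range(600), 40):
            r = rng.random()
            if r < 0.4:
                mut[p] = ""
            elif r < 0.8:
                mut[p] = rng.choice("ACGT")
            else:
                mut[p] = mut[p] + rng.choice("ACGT")
        mut = "".join(mut)
        full = pairwise_align(base, mut, SC, "overlap").score
        banded = pairwise_align(base, mut, SC, "overlap", band=64).score
        assert banded == full

    def test_dissimilar_lengths_fall_back_to_full(self):
        # banding is meaningless when one sequence dwarfs the other
        al = pairwise_align("ACGT", "ACGT" * 30, SC, "overlap", band=8)
        assert isinstance(al, Alignment)
        assert al.score == 8


class TestScoringValidation:
    def test_bad_scoring_rejected(self):
        with pytest.raises(ValueError):
            Scoring(1, 2, -1, -1)  # mismatch >= match
        with pytest.raises(ValueError):
            Scoring(1, -1, 1, -1)  # positive gap penalty
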