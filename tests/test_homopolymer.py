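"""Run-length parsing and the homopolymer check code."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dnastore.homopolymer import (
    DecodingFailure,
    HomopolymerProfile,
    StructureError,
    compute_checks,
    correct_lengths,
    correct_lengths_with_total,
    parse_homopolymers,
    repair_run_structure,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestParsing:
    @pytest.mark.parametrize(
        "seq,symbols,lengths",
        [
            ("AATCCCGA", ("A", "T", "C", "G", "A"), (2, 1, 3, 1, 1)),
            ("ATCCGA", ("A", "T", "C", "G", "A"), (1, 1, 2, 1, 1)),
            ("G", ("G",), (1,)),
        ],
    )
    def test_examples(self, seq, symbols, lengths):
        prof = parse_homopolymers(seq)
        assert prof.symbols == symbols
        assert prof.lengths == lengths

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            parse_homopolymers("")

    @given(dna)
    def test_roundtrip(self, seq):
        assert parse_homopolymers(seq).expand() == seq


class TestChecks:
    def test_residues_are_lengths_mod_3(self):
        prof = parse_homopolymers("AATCCCGA")
        chk = compute_checks(prof, t=1)
        # the residue vector (2,1,0,1,1) determines the syndromes
        from dnastore.homopolymer import _syndromes

        assert chk.syndromes == _syndromes([2, 1, 0, 1, 1], 1)

    def test_checks_depend_on_lengths_only(self):
        a = HomopolymerProfile(("A", "T", "C"), (2, 3, 1))
        b = HomopolymerProfile(("G", "C", "A"), (2, 3, 1))
        assert compute_checks(a, t=2).syndromes == compute_checks(b, t=2).syndromes

    def test_all_ones_profile(self):
        prof = parse_homopolymers("ACGT")
        from dnastore.homopolymer import residues_of

        assert residues_of(prof) == (1, 1, 1, 1)

    def test_redundancy_size_small(self):
        # a kilobase block parses to < 1,000 runs; at t=3 the check is six
        # field symbols -- some 60 bits of classical-side redundancy
        prof = HomopolymerProfile(tuple("ACGT" * 200), tuple([1] * 800))
        chk = compute_checks(prof, t=3)
        assert len(chk.syndromes) == 6


class TestCorrection:
    def test_worked_example_two_deletions(self):
        original = parse_homopolymers("AATCCCGA")
        chk = compute_checks(original, t=2)
        observed = parse_homopolymers("ATCCGA")
        assert sum(
            a != b for a, b in zip(observed.lengths, original.lengths)
        ) == 2
        fixed = correct_lengths(observed, chk)
        assert fixed.lengths == (2, 1, 3, 1, 1)
        assert fixed.expand() == "AATCCCGA"

    def test_zero_syndrome_is_identity(self):
        prof = parse_homopolymers("AATCCCGGTA")
        chk = compute_checks(prof, t=3)
        assert correct_lengths(prof, chk) == prof

    def test_exhaustive_toy_profile(self):
        """Every <=t pattern of magnitude-1/2 shortenings is repaired exactly."""
        original = HomopolymerProfile(
            tuple("ATCGATCGAT"), (3, 4, 5, 3, 4, 5, 3, 4, 5, 3)
        )
        t = 3
        chk = compute_checks(original, t=t)
        n = original.run_count
        for weight in range(1, t + 1):
            for positions in itertools.combinations(range(n), weight):
                for mags in itertools.product((1, 2), repeat=weight):
                    lengths = list(original.lengths)
                    for p, m in zip(positions, mags):
                        lengths[p] -= m
                    observed = HomopolymerProfile(
                        original.symbols, tuple(lengths)
                    )
                    fixed = correct_lengths(observed, chk)
                    assert fixed == original

    def test_corrections_never_shorten(self):
        original = HomopolymerProfile(tuple("ATCGA"), (4, 4, 4, 4, 4))
        chk = compute_checks(original, t=2)
        observed = HomopolymerProfile(tuple("ATCGA"), (2, 4, 3, 4, 4))
        fixed = correct_lengths(observed, chk)
        assert all(f >= o for f, o in zip(fixed.lengths, observed.lengths))

    def test_run_count_mismatch_raises(self):
        original = parse_homopolymers("AATCCCGA")  # five runs
        chk = compute_checks(original, t=2)
        with pytest.raises(StructureError):
            correct_lengths(parse_homopolymers("ATCA"), chk)  # four runs

    def test_too_many_errors_fail_loudly(self):
        original = HomopolymerProfile(tuple("ATCGATCGAT"), (4,) * 10)
        chk = compute_checks(original, t=1)
        observed = HomopolymerProfile(tuple("ATCGATCGAT"), (3, 3, 3) + (4,) * 7)
        with pytest.raises(DecodingFailure):
            correct_lengths(observed, chk)


class TestSideInformationRepair:
    def test_mixed_sign_with_total_length(self):
        # a transposed base: one run short by one, another long by one
        original = parse_homopolymers("AAATCCGGGT")
        chk = compute_checks(original, t=3)
        observed = parse_homopolymers("AATCCGGGGT")
        fixed = correct_lengths_with_total(observed, chk, len("AAATCCGGGT"))
        assert fixed.expand() == "AAATCCGGGT"

    def test_structural_repair_reinserts_lost_run(self):
        # the syndromes constrain lengths only, so symbol placement is
        # resolved by ranking candidates against a witness read, exactly
        # as the decoder ranks by read support
        import edlib

        original = parse_homopolymers("AAATCGCCTA")
        chk = compute_checks(original, t=3)
        # the lone G vanished; its different-base neighbours stay split
        observed = parse_homopolymers("AAATCCCTA")

        def rank(cands):
            return min(
                cands,
                key=lambda c: edlib.align(
                    c.expand(), "AAATCGCCTA", mode="NW"
                )["editDistance"],
            )

        fixed = repair_run_structure(
            observed, chk, len("AAATCGCCTA"), rank=rank
        )
        assert fixed.expand() == "AAATCGCCTA"

    def test_structural_repair_removes_spurious_run(self):
        original = parse_homopolymers("AAATCCCCTA")
        chk = compute_checks(original, t=3)
        observed = parse_homopolymers("AAATCCGCCTA")  # spurious G splits the Cs
        fixed = repair_run_structure(observed, chk, len("AAATCCCCTA"))
        assert fixed.expand() == "AAATCCCCTA"
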