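"""Consensus reconstruction: demultiplexing, MSA, aggregation, polishing."""

import edlib
import numpy as np
import pytest

from dnastore._seq import revcomp
from dnastore.addresses import generate_addresses
from dnastore.channel import ChannelParams, Read, sample_pool
from dnastore.consensus import (
    DEFAULT_PRESETS,
    MsaPreset,
    aggregate_majority_homopolymer,
    demultiplex,
    iterative_polish,
    msa_consensus,
    pin_address,
)


def _dist(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW")["editDistance"]


QUIET = ChannelParams(p_reverse=0.0)


class TestDemultiplex:
    def test_exact_match_assigned(self):
        addrs = generate_addresses(3)
        read = Read("TTT" + addrs[2].bases + "GGGACGT", "r0")
        assigned, leftovers = demultiplex([read], addrs)
        assert [r.id for r in assigned[2]] == ["r0"]
        assert leftovers == []

    def test_reverse_strand_canonicalized(self):
        addrs = generate_addresses(3)
        fwd = "TTT" + addrs[1].bases + "GGGACGT"
        read = Read(revcomp(fwd), "r0")
        assigned, _ = demultiplex([read], addrs)
        assert assigned[1][0].bases == fwd

    def test_one_substitution_unassigned(self):
        addrs = generate_addresses(1)
        bases = addrs[0].bases
        mutated = ("A" if bases[7] != "A" else "C").join(
            [bases[:7], bases[8:]]
        )
        read = Read("TT" + mutated + "GG", "r0")
        assigned, leftovers = demultiplex([read], addrs)
        assert assigned[0] == [] and len(leftovers) == 1

    def test_simulated_pool_assignments_correct(self, encoded_3633):
        blocks, _ = encoded_3633
        truth = [b.sequence for b in blocks]
        pool = sample_pool(truth, 10, ChannelParams(), seed=21)
        addrs = [b.address for b in blocks]
        assigned, leftovers = demultiplex(pool, addrs)
        n_assigned = sum(len(v) for v in assigned.values())
        assert 0 < n_assigned < len(pool)
        for idx, reads in assigned.items():
            assert all(r.source_block == idx for r in reads)


class TestMsaConsensus:
    def test_identical_reads_returned_verbatim(self, random_block):
        reads = [Read(random_block, f"r{i}") for i in range(5)]
        for preset in DEFAULT_PRESETS:
            assert msa_consensus(reads, preset) == random_block

    def test_empty_read_set_rejected(self):
        with pytest.raises(ValueError):
            msa_consensus([], DEFAULT_PRESETS[0])

    def test_noisy_consensus_beats_mean_read(self, random_block):
        pool = sample_pool([random_block], 15, QUIET, seed=3)
        mean_read = np.mean([_dist(r.bases, random_block) for r in pool])
        for preset in DEFAULT_PRESETS:
            cons = msa_consensus(pool, preset)
            assert _dist(cons, random_block) < mean_read

    def test_invalid_preset_rejected(self):
        with pytest.raises(ValueError):
            MsaPreset("bad", 1, 2, -1, -1)


class TestAggregation:
    def test_majority_homopolymer_worked_example(self):
        got = aggregate_majority_homopolymer(["AAATTGCC", "AATTTGCA", "AAATTGC"])
        assert got == "AAATTGCA"

    def test_minority_run_retained(self):
        # the trailing A appears in one input only, yet is kept
        got = aggregate_majority_homopolymer(["AAATTGCC", "AATTTGCA", "AAATTGC"])
        assert got.endswith("A")

    def test_identical_inputs(self):
        assert aggregate_majority_homopolymer(["ACGT"] * 4 ) == "ACGT"

    def test_mode_of_first_run(self):
        assert aggregate_majority_homopolymer(["AAT", "AAT", "AT"]) == "AAT"

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            aggregate_majority_homopolymer(["ACGT"])


class TestIterativePolish:
    def test_fixed_point_on_truth(self, random_block):
        reads = [Read(random_block, f"r{i}") for i in range(30)]
        pol = iterative_polish(random_block, reads, address_len=16)
        assert pol.bases == random_block
        assert pol.iteration == 1
        assert pol.flags == []

    def test_shortened_run_restored(self, random_block):
        reads = [Read(random_block, f"r{i}") for i in range(30)]
        est = random_block[:500] + random_block[501:]
        pol = iterative_polish(est, reads, address_len=16)
        assert pol.bases == random_block

    def test_noisy_polish_reduces_error_and_restores_balance(self, random_block):
        from dnastore.balanced import check_balance

        pool = sample_pool([random_block], 40, QUIET, seed=8)
        est = random_block[:300] + random_block[302:]  # 2 missing bases
        pre = _dist(est, random_block)
        pol = iterative_polish(est, pool, address_len=16)
        assert _dist(pol.bases, random_block) <= pre
        assert len(check_balance(pol.bases)) <= len(check_balance(est))

    def test_no_reads_rejected(self, random_block):
        with pytest.raises(ValueError):
            iterative_polish(random_block, [], address_len=16)


class TestPinAddress:
    def test_exact_prefix_untouched(self):
        addr = generate_addresses(1)[0].bases
        cons = addr + "ACGTACGT"
        assert pin_address(cons, addr) == cons

    def test_corrupt_address_region_replaced(self):
        addr = generate_addresses(1)[0].bases
        corrupt = "T" + addr[2:]  # one deletion + one substitution
        got = pin_address(corrupt + "ACGTACGT", addr)
        assert got.startswith(addr)
        assert got.endswith("ACGTACGT")


class TestCoverageMonotonicity:
    def test_mean_consensus_error_non_increasing_in_coverage(self, random_block):
        """More reads never hurt, on average, over >= 20 seeds."""
        preset = DEFAULT_PRESETS[0]
        errs = {10: [], 50: []}
        for seed in range(20):
            for cov in (10, 50):
                pool = sample_pool([random_block], cov, QUIET, seed=100 + seed)
                cons = msa_consensus(pool, preset)
                errs[cov].append(_dist(cons, random_block))
        assert np.mean(errs[50]) <= np.mean(errs[10])
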