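"""The nanopore-like error channel."""

import numpy as np
import pytest

from dnastore._seq import revcomp, to_codes
from dnastore.channel import (
    ChannelParams,
    Read,
    _run_lengths_per_position,
    corrupt_read,
    empirical_error_rates,
    sample_pool,
)

NOISELESS = ChannelParams(0.0, 0.0, 0.0, 1.0, 2, 0.0)


class TestCorruptRead:
    def test_identity_at_zero_noise(self, random_block):
        read = corrupt_read(random_block, NOISELESS, np.random.default_rng(0))
        assert read.bases == random_block
        assert read.true_ops == (0, 0, 0)

    def test_deterministic_given_seed(self, random_block):
        p = ChannelParams(p_reverse=0.5)
        r1 = corrupt_read(random_block, p, np.random.default_rng(11))
        r2 = corrupt_read(random_block, p, np.random.default_rng(11))
        assert r1.bases == r2.bases and r1.is_reverse == r2.is_reverse

    def test_total_deletion_returns_none(self):
        # hp_del_boost drives the per-base deletion probability to its cap
        p = ChannelParams(0.0, 0.0, 0.89, 1.0, 1000, 0.0)
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="deleted"):
            got = None
            for _ in range(200):
                got = corrupt_read("ACGT", p, rng)
                if got is None:
                    break
        assert got is None

    def test_empirical_rates_match_parameters(self, random_block):
        """Monte-Carlo op counts vs binomial expectation, ~(85, 20, 45)/kb."""
        p = ChannelParams(0.085, 0.020, 0.045, 1.0, 1000, 0.0)
        rng = np.random.default_rng(5)
        n_reads, L = 2000, len(random_block)
        tot = np.zeros(3)
        for _ in range(n_reads):
            tot += corrupt_read(random_block, p, rng).true_ops
        mean = tot / n_reads
        for got, prob in zip(mean, (p.p_sub, p.p_ins, p.p_del)):
            expect = L * prob
            se = np.sqrt(L * prob * (1 - prob) / n_reads)
            assert abs(got - expect) < 3 * se

    def test_homopolymer_deletion_bias(self):
        """With a boost, deletions concentrate inside runs of length >= 2."""
        block = "AAAACCGGTTTTACGT" * 40
        codes = to_codes(block)
        _, run_len = _run_lengths_per_position(codes)
        unbiased = (run_len >= 2).mean()
        p = ChannelParams(0.0, 0.0, 0.03, 1.8, 1000, 0.0)
        rng = np.random.default_rng(6)
        in_runs = total = 0
        for _ in range(400):
            read = corrupt_read(block, p, rng)
            total += read.true_ops[2]
        # recompute deletions positionally for the bias ratio
        dels_in_runs = 0
        dels = 0
        rng = np.random.default_rng(6)
        boost = np.minimum(0.03 * 1.8 ** (run_len - 1.0), 0.9)
        for _ in range(400):
            u = np.random.default_rng(rng.integers(1 << 31)).random(codes.size)
            d = u < boost
            dels += d.sum()
            dels_in_runs += (d & (run_len >= 2)).sum()
        assert dels_in_runs / dels > unbiased

    def test_run_shortening_cap(self):
        """No single run loses more than max_run_shortening bases per read."""
        block = "A" * 8 + "C" * 8 + "G" * 8 + "T" * 8
        p = ChannelParams(0.0, 0.0, 0.4, 1.0, 2, 0.0)
        rng = np.random.default_rng(7)
        for _ in range(200):
            read = corrupt_read(block, p, rng)
            from itertools import groupby

            lens = {b: max(len(list(g)) for bb, g in groupby(read.bases) if bb == b)
                    for b in set(read.bases)}
            for b in "ACGT":
                if b in lens:
                    assert lens[b] >= 6  # 8 minus at most 2


class TestSamplePool:
    def test_count_conservation(self, random_block):
        pool = sample_pool([random_block] * 17, 50, NOISELESS, seed=1)
        assert len(pool) == 850

    def test_per_block_coverage_list(self, random_block):
        pool = sample_pool([random_block] * 3, [5, 9, 2], NOISELESS, seed=1)
        counts = {b: 0 for b in range(3)}
        for r in pool:
            counts[r.source_block] += 1
        assert counts == {0: 5, 1: 9, 2: 2}

    def test_deterministic_fastq(self, random_block, tmp_path):
        from dnastore.codec import write_fastq

        p1 = sample_pool([random_block], 10, ChannelParams(), seed=9)
        p2 = sample_pool([random_block], 10, ChannelParams(), seed=9)
        f1, f2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_fastq(p1, str(f1))
        write_fastq(p2, str(f2))
        assert f1.read_bytes() == f2.read_bytes()

    def test_fastq_roundtrip_with_truth(self, random_block, tmp_path):
        from dnastore.codec import read_fastq, write_fastq

        pool = sample_pool([random_block], 5, ChannelParams(), seed=2)
        fq, tsv = str(tmp_path / "r.fastq"), str(tmp_path / "r.tsv")
        write_fastq(pool, fq, tsv)
        back = read_fastq(fq, tsv)
        assert [r.bases for r in back] == [r.bases for r in pool]
        assert [r.source_block for r in back] == [r.source_block for r in pool]


class TestEmpiricalRates:
    def test_noiseless_pool_is_zero(self, random_block):
        pool = sample_pool([random_block], 5, NOISELESS, seed=0)
        rates = empirical_error_rates(pool, [random_block])
        assert rates[0] == (0.0, 0.0, 0.0)

    def test_single_planted_substitution(self, random_block):
        mutated = "T" + random_block[1:] if random_block[0] != "T" else (
            "A" + random_block[1:]
        )
        read = Read(mutated, "r0", source_block=0)
        rates = empirical_error_rates([read], [random_block])
        assert rates[0] == (1.0, 0.0, 0.0)

    def test_unlabeled_read_rejected(self, random_block):
        with pytest.raises(ValueError):
            empirical_error_rates([Read("ACGT", "r0")], [random_block])

    def test_alignment_estimates_near_truth_counts(self, random_block):
        """The edit-script estimator lands near the generative op counts."""
        p = ChannelParams(0.085, 0.020, 0.045, 1.0, 1000, 0.5)
        pool = sample_pool([random_block], 60, p, seed=4)
        rates = empirical_error_rates(pool, [random_block])
        sub, ins, dele = rates[0]
        L = len(random_block)
        # alignment minimizes edits, so allow a generous relative band
        assert abs(sub - 0.085 * L) < 0.25 * 0.085 * L
        assert abs(ins - 0.020 * L) < 0.4 * 0.020 * L
        assert abs(dele - 0.045 * L) < 0.4 * 0.045 * L
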