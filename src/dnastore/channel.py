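"""Synthetic nanopore-like read generator.

Corrupts DNA blocks with substitution, insertion and deletion errors at
per-base rates of the order seen on MinION-class flowcells (roughly 15%
combined per base, deletion-heavy in homopolymers).  The model is
positionwise independent except for one structured effect: the deletion
probability of a base grows geometrically with the length of the maximal
run containing it (``p_del * hp_del_boost**(run_len - 1)``), reproducing
the characteristic shortening of homopolymers.  Per base, deletion /
substitution are drawn as mutually exclusive events from one uniform
variate (so expected per-read counts are exactly ``L * p``), and an
insertion of a uniform base may independently follow any position.

Defaults are calibrated so a 1,000-base block yields on the order of
(85 substitutions, 20 insertions, 45 deletions) per read, bracketing the
per-read averages observed on real MinION readouts of 1 kb blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._seq import from_codes, revcomp, to_codes

_DEL_CAP = 0.9  # boosted per-base deletion probability is capped below 1


@dataclass(frozen=True)
class ChannelParams:
    """Error model of the simulated sequencer.

    p_sub, p_ins, p_del
        Per-base probabilities of substitution, insertion-after, deletion.
    hp_del_boost
        Multiplicative deletion-rate factor per extra base of the maximal
        run containing a position (1.0 = no homopolymer bias).
    max_run_shortening
        At most this many deletions are applied within any single run of a
        single read; nanopore shortening clips runs by one or two bases
        rather than erasing them.
    p_reverse
        Probability a read is emitted as the reverse-complement strand.
    """

    p_sub: float = 0.085
    p_ins: float = 0.020
    p_del: float = 0.045
    hp_del_boost: float = 1.5
    max_run_shortening: int = 2
    p_reverse: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.p_sub, self.p_ins, self.p_del):
            if not 0 <= p < 1:
                raise ValueError("probabilities must be in [0, 1)")
        if self.p_sub + self.p_ins + self.p_del >= 1:
            raise ValueError("p_sub + p_ins + p_del must be < 1")
        if self.hp_del_boost < 1:
            raise ValueError("hp_del_boost must be >= 1")


@dataclass
class Read:
    """One (noisy) sequence emitted by the channel."""

    bases: str
    id: str
    source_block: int | None = None
    is_reverse: bool = False
    true_ops: tuple[int, int, int] | None = None  # (sub, ins, del) applied

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("reads must be non-empty")


def _run_lengths_per_position(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(run id, run length) for every position, vectorized."""
    n = codes.size
    boundaries = np.empty(n, bool)
    boundaries[0] = True
    boundaries[1:] = codes[1:] != codes[:-1]
    run_id = np.cumsum(boundaries) - 1
    counts = np.bincount(run_id)
    return run_id, counts[run_id]


def corrupt_read(
    block: str,
    params: ChannelParams,
    rng: np.random.Generator,
    read_id: str = "r0",
    source_block: int | None = None,
) -> Read | None:
    """One noisy read of ``block``; None if every base was deleted."""
    codes = to_codes(block)
    n = codes.size
    run_id, run_len = _run_lengths_per_position(codes)
    p_del_i = np.minimum(
        params.p_del * params.hp_del_boost ** (run_len - 1.0), _DEL_CAP
    )
    u = rng.random(n)
    deleted = u < p_del_i
    # substitution band sits above the deletion band of the same variate,
    # so E[subs] = n * p_sub independent of the homopolymer boost
    substituted = (u >= p_del_i) & (u < p_del_i + params.p_sub)
    # clip per-run shortening: keep only the first `max_run_shortening`
    # deletions inside any one run
    if deleted.any():
        k = params.max_run_shortening
        del_runs = run_id[deleted]
        excess = np.bincount(del_runs, minlength=run_id[-1] + 1) > k
        for r in np.nonzero(excess)[0]:
            idx = np.nonzero(deleted & (run_id == r))[0]
            deleted[idx[k:]] = False
    sub_offsets = rng.integers(1, 4, n, dtype=np.uint8)
    inserted = rng.random(n) < params.p_ins
    ins_bases = rng.integers(0, 4, n, dtype=np.uint8)

    out_codes = codes.copy()
    out_codes[substituted] = (codes[substituted] + sub_offsets[substituted]) % 4
    # interleave: slot 2i = (possibly substituted) base, slot 2i+1 = insertion
    slots = np.empty(2 * n, np.uint8)
    keep = np.zeros(2 * n, bool)
    slots[0::2] = out_codes
    keep[0::2] = ~deleted
    slots[1::2] = ins_bases
    keep[1::2] = inserted
    emitted = slots[keep]
    if emitted.size == 0:
        warnings.warn(f"read {read_id}: all bases deleted; dropped", stacklevel=2)
        return None
    bases = from_codes(emitted)
    is_reverse = bool(rng.random() < params.p_reverse)
    if is_reverse:
        bases = revcomp(bases)
    return Read(
        bases=bases,
        id=read_id,
        source_block=source_block,
        is_reverse=is_reverse,
        true_ops=(int(substituted.sum()), int(inserted.sum()), int(deleted.sum())),
    )


def sample_pool(
    blocks: list[str],
    coverage: int | list[int],
    params: ChannelParams,
    seed: int,
) -> list[Read]:
    """``coverage`` reads per block, shuffled; deterministic given the seed.

    Truth labels (source block, strand, applied op counts) are retained on
    each :class:`Read` for evaluation only; the decoder never looks at them.
    """
    rng = np.random.default_rng(seed)
    if isinstance(coverage, int):
        per_block = [coverage] * len(blocks)
    else:
        per_block = list(coverage)
        if len(per_block) != len(blocks):
            raise ValueError("per-block coverage list length mismatch")
    if any(c < 1 for c in per_block):
        raise ValueError("coverage must be >= 1")
    reads: list[Read] = []
    counter = 0
    for b, (block, cov) in enumerate(zip(blocks, per_block)):
        for _ in range(cov):
            r = None
            while r is None:  # re-draw the (vanishingly rare) empty read
                r = corrupt_read(
                    block, params, rng, read_id=f"r{counter:06d}", source_block=b
                )
            reads.append(r)
            counter += 1
    order = np.random.default_rng(seed + 1_000_003).permutation(len(reads))
    return [reads[i] for i in order]


def empirical_error_rates(
    reads: list[Read], truth_blocks: list[str]
) -> dict[int, tuple[float, float, float]]:
    """Alignment-estimated per-block mean (sub, ins, del) counts per read.

    Each read is aligned to its truth block with edlib (unit costs,
    extended CIGAR) and the edit operations are tallied, mirroring how
    per-read error tables are produced from real data.  Note this is an
    *estimator*: the minimum-edit script of a heavily corrupted read can
    contain slightly fewer operations than were actually applied.
    """
    import edlib

    sums: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for read in reads:
        if read.source_block is None:
            raise ValueError(f"read {read.id} has no truth label")
        truth = truth_blocks[read.source_block]
        seq = revcomp(read.bases) if read.is_reverse else read.bases
        res = edlib.align(seq, truth, mode="NW", task="path")
        sub = ins = dele = 0
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
            else:
                k = int(num)
                num = ""
                if ch == "X":
                    sub += k
                elif ch == "I":
                    ins += k
                elif ch == "D":
                    dele += k
        trip = np.array([sub, ins, dele], float)
        b = read.source_block
        sums[b] = sums.get(b, np.zeros(3)) + trip
        counts[b] = counts.get(b, 0) + 1
    return {
        b: tuple(np.round(sums[b] / counts[b], 3)) for b in sorted(sums)
    }
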