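"""Consensus reconstruction of DNA blocks from noisy reads.

The reconstruction runs in two phases, mirroring how nanopore readouts of
addressed storage blocks are post-processed in practice:

**Phase 1 -- rough estimate.**  Reads are demultiplexed by *exact* match to
a block's 16-base address (the in-silico analogue of selective PCR).  The
high-quality reads of each block are aligned with a progressive
(center-star) multiple sequence aligner under several scoring presets --
stand-ins for running several external MSA tools, whose parameters would
each be tuned differently -- and each preset yields a per-column plurality
consensus.  The preset consensuses are then fused run-by-run into an
*aggregate majority-homopolymer* consensus: homopolymer runs are put in
correspondence through an alignment of the consensuses, every run present
in at least one input is kept, and its length is the mode over the inputs
containing it (ties resolved toward the longer run, because the channel is
deletion-dominant).

**Phase 2 -- iterative polishing.**  All reads (not only the exact-address
ones) are re-aligned to the current estimate with a banded overlap
aligner.  Column-plurality re-estimation and a reference-free rebuild of
locally garbled regions come first; then every homopolymer run of the
estimate collects run-length votes from the aligned reads (insertions
consistently supported by a majority of covering reads become new runs),
and lengths are chosen by an exact dynamic program that keeps every
completed aligned 8-base window GC-balanced while maximizing a
channel-aware likelihood of the observed length histograms.  A
substitution sweep and ML-guarded micro-repair windows run between vote
rounds.  Each stage stops at a fixed point or after its round limit.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._seq import from_codes, revcomp, to_codes
from .addresses import Address
from .align import OP_A, OP_DIAG, Scoring, pairwise_align
from .balanced import WORD_BASES
from .channel import Read

GAP = 4
ABSENT = 5

#: half-width of the alignment band used throughout consensus building
DEFAULT_BAND = 64

SELECT_POOL = 40  # at most this many reads enter medoid selection


@dataclass(frozen=True)
class MsaPreset:
    """One scoring preset of the progressive MSA engine."""

    name: str
    match: int
    mismatch: int
    gap_open: int
    gap_extend: int

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.mismatch >= self.match:
            raise ValueError("mismatch score must be < match score")

    @property
    def scoring(self) -> Scoring:
        return Scoring(self.match, self.mismatch, self.gap_open, self.gap_extend)


#: four presets spanning gap-tolerant to gap-averse behaviour, so their
#: consensuses err differently and the aggregation step has diversity to use
DEFAULT_PRESETS: tuple[MsaPreset, ...] = (
    MsaPreset("gaptol", 2, -3, -2, -1),
    MsaPreset("balanced", 1, -1, -4, -1),
    MsaPreset("strict", 2, -2, -8, -2),
    MsaPreset("cheapext", 1, -2, -2, -1),
)

AGGREGATE_SCORING = Scoring(1, -2, -2, -1)
POLISH_SCORING = Scoring(2, -4, -4, -2)


@dataclass
class ConsensusEstimate:
    """A block estimate plus the evidence behind its homopolymer runs."""

    bases: str
    support: list[tuple[str, int, int, int]] = field(default_factory=list)
    # (run base, chosen length, votes for chosen, total votes)
    iteration: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("consensus estimate must be non-empty")


def demultiplex(
    pool: list[Read], addresses: list[Address]
) -> tuple[dict[int, list[Read]], list[Read]]:
    """Assign reads that contain exactly one address as an exact 16-mer.

    Matches are sought on both strands; reverse-strand reads are
    canonicalized to forward orientation.  Reads matching zero or more
    than one address are returned in the set-aside list.
    """
    seen = set()
    for a in addresses:
        if a.bases in seen:
            raise ValueError("addresses must be pairwise distinct")
        seen.add(a.bases)
    assigned: dict[int, list[Read]] = {a.index: [] for a in addresses}
    leftovers: list[Read] = []
    for read in pool:
        rc = revcomp(read.bases)
        hits: list[tuple[int, bool]] = []
        for a in addresses:
            fwd = a.bases in read.bases
            rev = a.bases in rc
            if fwd or rev:
                hits.append((a.index, fwd))
        if len(hits) != 1:
            leftovers.append(read)
            continue
        idx, fwd = hits[0]
        if fwd:
            assigned[idx].append(read)
        else:
            assigned[idx].append(
                Read(rc, read.id, read.source_block, not read.is_reverse, read.true_ops)
            )
    return assigned, leftovers


def _edlib_distance(a: str, b: str) -> int:
    import edlib

    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _select_reads(reads: list[Read], cap: int) -> tuple[Read, list[Read]]:
    """Medoid read plus the ``cap - 1`` reads nearest to it (deterministic)."""
    pool = reads[:SELECT_POOL]
    if len(pool) == 1:
        return pool[0], []
    k = len(pool)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = _edlib_distance(pool[i].bases, pool[j].bases)
            dist[i, j] = dist[j, i] = d
    totals = dist.sum(axis=1)
    medoid = int(np.argmin(totals))  # argmin is first-index on ties
    order = sorted(
        (i for i in range(k) if i != medoid), key=lambda i: (dist[medoid, i], i)
    )
    return pool[medoid], [pool[i] for i in order[: max(0, cap - 1)]]


def star_rows(
    center: str, others: list[str], scoring: Scoring, band: int = DEFAULT_BAND
) -> np.ndarray:
    """Center-star MSA matrix: row 0 is the center, then one row per read.

    Cell codes: 0..3 bases, 4 gap, 5 absent (outside a read's aligned
    span).  Pairwise alignments to the center are merged with the usual
    "once a gap, always a gap" rule on center coordinates.
    """
    n = len(center)
    all_ops = [
        pairwise_align(o, center, scoring, mode="overlap", band=band).ops
        for o in others
    ]
    max_ins = np.zeros(n + 1, np.int64)
    for ops in all_ops:
        cpos = 0
        run = 0
        for op in ops:
            if op == OP_A:
                run += 1
            else:
                if run:
                    max_ins[cpos] = max(max_ins[cpos], run)
                    run = 0
                cpos += 1
        if run:
            max_ins[n] = max(max_ins[n], run)
    cum = np.cumsum(max_ins)
    col_of = np.arange(n) + cum[:n]  # column of center position p
    ins_start = np.concatenate([cum - max_ins + np.arange(n + 1)])
    C = int(n + cum[-1])
    mat = np.full((len(others) + 1, C), GAP, np.uint8)
    mat[0, col_of] = to_codes(center)
    for r, (o, ops) in enumerate(zip(others, all_ops), start=1):
        codes = to_codes(o)
        used = np.zeros(n + 1, np.int64)
        ri = cpos = 0
        first_col = C
        last_col = -1
        for op in ops:
            if op == OP_DIAG:
                col = int(col_of[cpos])
                mat[r, col] = codes[ri]
                first_col = min(first_col, col)
                last_col = max(last_col, col)
                ri += 1
                cpos += 1
            elif op == OP_A:
                col = int(ins_start[cpos] + used[cpos])
                used[cpos] += 1
                mat[r, col] = codes[ri]
                first_col = min(first_col, col)
                last_col = max(last_col, col)
                ri += 1
            else:
                cpos += 1
        if first_col > 0:
            mat[r, :first_col] = ABSENT
        if last_col < C - 1:
            mat[r, last_col + 1 :] = ABSENT
    return mat


def _column_consensus(
    mat: np.ndarray, insert_cols: np.ndarray | None = None, insert_frac: float = 0.5
) -> str:
    """Per-column plurality call; gap-plurality columns are dropped.

    Ties between a base and the gap keep the base (the channel is
    deletion-dominant); ties between bases resolve in A<C<G<T order.
    Columns supported by a single read at the flanks (all other rows
    absent) are dropped as unverifiable.

    ``insert_cols`` marks columns that are insertions relative to a
    reference row; those are kept at the (lower) ``insert_frac`` of
    present rows, because reads supporting a genuinely missing base often
    scatter across adjacent insertion slots while a spurious inserted run
    is cheap to remove by later run-length voting.
    """
    cnt = np.stack([(mat == v).sum(axis=0) for v in range(6)])
    base_best = cnt[:4].argmax(axis=0)
    base_cnt = cnt[:4].max(axis=0)
    min_support = min(2, mat.shape[0])
    # absent rows count against a column: bases seen only in the overhang
    # of a few reads (all others ended before) are unverifiable junk
    keep = (base_cnt >= cnt[4] + cnt[5]) & (base_cnt >= min_support)
    if insert_cols is not None:
        present = mat.shape[0] - cnt[5]
        keep_ins = (base_cnt >= insert_frac * present) & (base_cnt >= min_support)
        keep = np.where(insert_cols, keep_ins, keep)
    return from_codes(base_best[keep].astype(np.uint8))


def msa_consensus(
    reads: list[Read],
    preset: MsaPreset,
    cap: int = 15,
    band: int = DEFAULT_BAND,
) -> str:
    """Progressive (center-star) MSA consensus of up to ``cap`` reads."""
    if not reads:
        raise ValueError("msa_consensus requires at least one read")
    if len(reads) == 1:
        return reads[0].bases
    center, others = _select_reads(reads, cap)
    mat = star_rows(center.bases, [o.bases for o in others], preset.scoring, band)
    return _column_consensus(mat)


def _row_runs(row: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Maximal same-base runs of one MSA row: (base, start_col, end_col, len).

    Gap cells inside a run (caused by other rows' insertions) do not break
    it; a run ends when a different base appears.
    """
    runs = []
    cur_base = -1
    start = length = last = 0
    for col in range(row.size):
        v = int(row[col])
        if v >= GAP:
            continue
        if v == cur_base:
            length += 1
            last = col
        else:
            if cur_base >= 0:
                runs.append((cur_base, start, last, length))
            cur_base = v
            start = last = col
            length = 1
    if cur_base >= 0:
        runs.append((cur_base, start, last, length))
    return runs


def aggregate_majority_homopolymer(
    consensuses: list[str],
    band: int = DEFAULT_BAND,
    scoring: Scoring = AGGREGATE_SCORING,
) -> str:
    """Fuse >= 2 consensus sequences run-by-run (majority homopolymer).

    Runs are put in correspondence by aligning all consensuses (center-star
    around the medoid) and grouping same-base runs whose column extents
    overlap.  A run present in at least one input is included; its length
    is the mode over the inputs containing it, ties resolved toward the
    longer length.
    """
    if len(consensuses) < 2:
        raise ValueError("aggregation requires at least two consensuses")
    k = len(consensuses)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = _edlib_distance(consensuses[i], consensuses[j])
            dist[i, j] = dist[j, i] = d
    medoid = int(np.argmin(dist.sum(axis=1)))
    others = [consensuses[i] for i in range(k) if i != medoid]
    mat = star_rows(consensuses[medoid], others, scoring, band)

    # group runs across rows: same base, overlapping column extents,
    # at most one run per row per group
    groups: list[dict] = []
    by_base: dict[int, list[tuple[int, int, int, int, int]]] = {}
    for r in range(mat.shape[0]):
        for base, start, end, length in _row_runs(mat[r]):
            by_base.setdefault(base, []).append((start, end, length, r, base))
    for base, runs in by_base.items():
        runs.sort()
        open_groups: list[dict] = []
        for start, end, length, r, _ in runs:
            placed = False
            for g in open_groups:
                if start <= g["end"] and r not in g["rows"]:
                    g["end"] = max(g["end"], end)
                    g["start"] = min(g["start"], start)
                    g["rows"].add(r)
                    g["lengths"].append(length)
                    placed = True
                    break
            if not placed:
                open_groups.append(
                    {
                        "base": base,
                        "start": start,
                        "end": end,
                        "rows": {r},
                        "lengths": [length],
                    }
                )
        groups.extend(open_groups)

    groups.sort(key=lambda g: (g["start"], g["end"], g["base"]))
    out = []
    for g in groups:
        counts = Counter(g["lengths"])
        length = max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
        out.append("ACGT"[g["base"]] * length)
    return "".join(out)


def _mode_longest(values: list[int]) -> int:
    counts = Counter(values)
    return max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]


@dataclass(frozen=True)
class LengthPrior:
    """Observation model for homopolymer run lengths under a nanopore-like
    channel: deletions shorten runs (more often the longer the run), by at
    most ``max_shortening``; insertions occasionally lengthen them.

    Used to score candidate true lengths against the histogram of aligned
    per-read lengths: a candidate one longer than most observations is
    cheap (deletions are expected), one shorter than many observations is
    expensive (insertions are rare).  Defaults mirror the simulator's
    channel calibration; they need only be roughly right.
    """

    p_del: float = 0.045
    hp_del_boost: float = 1.5
    p_ins: float = 0.02
    max_shortening: int = 2

    def log_obs(self, true_len: int, obs: int) -> float:
        import math

        floor = 1e-4
        if true_len == 0:
            p = 0.97 if obs == 0 else (0.02 if obs == 1 else floor)
            return math.log(p)
        delta = min(0.5, self.p_del * self.hp_del_boost ** (true_len - 1))
        p0 = (1 - delta) ** true_len
        p1 = true_len * delta * (1 - delta) ** (true_len - 1)
        p2 = max(floor, 1 - p0 - p1) if true_len >= 2 else floor
        p_ins = min(0.2, self.p_ins * (true_len + 1) * 2)
        if obs == true_len:
            p = p0 * (1 - p_ins)
        elif obs == true_len - 1:
            p = p1
        elif obs == true_len - 2 and true_len >= 2:
            p = p2
        elif obs == true_len + 1:
            p = p_ins
        elif obs < true_len - 2:
            # deeper shortenings are mostly alignment attribution noise;
            # rare, but nowhere near impossible
            p = 0.01 * 0.3 ** (true_len - 2 - obs - 1)
        elif obs == true_len + 2:
            p = 0.008
        else:
            p = floor
        return math.log(max(p, floor))

    def score(self, true_len: int, histogram: Counter) -> float:
        return sum(n * self.log_obs(true_len, k) for k, n in histogram.items())


DEFAULT_LENGTH_PRIOR = LengthPrior()


def _window_scan(pos: int, gc: int, is_gc: int, length: int) -> tuple[int, int, int]:
    """Append ``length`` bases of one GC class to the running window state.

    Returns (violations among windows completed during the append, new
    position, new partial-window GC count).  The scan never aborts, so the
    window frame stays consistent even across a violated window.
    """
    violations = 0
    for _ in range(length):
        gc += is_gc
        pos += 1
        if pos % WORD_BASES == 0:
            if gc != 4:
                violations += 1
            gc = 0
    return violations, pos, gc


def _repair_regions(
    est: str,
    reads: list[Read],
    scoring: Scoring,
    band: int,
    address_len: int,
    rate_threshold: float = 0.08,
    pad: int = 24,
) -> tuple[str, list[str]]:
    """Rebuild locally garbled stretches of the estimate from read segments.

    A badly reconstructed region is recognizable without truth: reads pile
    up insertions against it at many times the channel's insertion rate,
    because the estimate is locally missing bases.  Reference-anchored
    column or run voting cannot repair such a stretch (every read takes a
    different alignment path through it, so the votes scatter), but a
    reference-free mini-consensus of the reads' own segments can: the
    segments are re-aligned around a medoid *read* segment, whose errors
    are isolated rather than clustered, and the column plurality is solid
    again.
    """
    n = len(est)
    ins = np.zeros(n + 1)
    cov = np.zeros(n + 1)
    all_ops = []
    for read in reads:
        ops = pairwise_align(read.bases, est, scoring, mode="overlap", band=band).ops
        all_ops.append(ops)
        ei = 0
        started = False
        for op in ops:
            if op == OP_DIAG:
                started = True
                cov[ei] += 1
                ei += 1
            elif op == OP_A:
                if started:
                    ins[ei] += 1
            else:
                ei += 1
    rate = ins[:n] / np.maximum(cov[:n], 1)
    w = 24
    smooth = np.convolve(rate, np.ones(w) / w, mode="same")
    hot = smooth > rate_threshold
    hot[:address_len] = False
    if not hot.any():
        return est, []
    # merge hot positions into padded regions
    regions: list[list[int]] = []
    for p in np.nonzero(hot)[0]:
        if regions and p - regions[-1][1] <= 2 * pad:
            regions[-1][1] = p
        else:
            regions.append([int(p), int(p)])
    flags = []
    out = []
    prev = 0
    for a, b in regions:
        a = max(address_len, a - pad)
        b = min(n, b + pad + 1)
        if a < prev:
            a = prev
        segments = []
        for read, ops in zip(reads, all_ops):
            seg, covered = _read_segment(read.bases, ops, a, b)
            if covered and seg:
                segments.append(seg)
        if len(segments) < 3:
            flags.append(f"garbled region {a}-{b}: too few covering reads")
            continue
        segments = segments[:SELECT_POOL]
        k = len(segments)
        dist = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                d = _edlib_distance(segments[i], segments[j])
                dist[i, j] = dist[j, i] = d
        medoid = int(np.argmin(dist.sum(axis=1)))
        others = [segments[i] for i in range(k) if i != medoid]
        mat = star_rows(segments[medoid], others, scoring, band=max(16, band // 2))
        patch = _column_consensus(mat)
        if patch:
            flags.append(f"rebuilt garbled region {a}-{b} from {k} read segments")
            out.append(est[prev:a])
            out.append(patch)
            prev = b
    out.append(est[prev:])
    return "".join(out), flags


def _read_segment(bases: str, ops: np.ndarray, a: int, b: int) -> tuple[str, bool]:
    """The read substring aligned to estimate positions [a, b)."""
    ri = ei = 0
    r_a = r_b = -1
    seen_first = False
    seen_last = False
    for op in ops:
        if op == OP_DIAG:
            if ei == a:
                r_a = ri
            if not seen_first:
                seen_first = ei <= a
            if ei == b - 1:
                r_b = ri + 1
                seen_last = True
            ri += 1
            ei += 1
        elif op == OP_A:
            if ei == a and r_a < 0:
                r_a = ri
            ri += 1
        else:
            if ei == a:
                r_a = ri
            if ei == b - 1:
                r_b = ri
                seen_last = True
            ei += 1
    if r_a < 0 or r_b < 0 or r_b <= r_a:
        return "", False
    return bases[r_a:r_b], seen_first and seen_last


def pin_address(consensus: str, address: str, flags: list[str] | None = None) -> str:
    """Replace a consensus's address region with the known address.

    The address is located exactly if possible, otherwise by infix edit
    distance; as a last resort the consensus is assumed to start at the
    address and its first ``len(address)`` bases are overwritten.
    """
    import edlib

    pos = consensus.find(address)
    if pos >= 0:
        return address + consensus[pos + len(address) :]
    # anchored prefix alignment; among tied end positions prefer the one
    # closest to the address length, so a repeat straddling the
    # address/payload seam cannot duplicate or swallow payload bases
    n_addr = len(address)
    head = consensus[: n_addr + 16]
    res = edlib.align(address, head, mode="SHW", task="locations", k=n_addr // 3)
    if res["editDistance"] == -1 or not res["locations"]:
        res = edlib.align(
            address, consensus, mode="HW", task="locations", k=n_addr // 2
        )
    if res["editDistance"] == -1 or not res["locations"]:
        if flags is not None:
            flags.append("address not located in consensus; assuming offset 0")
        return address + consensus[n_addr:]
    end = min((loc[1] + 1 for loc in res["locations"]), key=lambda e: abs(e - n_addr))
    return address + consensus[end:]


def iterative_polish(
    estimate: ConsensusEstimate | str,
    reads: list[Read],
    address_len: int = 16,
    max_iters: int = 5,
    band: int = DEFAULT_BAND,
    scoring: Scoring = POLISH_SCORING,
    new_run_frac: float = 0.5,
    refine_rounds: int = 2,
    prior: LengthPrior = DEFAULT_LENGTH_PRIOR,
) -> ConsensusEstimate:
    """Refine a block estimate by re-aligning reads and re-voting run lengths.

    Two mechanisms run in sequence each call.  First, up to
    ``refine_rounds`` of whole-column re-estimation: all reads are
    star-aligned to the current estimate and a per-column plurality call
    replaces it, which repairs locally garbled stretches that per-run
    votes cannot anchor to.  Then up to ``max_iters`` rounds of
    homopolymer-run length voting under the GC-balance constraint (see
    the module docstring).  The first ``address_len`` bases are treated
    as trusted (they come from the sidecar address) and are re-pinned
    after every round.
    """
    if not reads:
        raise ValueError("polishing requires at least one read")
    est = estimate.bases if isinstance(estimate, ConsensusEstimate) else estimate
    address = est[:address_len]
    flags: list[str] = []

    def _refine(cur: str, rounds: int) -> str:
        for _ in range(rounds):
            mat = star_rows(cur, [r.bases for r in reads], scoring, band)
            if mat.shape[0] < 2:
                break
            insert_cols = mat[0] == GAP  # columns absent from the reference
            cons = _column_consensus(mat[1:], insert_cols, insert_frac=0.35)
            if not cons:
                break
            cons = pin_address(cons, address, flags)
            if cons == cur:
                break
            cur = cons
        return cur

    est = _refine(est, refine_rounds)
    if len(reads) >= 3:
        repaired, repair_flags = _repair_regions(est, reads, scoring, band, address_len)
        flags.extend(repair_flags)
        if repaired != est:
            est = pin_address(repaired, address, flags)
            est = _refine(est, refine_rounds)
    support: list[tuple[str, int, int, int]] = []
    iteration = 0
    # vote rounds, one ML-guarded micro-repair pass, then vote rounds again:
    # the run-length/balance vote always has the last word, since the
    # segment consensus used by micro-repair inherits the channel's
    # homopolymer-shortening bias that only the balance vote undoes
    for outer in range(3):
        for iteration in range(1, max_iters + 1):
            evidence = _collect_evidence(est, reads, scoring, band)
            new_est, support, round_flags = _polish_round(
                est, reads, address_len, band, scoring, new_run_frac, evidence, prior
            )
            flags.extend(round_flags)
            if new_est == est:
                break
            est = new_est
        if outer == 2 or len(reads) < 4:
            break
        evidence = _collect_evidence(est, reads, scoring, band)
        swept, sweep_flags = _substitution_sweep(est, evidence, address_len)
        if swept != est:
            flags.extend(sweep_flags)
            est = swept
            evidence = _collect_evidence(est, reads, scoring, band)
        repaired, micro_flags = _micro_repair(
            est, reads, evidence, scoring, band, address_len
        )
        flags.extend(micro_flags)
        if repaired == est and swept == est:
            break
        if repaired != est:
            est = pin_address(repaired, address, flags)
    return ConsensusEstimate(bases=est, support=support, iteration=iteration, flags=flags)


@dataclass
class _Evidence:
    """Everything one read-alignment pass tells us about an estimate."""

    runs: list[tuple[str, int, int]]  # (base, start, end-exclusive)
    votes: list[Counter]  # per run: observed length -> #reads
    ins_votes: dict[tuple[int, str], list[int]]  # (pos, base) -> lengths
    pos_cov: np.ndarray  # reads whose aligned core spans each position
    ops_list: list[np.ndarray]  # per read: alignment op path to the estimate
    cores: list[tuple[int, int]]  # per read: aligned [start, end) on estimate
    base_votes: np.ndarray  # (n, 4) diagonal read-base tallies per position


def _collect_evidence(
    est: str, reads: list[Read], scoring: Scoring, band: int
) -> _Evidence:
    n = len(est)
    runs: list[tuple[str, int, int]] = []
    start = 0
    for base, grp in itertools.groupby(est):
        length = sum(1 for _ in grp)
        runs.append((base, start, start + length))
        start += length
    run_of = np.empty(n, np.int64)
    for r, (_, s, e) in enumerate(runs):
        run_of[s:e] = r
    n_runs = len(runs)
    votes: list[Counter] = [Counter() for _ in range(n_runs)]
    ins_votes: dict[tuple[int, str], list[int]] = {}
    pos_cov = np.zeros(n + 1, np.int64)
    ops_list: list[np.ndarray] = []
    cores: list[tuple[int, int]] = []
    base_votes = np.zeros((n, 4), np.int64)
    b2i = {"A": 0, "C": 1, "G": 2, "T": 3}

    for read in reads:
        ops = pairwise_align(read.bases, est, scoring, mode="overlap", band=band).ops
        ops_list.append(ops)
        counts = np.zeros(n_runs, np.int64)
        read_ins: dict[tuple[int, str], int] = {}
        min_match = np.full(n_runs, n + 1, np.int64)
        max_match = np.full(n_runs, -1, np.int64)
        pending_subs: list[tuple[int, int]] = []
        ri = ei = 0
        first_diag = -1
        last_diag = -1
        rb = read.bases
        for op in ops:
            if op == OP_DIAG:
                c = rb[ri]
                base_votes[ei, b2i[c]] += 1
                if c == est[ei]:
                    r0 = run_of[ei]
                    counts[r0] += 1
                    if ei < min_match[r0]:
                        min_match[r0] = ei
                    if ei > max_match[r0]:
                        max_match[r0] = ei
                # a boundary mismatch that matches an adjacent run is
                # evidence for that run's length, not a free-floating error
                elif ei > 0 and c == est[ei - 1]:
                    counts[run_of[ei - 1]] += 1
                elif ei + 1 < n and c == est[ei + 1]:
                    counts[run_of[ei + 1]] += 1
                else:
                    pending_subs.append((ei, int(run_of[ei])))
                if first_diag < 0:
                    first_diag = ei
                last_diag = ei
                ri += 1
                ei += 1
            elif op == OP_A:
                c = rb[ri]
                if ei > 0 and c == est[ei - 1]:
                    counts[run_of[ei - 1]] += 1
                elif ei < n and c == est[ei]:
                    counts[run_of[ei]] += 1
                else:
                    key = (ei, c)
                    read_ins[key] = read_ins.get(key, 0) + 1
                ri += 1
            else:
                ei += 1
        if first_diag < 0:
            cores.append((0, 0))
            continue
        # an interior substitution flanked by matches of the same run still
        # consumes one of the run's positions, so it witnesses the length;
        # an unanchored mismatch (e.g. on a junk single-base run) does not
        for pos_s, r0 in pending_subs:
            if min_match[r0] < pos_s < max_match[r0]:
                counts[r0] += 1
        e_start, e_end = first_diag, last_diag + 1
        cores.append((e_start, e_end))
        for r, (_, s, e) in enumerate(runs):
            if s >= e_start and e <= e_end:
                votes[r][int(counts[r])] += 1
            elif r == n_runs - 1 and s >= e_start and e_end >= s:
                # the terminal run: a read whose alignment stops at or past
                # the run's start still witnesses how long the block's tail
                # is -- otherwise unsupported trailing bases collect no
                # votes at all and can never be removed
                votes[r][int(counts[r])] += 1
        for (pos, c), length in read_ins.items():
            if e_start < pos < e_end:
                ins_votes.setdefault((pos, c), []).append(length)
        pos_cov[e_start + 1 : e_end] += 1
    return _Evidence(runs, votes, ins_votes, pos_cov, ops_list, cores, base_votes)


def _polish_round(
    est: str,
    reads: list[Read],
    address_len: int,
    band: int,
    scoring: Scoring,
    new_run_frac: float,
    evidence: _Evidence | None = None,
    prior: LengthPrior = DEFAULT_LENGTH_PRIOR,
) -> tuple[str, list[tuple[str, int, int, int]], list[str]]:
    if evidence is None:
        evidence = _collect_evidence(est, reads, scoring, band)
    runs = evidence.runs
    votes = evidence.votes
    ins_votes = evidence.ins_votes
    pos_cov = evidence.pos_cov

    accepted_ins: list[tuple[int, str, int]] = []
    for (pos, c), lens in ins_votes.items():
        if pos < address_len:
            continue
        cov = int(pos_cov[pos])
        if cov > 0 and len(lens) > new_run_frac * cov:
            accepted_ins.append((pos, c, _mode_longest(lens)))
    accepted_ins.sort(key=lambda t: (t[0], t[1]))

    # assemble slots: fixed address runs, voted runs, inserted runs, splits
    slots: list[dict] = []
    ins_iter = iter(accepted_ins)
    pending = next(ins_iter, None)
    for r, (base, s, e) in enumerate(runs):
        while pending is not None and pending[0] <= s:
            slots.append({"base": pending[1], "cands": [pending[2]], "new": True})
            pending = next(ins_iter, None)
        interior = []
        while pending is not None and s < pending[0] < e:
            interior.append(pending)
            pending = next(ins_iter, None)
        cur_len = e - s
        if e <= address_len:
            slots.append({"base": base, "cands": [cur_len], "fixed": True})
            continue
        if interior:
            # split the run around interior insertions; lengths re-voted
            # on the next round once the structure has settled
            cut = s
            for pos, c, length in interior:
                if pos > cut:
                    slots.append({"base": base, "cands": [pos - cut], "fixed": True})
                slots.append({"base": c, "cands": [length], "new": True})
                cut = pos
            if e > cut:
                slots.append({"base": base, "cands": [e - cut], "fixed": True})
            continue
        vc = votes[r]
        min_len = max(0, address_len - s)
        if not vc:
            cands = [max(cur_len, min_len)]
            scores = {cands[0]: 0.0}
        else:
            kmin, kmax = min(vc), max(vc)
            lo = max(min_len, kmin - 1)
            hi = kmax + prior.max_shortening
            cands_all = list(range(lo, hi + 1)) or [max(cur_len, min_len)]
            scores = {L: prior.score(L, vc) for L in cands_all}
            # keep the plausible few, best first, so the balance DP stays
            # small; a candidate the reads cannot explain is never offered
            cands = sorted(cands_all, key=lambda L: -scores[L])[:6]
        slots.append({"base": base, "cands": cands, "scores": scores, "votes": vc})
    while pending is not None:
        slots.append({"base": pending[1], "cands": [pending[2]], "new": True})
        pending = next(ins_iter, None)

    chosen_lens, n_viol = _balance_dp(slots)
    round_flags: list[str] = []
    if n_viol:
        round_flags.append(f"{n_viol} window(s) left unbalanced by the vote DP")
    out = []
    support: list[tuple[str, int, int, int]] = []
    for slot, chosen in zip(slots, chosen_lens):
        out.append(slot["base"] * chosen)
        vc = slot.get("votes")
        if vc is not None:
            support.append(
                (slot["base"], chosen, vc.get(chosen, 0), sum(vc.values()))
            )
        else:
            support.append((slot["base"], chosen, 0, 0))
    return "".join(out), support, round_flags


def _micro_repair(
    est: str,
    reads: list[Read],
    evidence: _Evidence,
    scoring: Scoring,
    band: int,
    address_len: int,
    pad: int = 25,
    min_gain: int = 2,
) -> tuple[str, list[str]]:
    """Rebuild small suspicious windows from read segments, ML-guarded.

    Reference-anchored voting has known blind spots: a transposed base can
    sit in an alignment-ambiguous attractor where reads appear to confirm
    the wrong structure, and unsupported bases at the very ends collect no
    run votes at all.  This pass turns every local anomaly -- an insertion
    event with non-trivial support, a run whose vote runner-up is close to
    the winner, and the two terminal windows -- into a candidate window,
    rebuilds the window as a reference-free mini-consensus of the covering
    reads' segments, and accepts the patch only if it strictly lowers the
    total edit distance between the window and those segments (i.e. only
    if the reads genuinely prefer it).
    """
    n = len(est)
    sites: list[int] = []
    for (pos, c), lens in evidence.ins_votes.items():
        cov = int(evidence.pos_cov[pos])
        if pos >= address_len and cov >= 4 and len(lens) >= 0.2 * cov:
            sites.append(pos)
    for r, (base, s, e) in enumerate(evidence.runs):
        if e <= address_len:
            continue
        vc = evidence.votes[r]
        if len(vc) < 2:
            continue
        ordered = vc.most_common(2)
        if ordered[1][1] >= 0.4 * ordered[0][1] and ordered[1][1] >= 3:
            sites.append(s)
    sites.extend([address_len + 1, n - 1])  # terminal windows
    sites = sorted(set(sites))
    # merge nearby sites into windows, capped so that a dense stretch of
    # anomalies becomes several medium windows instead of one huge one
    # (the mini-consensus quality degrades with window length)
    max_width = 2 * pad + 10
    windows: list[list[int]] = []
    for p in sites:
        # windows may reach into the (trusted, well-anchored) address so a
        # repeat straddling the seam cannot scramble segment extraction;
        # the caller re-pins the address afterwards
        a, b = max(0, p - pad), min(n, p + pad)
        if windows and a <= windows[-1][1] and b - windows[-1][0] <= max_width:
            windows[-1][1] = max(windows[-1][1], b)
        else:
            windows.append([a, b])
    flags: list[str] = []
    out: list[str] = []
    prev = 0
    for a, b in windows:
        if a < prev:
            a = prev
        if b - a < 4:
            continue
        terminal = b >= n - 1
        segments: list[str] = []
        for read, ops, (cs, ce) in zip(reads, evidence.ops_list, evidence.cores):
            if ce - cs == 0:
                continue
            if terminal and ce >= a + 4:
                seg = _read_segment_to_end(read.bases, ops, a)
                if seg:
                    segments.append(seg)
            elif cs <= a and ce >= b:
                seg, covered = _read_segment(read.bases, ops, a, b)
                if covered and seg:
                    segments.append(seg)
        if len(segments) < 4:
            continue
        segments = segments[:30]
        k = len(segments)
        dist = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                d = _edlib_distance(segments[i], segments[j])
                dist[i, j] = dist[j, i] = d
        medoid = int(np.argmin(dist.sum(axis=1)))
        others = [segments[i] for i in range(k) if i != medoid]
        mat = star_rows(segments[medoid], others, scoring, band=max(16, band // 4))
        current = est[a:b]
        candidates = {}
        patch = _column_consensus(mat, mat[0] == GAP, insert_frac=0.4)
        if patch:
            candidates["segment consensus"] = patch
        # single-insertion variants: an alignment-ambiguous missing base
        # splits between substitution and insertion interpretations, so
        # neither column voting nor run voting ever commits it -- but an
        # explicit variant comparison does
        for (pos, c), lens in evidence.ins_votes.items():
            cov = int(evidence.pos_cov[pos])
            if a <= pos < b and cov >= 4 and len(lens) >= 0.2 * cov:
                rel = pos - a
                ins = c * _mode_longest(lens)
                candidates[f"insert {ins}@{pos}"] = (
                    current[:rel] + ins + current[rel:]
                )
        if not candidates:
            continue
        cost_cur = sum(_edlib_distance(s, current) for s in segments)
        scored = []
        for name, cand in candidates.items():
            if cand == current:
                continue
            scored.append(
                (sum(_edlib_distance(s, cand) for s in segments), name, cand)
            )
        if not scored:
            continue
        cost_new, name, best = min(scored, key=lambda x: (x[0], x[1]))
        if cost_new + min_gain <= cost_cur:
            flags.append(
                f"micro-repair {a}-{b} ({name}): preferred by reads "
                f"({cost_cur} -> {cost_new} over {k} segments)"
            )
            out.append(est[prev:a])
            out.append(best)
            prev = b
    out.append(est[prev:])
    return "".join(out), flags


def _substitution_sweep(
    est: str, evidence: _Evidence, address_len: int
) -> tuple[str, list[str]]:
    """Replace estimate bases that the aligned reads clearly vote against.

    Run-length voting deliberately counts an interior mismatch as length
    evidence, which means a *systematic* substitution error in the
    estimate (one that merges or splits runs) can survive it; the
    per-position diagonal base tallies expose exactly those sites.
    """
    bv = evidence.base_votes
    n = len(est)
    out = list(est)
    flags = []
    b2i = {"A": 0, "C": 1, "G": 2, "T": 3}
    cov = bv.sum(axis=1)
    top = bv.argmax(axis=1)
    top_cnt = bv.max(axis=1)
    for pos in range(address_len, n):
        if cov[pos] < 6:
            continue
        cur = b2i[est[pos]]
        if (
            top[pos] != cur
            and top_cnt[pos] >= 0.6 * cov[pos]
            and top_cnt[pos] >= 2 * bv[pos, cur]
        ):
            out[pos] = "ACGT"[top[pos]]
            flags.append(f"substitution sweep: {est[pos]}->{out[pos]} at {pos}")
    return "".join(out), flags


def _read_segment_to_end(bases: str, ops: np.ndarray, a: int) -> str:
    """The read suffix aligned to estimate positions >= a (incl. overhang)."""
    ri = ei = 0
    r_a = -1
    for op in ops:
        if op == OP_DIAG:
            if ei == a:
                r_a = ri
            ri += 1
            ei += 1
        elif op == OP_A:
            if ei == a and r_a < 0:
                r_a = ri
            ri += 1
        else:
            if ei == a:
                r_a = ri
            ei += 1
    if r_a < 0:
        return ""
    return bases[r_a:]


def _balance_dp(slots: list[dict]) -> tuple[list[int], int]:
    """Choose one candidate length per slot, balancing every 8-window.

    Exact dynamic program over the tiny state (window phase, partial-window
    GC count): primary objective is the number of unbalanced completed
    windows, secondary is the total length-observation log-likelihood.
    This applies the "majority among balance-preserving lengths" rule
    globally instead of greedily, so a single noisy run cannot
    desynchronize the frame and cascade.
    """
    # state -> (violations, -loglik, backpointer); backpointer =
    # (prev_state, candidate index)
    frontier: dict[tuple[int, int], tuple[int, float, tuple | None]] = {
        (0, 0): (0, 0.0, None)
    }
    trail: list[dict] = []
    for slot in slots:
        is_gc = 1 if slot["base"] in "GC" else 0
        scores = slot.get("scores") or {}
        nxt: dict[tuple[int, int], tuple[int, float, tuple]] = {}
        for state, (viol, negv, _) in frontier.items():
            pos, gc = state
            for ci, cand in enumerate(slot["cands"]):
                bad, p2, g2 = _window_scan(pos, gc, is_gc, cand)
                key = (p2 % WORD_BASES, g2)
                cost = (viol + bad, negv - scores.get(cand, 0.0), (state, ci))
                if key not in nxt or cost[:2] < nxt[key][:2]:
                    nxt[key] = cost
        trail.append({k: v[2] for k, v in nxt.items()})
        frontier = nxt
    end_state = min(frontier, key=lambda k: frontier[k][:2])
    n_viol = frontier[end_state][0]
    choices: list[int] = []
    state = end_state
    for slot, back in zip(reversed(slots), reversed(trail)):
        prev_state, ci = back[state]
        choices.append(slot["cands"][ci])
        state = prev_state
    choices.reverse()
    return choices, n_viol
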