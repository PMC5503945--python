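"""End-to-end encoder/decoder: bytes -> addressed DNA blocks -> bytes.

Layout.  The input byte stream is read MSB-first into a bit stream,
zero-padded to a multiple of 14 bits, and split into groups of
123 x 14 = 1,722 bits (the last group may be shorter, still a multiple of
14).  Each group becomes one DNA block: a 16-base address prefix followed
by one balanced 8-base codeword per 14-bit word -- 984 payload bases and
1,000 bases total for a full block.  A full block therefore carries
1,722 bits in 1,000 bases, a net density of 1.72 bits/base.

Address avoidance.  Before mapping, the bits of a block are whitened by a
deterministic pseudo-random mask keyed by a per-block *salt*; if any
address (or reverse complement) appears inside the encoded block, the salt
is bumped and the block re-encoded, so the emitted FASTA provably contains
each address only at its own block's prefix.

Sidecar.  Everything the decoder needs beyond the DNA itself -- exact bit
length, per-block address, salt, expected length and homopolymer check
syndromes -- travels in a small versioned JSON file, the classical-media
side channel of the scheme.

Decoding runs the consensus pipeline (exact-address demultiplexing with a
near-match rescue for under-covered blocks, multi-preset MSA consensus,
majority-homopolymer aggregation, balance-constrained iterative
polishing), applies the homopolymer check code, strips the address, and
inverts the codeword map and whitening.  Random access decodes one block
while touching only reads that match its address.
"""

from __future__ import annotations

import base64
import json
import sys
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp
from .addresses import Address, generate_addresses, screen_payload
from .align import Scoring
from .balanced import (
    WORD_BASES,
    WORD_BITS,
    BalanceError,
    OutOfCodebookError,
    check_balance,
    decode_codeword,
    encode_bits14,
)
from .channel import Read
from .consensus import (
    DEFAULT_BAND,
    DEFAULT_PRESETS,
    MsaPreset,
    aggregate_majority_homopolymer,
    demultiplex,
    iterative_polish,
    msa_consensus,
    pin_address,
)
from .homopolymer import (
    DecodingFailure,
    HomopolymerCheck,
    StructureError,
    compute_checks,
    correct_lengths,
    correct_lengths_with_total,
    parse_homopolymers,
    repair_run_structure,
)

SIDECAR_VERSION = 1
#: alternate polish scorings tried when a block fails sidecar validation;
#: different tie-breaking shifts alignment-ambiguous attractors
_RETRY_SCORINGS = (Scoring(1, -2, -3, -1), Scoring(3, -5, -6, -3))
BLOCK_WORDS = 123  # 14-bit words per full block
BLOCK_BITS = BLOCK_WORDS * WORD_BITS  # 1,722
ADDRESS_LEN = 16
FULL_BLOCK_LEN = ADDRESS_LEN + BLOCK_WORDS * WORD_BASES  # 1,000


class EncodingError(RuntimeError):
    """No salt within the retry budget yields an address-free block."""


class BlockMissingError(RuntimeError):
    """One or more blocks received zero reads."""

    def __init__(self, addresses: list[str]):
        self.addresses = addresses
        super().__init__(
            "no reads assigned to block address(es): " + ", ".join(addresses)
        )


@dataclass(frozen=True)
class CodecConfig:
    """Tunables of the encode/decode pipeline (defaults match a 1 kb layout)."""

    block_words: int = BLOCK_WORDS
    address_len: int = ADDRESS_LEN
    ecc_t: int = 3
    presets: tuple[MsaPreset, ...] = DEFAULT_PRESETS
    msa_cap: int = 15
    band: int = DEFAULT_BAND
    max_iters: int = 5
    min_hq_reads: int = 3  # below this, near-match address rescue kicks in
    rescue_max_edits: int = 3
    rescue_margin: int = 2
    salt_tries: int = 256


@dataclass
class Block:
    index: int
    address: Address
    payload: str
    salt: int
    check: HomopolymerCheck
    n_bits: int

    @property
    def sequence(self) -> str:
        return self.address.bases + self.payload


@dataclass
class BlockReport:
    index: int
    address: str
    n_exact_reads: int = 0
    n_polish_reads: int = 0
    iterations: int = 0
    pre_ecc: str = ""
    post_ecc: str = ""
    flags: list[str] = field(default_factory=list)  # unresolved problems
    notes: list[str] = field(default_factory=list)  # repairs that succeeded


@dataclass
class DecodeResult:
    data: bytes
    blocks: list[BlockReport]

    @property
    def ok(self) -> bool:
        return not any(b.flags for b in self.blocks)


# ---------------------------------------------------------------------------
# bit plumbing

def bytes_to_bits(data: bytes) -> np.ndarray:
    return np.unpackbits(np.frombuffer(data, np.uint8))


def bits_to_bytes(bits: np.ndarray, bit_length: int) -> bytes:
    bits = bits[:bit_length]
    return np.packbits(bits).tobytes()[: (bit_length + 7) // 8]


def _whiten(bits: np.ndarray, salt: int) -> np.ndarray:
    mask = np.random.Generator(np.random.PCG64(salt)).integers(
        0, 2, bits.size, dtype=np.uint8
    )
    return bits ^ mask


def _bits_to_words(bits: np.ndarray) -> np.ndarray:
    assert bits.size % WORD_BITS == 0
    weights = 1 << np.arange(WORD_BITS - 1, -1, -1)
    return bits.reshape(-1, WORD_BITS) @ weights


def _words_to_bits(words: list[int]) -> np.ndarray:
    out = np.zeros(len(words) * WORD_BITS, np.uint8)
    for i, w in enumerate(words):
        for j in range(WORD_BITS):
            out[i * WORD_BITS + j] = (w >> (WORD_BITS - 1 - j)) & 1
    return out


# ---------------------------------------------------------------------------
# encoding

def encode_payload(
    bits: np.ndarray,
    addresses: list[Address],
    salt: int = 0,
    prefix_address: Address | None = None,
    max_tries: int = 256,
) -> tuple[str, int]:
    """Whiten, map to balanced codewords, and retry salts until address-free.

    Returns ``(payload, salt_used)``.  When ``prefix_address`` is given the
    screen also covers the address/payload seam and requires the address
    set to occur exactly once, at the block's own prefix.
    """
    if bits.size % WORD_BITS:
        raise ValueError("bit group length must be divisible by 14")
    for attempt in range(max_tries):
        s = salt + attempt
        words = _bits_to_words(_whiten(bits, s))
        payload = "".join(encode_bits14(int(w)) for w in words)
        if prefix_address is None:
            hits = screen_payload(payload, addresses)
            clean = not hits
        else:
            hits = screen_payload(prefix_address.bases + payload, addresses)
            clean = hits == [(prefix_address.index, 0)]
        if clean:
            return payload, s
    raise EncodingError(f"no clean salt in {max_tries} tries (starting at {salt})")


def encode_file(data: bytes, config: CodecConfig = CodecConfig()) -> list[Block]:
    """Encode a byte stream into addressed, balanced, address-free DNA blocks."""
    if not data:
        raise ValueError("input must be non-empty")
    bits = bytes_to_bits(data)
    n_bits = bits.size
    pad = (-n_bits) % WORD_BITS
    bits = np.concatenate([bits, np.zeros(pad, np.uint8)])
    block_bits = config.block_words * WORD_BITS
    n_blocks = (bits.size + block_bits - 1) // block_bits
    addresses = generate_addresses(n_blocks)
    blocks: list[Block] = []
    for b in range(n_blocks):
        group = bits[b * block_bits : (b + 1) * block_bits]
        payload, salt = encode_payload(
            group, addresses, prefix_address=addresses[b], max_tries=config.salt_tries
        )
        seq = addresses[b].bases + payload
        assert not check_balance(seq)
        check = compute_checks(parse_homopolymers(seq), t=config.ecc_t)
        blocks.append(
            Block(
                index=b,
                address=addresses[b],
                payload=payload,
                salt=salt,
                check=check,
                n_bits=group.size,
            )
        )
    return blocks


def make_sidecar(blocks: list[Block], bit_length: int) -> dict:
    return {
        "version": SIDECAR_VERSION,
        "bit_length": bit_length,
        "word_bits": WORD_BITS,
        "block_words": BLOCK_WORDS,
        "address_len": ADDRESS_LEN,
        "blocks": [
            {
                "index": b.index,
                "address": b.address.bases,
                "salt": b.salt,
                "length": len(b.sequence),
                "n_bits": b.n_bits,
                "check": {
                    "t": b.check.t,
                    "run_count": b.check.run_count,
                    "prime": b.check.prime,
                    "syndromes": list(b.check.syndromes),
                },
            }
            for b in blocks
        ],
    }


def encode_to_files(
    data: bytes,
    fasta_path: str,
    sidecar_path: str,
    config: CodecConfig = CodecConfig(),
) -> list[Block]:
    blocks = encode_file(data, config)
    write_blocks_fasta(blocks, fasta_path)
    with open(sidecar_path, "w") as fh:
        json.dump(make_sidecar(blocks, len(data) * 8), fh, indent=1)
    return blocks


# ---------------------------------------------------------------------------
# FASTA / FASTQ / sidecar I/O

def write_blocks_fasta(blocks: list[Block], path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(b.sequence),
            id=f"block{b.index:03d}",
            description=f"addr={b.address.bases} salt={b.salt}",
        )
        for b in blocks
    ]
    SeqIO.write(records, path, "fasta")


def read_sequences_fasta(path: str) -> list[str]:
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(path, "fasta")]


def write_fastq(reads: list[Read], path: str, truth_tsv: str | None = None) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [20] * len(r.bases)
        records.append(rec)
    SeqIO.write(records, path, "fastq")
    if truth_tsv is not None:
        with open(truth_tsv, "w") as fh:
            fh.write("read_id\tsource_block\tis_reverse\n")
            for r in reads:
                fh.write(f"{r.id}\t{r.source_block}\t{int(r.is_reverse)}\n")


def read_fastq(path: str, truth_tsv: str | None = None) -> list[Read]:
    from Bio import SeqIO

    labels: dict[str, tuple[int, bool]] = {}
    if truth_tsv is not None:
        with open(truth_tsv) as fh:
            next(fh)
            for line in fh:
                rid, blk, rev = line.rstrip("\n").split("\t")
                labels[rid] = (int(blk), bool(int(rev)))
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        blk, rev = labels.get(rec.id, (None, False))
        reads.append(Read(str(rec.seq), rec.id, blk, rev))
    return reads


def read_sidecar(path: str) -> dict:
    with open(path) as fh:
        sidecar = json.load(fh)
    if sidecar.get("version") != SIDECAR_VERSION:
        raise ValueError(f"unsupported sidecar version {sidecar.get('version')}")
    return sidecar


# ---------------------------------------------------------------------------
# decoding

def _sidecar_addresses(sidecar: dict) -> list[Address]:
    return [Address(b["address"], b["index"]) for b in sidecar["blocks"]]


def _sidecar_check(entry: dict) -> HomopolymerCheck:
    c = entry["check"]
    return HomopolymerCheck(
        t=c["t"],
        run_count=c["run_count"],
        syndromes=tuple(c["syndromes"]),
        prime=c["prime"],
    )


def _approx_assign(
    reads: list[Read],
    addresses: list[Address],
    max_edits: int,
    margin: int,
) -> dict[int, list[Read]]:
    """Near-match address assignment (infix edit distance, unique best).

    Rescues reads whose address region carries a few sequencing errors;
    requires the best address to beat the runner-up by ``margin`` edits.
    """
    import edlib

    out: dict[int, list[Read]] = {a.index: [] for a in addresses}
    cutoff = max_edits + margin
    for read in reads:
        rc = revcomp(read.bases)
        per_addr: list[tuple[int, int, bool]] = []  # (distance, index, fwd)
        for a in addresses:
            d_best, fwd_best = cutoff + 1, True
            for seq, fwd in ((read.bases, True), (rc, False)):
                d = edlib.align(a.bases, seq, mode="HW", task="distance",
                                k=cutoff)["editDistance"]
                if d != -1 and d < d_best:
                    d_best, fwd_best = d, fwd
            per_addr.append((d_best, a.index, fwd_best))
        per_addr.sort()
        d, idx, fwd = per_addr[0]
        second = per_addr[1][0] if len(per_addr) > 1 else cutoff + 1
        if d <= max_edits and second - d >= margin:
            bases = read.bases if fwd else rc
            out[idx].append(
                Read(bases, read.id, read.source_block,
                     read.is_reverse if fwd else not read.is_reverse,
                     read.true_ops)
            )
    return out


def _decode_block_estimate(
    estimate: str,
    entry: dict,
    config: CodecConfig,
    report: BlockReport,
    reads: list[Read] | None = None,
) -> np.ndarray:
    """Homopolymer ECC + codeword inversion for one polished estimate."""
    check = _sidecar_check(entry)
    expected_len = entry["length"]
    corrected = estimate
    profile = parse_homopolymers(estimate)

    def _rank_by_reads(candidates):
        # syndrome- and constraint-equivalent repairs differ in where a
        # run sits; the reads have no trouble telling those apart
        import edlib

        pool_r = (reads or [])[:30]
        report.notes.append(
            f"homopolymer ECC: {len(candidates)} equivalent repairs, "
            "ranked by read support"
        )
        return min(
            candidates,
            key=lambda c: sum(
                edlib.align(r.bases, c.expand(), mode="NW")["editDistance"]
                for r in pool_r
            ),
        )

    rank = _rank_by_reads if reads else None

    def _dna_valid(candidate) -> bool:
        # the length code is blind to run symbols; window balance and
        # codebook membership discriminate between syndrome-equivalent fixes
        seq = candidate.expand()
        if len(seq) != expected_len or check_balance(seq):
            return False
        payload = seq[config.address_len :]
        for w in range(entry["n_bits"] // WORD_BITS):
            try:
                decode_codeword(payload[w * WORD_BASES : (w + 1) * WORD_BASES])
            except (BalanceError, OutOfCodebookError):
                return False
        return True

    try:
        if profile.run_count == check.run_count:
            fixed = correct_lengths(profile, check)
            if len(fixed.expand()) != expected_len:
                # the one-sided reconstruction disagrees with the known
                # block length: re-resolve the decoded pattern's signs
                fixed = correct_lengths_with_total(
                    profile, check, expected_len, validate=_dna_valid, rank=rank
                )
                report.notes.append("homopolymer ECC: mixed-sign correction")
            corrected = fixed.expand()
        else:
            fixed = repair_run_structure(
                profile, check, expected_len, validate=_dna_valid, rank=rank
            )
            corrected = fixed.expand()
            report.notes.append(
                "homopolymer ECC: structural repair "
                f"(run count was off by {check.run_count - profile.run_count})"
            )
    except StructureError as exc:
        report.flags.append(f"homopolymer structure: {exc}")
    except DecodingFailure as exc:
        report.flags.append(f"homopolymer ECC: {exc}")
    if len(corrected) != expected_len:
        report.flags.append(
            f"length {len(corrected)} != expected {expected_len}"
        )
    report.post_ecc = corrected
    payload = corrected[config.address_len :]
    n_words = entry["n_bits"] // WORD_BITS
    words = []
    for w in range(n_words):
        cw = payload[w * WORD_BASES : (w + 1) * WORD_BASES]
        try:
            words.append(decode_codeword(cw))
        except (BalanceError, OutOfCodebookError):
            report.flags.append(f"codeword {w}: undecodable ({cw!r})")
            words.append(0)
    bits = _whiten(_words_to_bits(words), entry["salt"])
    return bits


def _phase1_estimate(
    reads: list[Read], entry: dict, config: CodecConfig, report: BlockReport
) -> str:
    consensuses = []
    for preset in config.presets:
        consensuses.append(
            msa_consensus(reads, preset, cap=config.msa_cap, band=config.band)
        )
    distinct = sorted(set(consensuses))
    if len(distinct) >= 2:
        agg = aggregate_majority_homopolymer(consensuses, band=config.band)
    else:
        agg = consensuses[0]
    return pin_address(agg, entry["address"], report.flags)


def _reassign_by_estimate(
    reads: list[Read],
    estimates: dict[int, str],
    max_frac: float = 0.40,
    margin: int = 30,
) -> dict[int, list[Read]]:
    """Match reads to block estimates by whole-read edit distance.

    The analogue of the extra whole-pool alignment round: reads whose
    address region was too corrupted for demultiplexing usually still
    identify their block unambiguously over their full length.  A read is
    assigned to the nearest estimate (either strand) when the distance is
    plausible for a sequencing read and beats the runner-up block by
    ``margin`` edits.
    """
    import edlib

    out: dict[int, list[Read]] = {idx: [] for idx in estimates}
    for read in reads:
        rc = revcomp(read.bases)
        best = (10**9, -1, True)
        second = 10**9
        k = 10**9
        for idx, est in estimates.items():
            for seq, fwd in ((read.bases, True), (rc, False)):
                d = edlib.align(seq, est, mode="NW", task="distance",
                                k=min(k, int(0.6 * len(est))))["editDistance"]
                if d == -1:
                    continue
                if d < best[0]:
                    if best[1] != idx:
                        second = best[0]
                    best = (d, idx, fwd)
                elif idx != best[1] and d < second:
                    second = d
            k = second + margin  # no better candidate can matter beyond this
        d, idx, fwd = best
        if idx >= 0 and d <= max_frac * len(estimates[idx]) and second - d >= margin:
            out[idx].append(
                Read(read.bases if fwd else rc, read.id, read.source_block,
                     read.is_reverse if fwd else not read.is_reverse,
                     read.true_ops)
            )
    return out


def decode_file(
    pool: list[Read],
    sidecar: dict,
    config: CodecConfig = CodecConfig(),
    progress: bool = False,
) -> DecodeResult:
    """Full decode: read pool + sidecar -> original bytes + per-block report."""
    addresses = _sidecar_addresses(sidecar)
    assigned, leftovers = demultiplex(pool, addresses)
    rescued = _approx_assign(
        leftovers, addresses, config.rescue_max_edits, config.rescue_margin
    )
    missing = [
        a.bases
        for a in addresses
        if not assigned[a.index] and not rescued[a.index]
    ]
    if missing:
        raise BlockMissingError(missing)

    # phase 1: rough per-block estimates from address-identified reads
    estimates: dict[int, str] = {}
    reports: list[BlockReport] = []
    for entry in sidecar["blocks"]:
        idx = entry["index"]
        report = BlockReport(index=idx, address=entry["address"])
        report.n_exact_reads = len(assigned[idx])
        hq = assigned[idx] + rescued[idx]
        estimates[idx] = _phase1_estimate(hq, entry, config, report)
        reports.append(report)

    # extra alignment round: match the remaining reads to the estimates
    rescued_ids = {r.id for lst in rescued.values() for r in lst}
    unmatched = [r for r in leftovers if r.id not in rescued_ids]
    extra = _reassign_by_estimate(unmatched, estimates)

    # phase 2: balance-constrained polishing, ECC, codeword inversion
    all_bits: list[np.ndarray] = []
    for entry, report in zip(sidecar["blocks"], reports):
        idx = entry["index"]
        polish_reads = assigned[idx] + rescued[idx] + extra[idx]
        report.n_polish_reads = len(polish_reads)
        polished = iterative_polish(
            estimates[idx],
            polish_reads,
            address_len=config.address_len,
            max_iters=config.max_iters,
            band=config.band,
        )
        report.iterations = polished.iteration
        report.pre_ecc = polished.bases
        report.notes.extend(polished.flags)
        bits_b = _decode_block_estimate(
            polished.bases, entry, config, report, polish_reads
        )
        if report.flags:
            # the sidecar validation (syndromes, balance, codebook) is a
            # near-certain oracle, so retrying the polish under alternate
            # scoring is safe: a wrong retry cannot validate, and a clean
            # one replaces the flagged result
            for alt in _RETRY_SCORINGS:
                retry_report = BlockReport(index=idx, address=entry["address"])
                retried = iterative_polish(
                    estimates[idx],
                    polish_reads,
                    address_len=config.address_len,
                    max_iters=config.max_iters,
                    band=config.band,
                    scoring=alt,
                )
                retry_bits = _decode_block_estimate(
                    retried.bases, entry, config, retry_report, polish_reads
                )
                if not retry_report.flags:
                    report.notes.append(
                        f"retry with scoring {alt} validated cleanly"
                    )
                    report.notes.extend(retry_report.notes)
                    report.flags = []
                    report.pre_ecc = retried.bases
                    report.post_ecc = retry_report.post_ecc
                    bits_b = retry_bits
                    break
        all_bits.append(bits_b)
        if progress:
            print(
                f"block {idx}: {report.n_exact_reads} exact reads, "
                f"{report.n_polish_reads} polished, "
                f"{polished.iteration} iteration(s), "
                f"{len(report.flags)} flag(s)",
                file=sys.stderr,
            )
    bits = np.concatenate(all_bits)
    data = bits_to_bytes(bits, sidecar["bit_length"])
    return DecodeResult(data=data, blocks=reports)


def random_access_decode(
    pool: list[Read],
    address: Address | str,
    sidecar: dict,
    config: CodecConfig = CodecConfig(),
) -> tuple[bytes, dict]:
    """Decode a single block selected by its address.

    Only reads matching the requested address (exactly, or by near-match
    rescue if too few) are ever used; the returned metadata reports the
    number of reads touched plus the block's bit framing so the caller can
    splice the bytes into the file.
    """
    bases = address.bases if isinstance(address, Address) else address
    entry = next(
        (e for e in sidecar["blocks"] if e["address"] == bases), None
    )
    if entry is None:
        raise KeyError(f"address {bases} not present in sidecar")
    addr = Address(bases, entry["index"])
    assigned, leftovers = demultiplex(pool, [addr])
    hq = assigned[addr.index]
    # single-address rescue must stay strict: without competing addresses
    # to enforce a margin, a loose edit threshold would pull in chance
    # matches from other blocks' reads.  Two edits in 16 bases is far
    # below what random 1 kb sequence produces.
    rescued = _approx_assign(leftovers, [addr], 2, margin=1)[addr.index]
    if not hq and not rescued:
        raise BlockMissingError([bases])
    report = BlockReport(index=entry["index"], address=bases)
    report.n_exact_reads = len(hq)
    est = _phase1_estimate(hq if len(hq) >= config.min_hq_reads else hq + rescued,
                           entry, config, report)
    polish_reads = hq + rescued
    report.n_polish_reads = len(polish_reads)
    polished = iterative_polish(
        est, polish_reads, address_len=config.address_len,
        max_iters=config.max_iters, band=config.band,
    )
    report.pre_ecc = polished.bases
    report.notes.extend(polished.flags)
    bits = _decode_block_estimate(
        polished.bases, entry, config, report, polish_reads
    )
    bit_offset = sum(e["n_bits"] for e in sidecar["blocks"] if e["index"] < entry["index"])
    meta = {
        "block_index": entry["index"],
        "bit_offset": bit_offset,
        "n_bits": entry["n_bits"],
        "reads_used": len(polish_reads),
        "flags": report.flags,
    }
    return bits_to_bytes(bits, entry["n_bits"]), meta


# ---------------------------------------------------------------------------
# workflow-parity helpers

def to_base64(data: bytes) -> bytes:
    """Base64 helper for parity with image->text workflows; nothing more."""
    return base64.b64encode(data)


def from_base64(text: bytes | str) -> bytes:
    return base64.b64decode(text)
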