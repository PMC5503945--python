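"""Homopolymer run-length parsing and limited-magnitude error correction.

Nanopore consensus sequences exhibit a highly structured residual error:
maximal runs of identical bases ("homopolymers") come out *shortened*, by
one or two bases, while the sequence of run symbols survives.  Parsing a
sequence into runs -- e.g. ``AATCCCGA -> (A,T,C,G,A)`` with lengths
``(2,1,3,1,1)`` -- turns those errors into asymmetric, bounded-magnitude
substitutions on the integer length sequence: an observed length ``l'``
satisfies ``l' = l - s`` with ``s`` in ``{0, 1, 2}``.

With shortening magnitude at most ``L = 2``, the residues ``l mod (L+1) =
l mod 3`` determine the shortening uniquely, so protecting the residue
vector with any t-error-correcting code yields a *homopolymer check code*
that repairs up to ``t`` shortened runs exactly, and the correction can
only ever lengthen runs.  The check layer here is a Reed-Solomon-style
syndrome code over the prime field GF(1009): for runs ``i = 0..n-1`` with
residues ``r_i`` the stored checks are

    S_j = sum_i r_i * (i+1)^j  (mod 1009),   j = 1..2t.

Any 2t columns of this Vandermonde system are linearly independent, so
error patterns of weight <= t have distinct syndromes and decoding (a
small combinatorial search over candidate positions, each position having
only two possible residue corrections) is exact.  The redundancy is
2t field symbols -- a few dozen bits per kilobase block, independent of
payload size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

PRIME = 1009
MAX_SHORTENING = 2  # magnitude bound L; residues are taken mod L+1 = 3
MOD = MAX_SHORTENING + 1


class StructureError(ValueError):
    """Observed run count differs from the check's run count.

    This signals a consensus failure upstream (a run was lost or invented),
    which the limited-magnitude code does not cover.
    """


class DecodingFailure(ValueError):
    """No error pattern of weight <= t explains the observed syndrome."""


@dataclass(frozen=True)
class HomopolymerProfile:
    """Maximal-run parse of a DNA sequence: symbols and their run lengths."""

    symbols: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.lengths):
            raise ValueError("symbols and lengths must have equal arity")
        if any(l < 1 for l in self.lengths):
            raise ValueError("all run lengths must be >= 1")
        if any(a == b for a, b in zip(self.symbols, self.symbols[1:])):
            raise ValueError("adjacent run symbols must differ")

    @property
    def run_count(self) -> int:
        return len(self.symbols)

    def expand(self) -> str:
        """The sequence this profile parses; inverse of parse_homopolymers."""
        return "".join(s * l for s, l in zip(self.symbols, self.lengths))


@dataclass(frozen=True)
class HomopolymerCheck:
    """Stored redundancy for a profile: 2t syndromes over GF(1009)."""

    t: int
    run_count: int
    syndromes: tuple[int, ...]
    prime: int = PRIME

    def __post_init__(self) -> None:
        if len(self.syndromes) != 2 * self.t:
            raise ValueError("expected 2t syndromes")


def parse_homopolymers(seq: str) -> HomopolymerProfile:
    """Parse a sequence into maximal homopolymer runs.

    ``AATCCCGA`` parses to symbols ``(A,T,C,G,A)`` with lengths
    ``(2,1,3,1,1)``.
    """
    if not seq:
        raise ValueError("cannot parse an empty sequence")
    symbols, lengths = [], []
    for base, grp in itertools.groupby(seq):
        symbols.append(base)
        lengths.append(sum(1 for _ in grp))
    return HomopolymerProfile(tuple(symbols), tuple(lengths))


def _syndromes(residues: list[int], t: int, prime: int = PRIME) -> tuple[int, ...]:
    out = []
    for j in range(1, 2 * t + 1):
        s = 0
        for i, r in enumerate(residues):
            if r:
                s = (s + r * pow(i + 1, j, prime)) % prime
        out.append(s)
    return tuple(out)


def compute_checks(profile: HomopolymerProfile, t: int = 3) -> HomopolymerCheck:
    """Syndromes of the profile's mod-3 residue vector.

    Checks depend on lengths only, never on the run symbols.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    n = profile.run_count
    if n >= PRIME:
        raise ValueError(f"run count {n} exceeds field capacity {PRIME - 1}")
    residues = [l % MOD for l in profile.lengths]
    return HomopolymerCheck(t=t, run_count=n, syndromes=_syndromes(residues, t))


def residues_of(profile: HomopolymerProfile) -> tuple[int, ...]:
    return tuple(l % MOD for l in profile.lengths)


def _allowed_deltas(r_obs: int) -> tuple[int, ...]:
    # true residue must lie in {0,1,2} and differ from the observed one
    return tuple(r - r_obs for r in range(MOD) if r != r_obs)


from functools import lru_cache


@lru_cache(maxsize=65536)
def _delta_syndrome(pos: int, delta: int, t: int, prime: int = PRIME) -> tuple[int, ...]:
    return tuple((delta * pow(pos + 1, j, prime)) % prime for j in range(1, 2 * t + 1))


def _search_error_pattern(
    target: tuple[int, ...], r_obs: list[int], t: int, max_weight: int | None = None
) -> dict[int, int] | None:
    """Find positions/deltas of weight <= t whose syndrome equals ``target``.

    Unique within weight t by the Vandermonde argument, so the first hit is
    the answer.  Each position admits only two candidate deltas (the true
    residue is one of the other two values mod 3).
    """
    prime = PRIME
    n = len(r_obs)
    w_cap = t if max_weight is None else min(t, max_weight)
    if all(s == 0 for s in target):
        return {}
    singles: dict[tuple[int, ...], tuple[int, int]] = {}
    for i in range(n):
        for d in _allowed_deltas(r_obs[i]):
            singles[_delta_syndrome(i, d, t)] = (i, d)
    hit = singles.get(target)
    if hit is not None:
        return {hit[0]: hit[1]}
    if w_cap < 2:
        return None
    # weight 2: one explicit position + dictionary lookup for the other
    for i in range(n):
        for d in _allowed_deltas(r_obs[i]):
            s1 = _delta_syndrome(i, d, t)
            rest = tuple((a - b) % prime for a, b in zip(target, s1))
            hit = singles.get(rest)
            if hit is not None and hit[0] > i:
                return {i: d, hit[0]: hit[1]}
    if w_cap < 3:
        return None
    # weight 3..t: enumerate (w-1)-subsets and close with the dictionary
    for w in range(3, w_cap + 1):
        for combo in itertools.combinations(range(n), w - 1):
            delta_sets = [_allowed_deltas(r_obs[i]) for i in combo]
            for deltas in itertools.product(*delta_sets):
                acc = [0] * (2 * t)
                for i, d in zip(combo, deltas):
                    s = _delta_syndrome(i, d, t)
                    acc = [(a + b) % prime for a, b in zip(acc, s)]
                rest = tuple((a - b) % prime for a, b in zip(target, acc))
                hit = singles.get(rest)
                if hit is not None and hit[0] > combo[-1]:
                    out = dict(zip(combo, deltas))
                    out[hit[0]] = hit[1]
                    return out
    return None


def _decode_pattern(
    observed: HomopolymerProfile,
    check: HomopolymerCheck,
    max_weight: int | None = None,
) -> dict[int, int]:
    if observed.run_count != check.run_count:
        raise StructureError(
            f"observed {observed.run_count} runs but check expects {check.run_count}"
        )
    r_obs = [l % MOD for l in observed.lengths]
    s_obs = _syndromes(r_obs, check.t, check.prime)
    target = tuple((a - b) % check.prime for a, b in zip(check.syndromes, s_obs))
    pattern = _search_error_pattern(target, r_obs, check.t, max_weight)
    if pattern is None:
        raise DecodingFailure(
            f"no error pattern of weight <= {check.t} matches the syndrome"
        )
    return pattern


def correct_lengths(
    observed: HomopolymerProfile, check: HomopolymerCheck
) -> HomopolymerProfile:
    """Restore run lengths shortened by at most 2 in at most ``t`` runs.

    Decodes the residue vector against the stored syndromes, then applies
    ``length += (r_corrected - length) mod 3``; increments are always in
    {0, 1, 2}, so a correction never shortens a run.
    """
    pattern = _decode_pattern(observed, check)
    r_obs = [l % MOD for l in observed.lengths]
    new_lengths = list(observed.lengths)
    for i, d in pattern.items():
        r_true = r_obs[i] + d
        inc = (r_true - observed.lengths[i]) % MOD
        new_lengths[i] += inc
    return HomopolymerProfile(observed.symbols, tuple(new_lengths))


def correct_lengths_with_total(
    observed: HomopolymerProfile,
    check: HomopolymerCheck,
    total_length: int,
    max_weight: int | None = None,
    validate=None,
    rank=None,
) -> HomopolymerProfile:
    """Length correction that may also *shorten* runs, using the known total.

    The residue decode determines each erroneous run's true length only up
    to a multiple of 3, and the pure asymmetric reconstruction always picks
    the lengthening option.  When the decoder additionally knows the exact
    block length (it does: the sidecar records it), the sign ambiguity is
    resolved by requiring the corrected lengths to sum to that total.  This
    covers mixed error patterns such as a base transposed between two
    nearby runs (one run short by one, another long by one), which the
    one-sided code alone cannot repair.

    ``validate``, if given, is called with each candidate profile and must
    return True to accept it; the caller can thereby impose constraints
    the length code cannot see (window balance, codeword membership).
    """
    cands = _total_candidates(observed, check, total_length, max_weight, validate)
    if not cands:
        raise DecodingFailure(
            "no sign assignment of the decoded pattern matches the block length"
        )
    if len(cands) > 1 and rank is not None:
        return rank(cands)
    return cands[0]


def _total_candidates(
    observed: HomopolymerProfile,
    check: HomopolymerCheck,
    total_length: int,
    max_weight: int | None = None,
    validate=None,
    cap: int = 8,
) -> list[HomopolymerProfile]:
    import itertools as _it

    pattern = _decode_pattern(observed, check, max_weight)
    r_obs = [l % MOD for l in observed.lengths]
    positions = sorted(pattern)
    options: list[list[int]] = []
    for i in positions:
        r_true = r_obs[i] + pattern[i]
        inc = (r_true - observed.lengths[i]) % MOD
        opts = [inc]
        if observed.lengths[i] + inc - MOD >= 1:
            opts.append(inc - MOD)
        options.append(opts)
    need = total_length - sum(observed.lengths)
    out: list[HomopolymerProfile] = []
    for combo in _it.product(*options):
        if sum(combo) != need:
            continue
        new_lengths = list(observed.lengths)
        for i, inc in zip(positions, combo):
            new_lengths[i] += inc
        fixed = HomopolymerProfile(observed.symbols, tuple(new_lengths))
        if validate is None or validate(fixed):
            out.append(fixed)
            if len(out) >= cap:
                break
    return out


def _structure_variants(observed: HomopolymerProfile, delta: int):
    """Candidate profiles with ``delta`` more runs than observed.

    delta +1: re-insert a vanished length-1 run at a boundary between two
    different-base runs; +2: re-insert a length-1 run inside an existing
    run (splitting it); -1: drop a spurious length-1 run between
    different-base neighbours; -2: drop a spurious length-1 run between
    same-base neighbours (merging them).
    """
    syms = list(observed.symbols)
    lens = list(observed.lengths)
    n = len(syms)
    bases = "ACGT"
    if delta == 1:
        for k in range(n + 1):
            left = syms[k - 1] if k > 0 else None
            right = syms[k] if k < n else None
            for c in bases:
                if c == left or c == right:
                    continue
                yield HomopolymerProfile(
                    tuple(syms[:k] + [c] + syms[k:]),
                    tuple(lens[:k] + [1] + lens[k:]),
                )
    elif delta == 2:
        for r in range(n):
            if lens[r] < 2:
                continue
            for cut in range(1, lens[r]):
                for c in bases:
                    if c == syms[r]:
                        continue
                    yield HomopolymerProfile(
                        tuple(syms[:r] + [syms[r], c, syms[r]] + syms[r + 1 :]),
                        tuple(lens[:r] + [cut, 1, lens[r] - cut] + lens[r + 1 :]),
                    )
    elif delta == -1:
        for r in range(1, n - 1):
            if lens[r] == 1 and syms[r - 1] != syms[r + 1]:
                yield HomopolymerProfile(
                    tuple(syms[:r] + syms[r + 1 :]),
                    tuple(lens[:r] + lens[r + 1 :]),
                )
    elif delta == -2:
        for r in range(1, n - 1):
            if lens[r] == 1 and syms[r - 1] == syms[r + 1]:
                yield HomopolymerProfile(
                    tuple(syms[: r - 1] + syms[r + 1 :]),
                    tuple(
                        lens[: r - 1]
                        + [lens[r - 1] + lens[r + 1]]
                        + lens[r + 2 :]
                    ),
                )


def repair_run_structure(
    observed: HomopolymerProfile,
    check: HomopolymerCheck,
    total_length: int,
    validate=None,
    rank=None,
    max_variants: int = 6000,
) -> HomopolymerProfile:
    """Recover from a small run-count mismatch using the syndromes as a seal.

    A consensus occasionally loses or invents one whole run -- an error
    class outside the limited-magnitude code.  The stored syndromes pin
    down the *length* sequence tightly, but they are blind to run symbols,
    so several structural edits can be syndrome-equivalent (e.g. inserting
    a length-1 run anywhere inside a stretch of length-1 runs).  The
    ``validate`` callback therefore carries the discriminating power of
    the DNA-level constraints -- every aligned 8-window balanced, every
    payload codeword inside the codebook -- and only a candidate passing
    both the syndromes and the validator is accepted.
    """
    delta = check.run_count - observed.run_count
    if delta == 0:
        return correct_lengths_with_total(
            observed, check, total_length, validate=validate, rank=rank
        )
    if abs(delta) > 2:
        raise StructureError(
            f"run count off by {delta}; structural repair covers |delta| <= 2"
        )
    candidates: list[HomopolymerProfile] = []
    seen: set[str] = set()
    tried = 0
    for variant in _structure_variants(observed, delta):
        tried += 1
        if tried > max_variants or len(candidates) >= 12:
            break
        try:
            # cap the residual pattern weight: keeps the scan over many
            # wrong variants cheap, and a structural slip plus three
            # independent shortenings in one block is out of scope anyway
            found = _total_candidates(
                variant, check, total_length, max_weight=2, validate=validate, cap=4
            )
        except (DecodingFailure, StructureError):
            continue
        for f in found:
            key = f.expand()
            if key not in seen:
                seen.add(key)
                candidates.append(f)
    if not candidates:
        raise DecodingFailure(
            f"no structural repair (run count off by {delta}) matches the syndrome"
        )
    if len(candidates) > 1 and rank is not None:
        return rank(candidates)
    return candidates[0]
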