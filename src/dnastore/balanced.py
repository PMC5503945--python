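"""The (14 bit -> 8 base) GC-balanced constrained block code.

Every stored DNA payload in this package is a concatenation of 8-base
codewords in which exactly four of the eight bases are G or C.  Balancing
short windows avoids the GC-skewed substrings that cause synthesis failures
and secondary structure, and it caps homopolymer runs: a balanced 8-mer can
contain at most four consecutive bases of the same GC class, so no run
inside a codeword exceeds length 4 and no run in any concatenation of
codewords exceeds 8.

There are C(8,4) * 4^4 = 17,920 balanced 8-mers, so the code can carry
floor(log2 17,920) = 14 bits per codeword -- a coding rate of
log2(17,920)/16 ~= 0.88.  The codebook used here is the 16,384
lexicographically smallest balanced 8-mers (A < C < G < T), which makes the
bit <-> base map canonical and reproducible without any stored table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

from ._seq import gc_count

BASES = "ACGT"
WORD_BITS = 14
WORD_BASES = 8
CODEBOOK_SIZE = 1 << WORD_BITS  # 16,384
BALANCED_8MER_COUNT = 17_920  # C(8,4) * 2^4 * 2^4


class BalanceError(ValueError):
    """A sequence (or window) violates the GC-balance constraint."""


class OutOfCodebookError(ValueError):
    """A balanced 8-mer whose rank falls outside the 2^14-word codebook.

    Seeing this during decoding signals an uncorrected consensus error
    rather than malformed input.
    """


def is_balanced(word: str) -> bool:
    """True iff ``word`` is 8 bases long with exactly four bases in {G, C}."""
    return len(word) == WORD_BASES and gc_count(word) == 4


@lru_cache(maxsize=1)
def enumerate_balanced_8mers() -> tuple[str, ...]:
    """All 17,920 GC-balanced 8-mers in lexicographic order (A<C<G<T)."""
    out = []
    for tup in itertools.product(BASES, repeat=WORD_BASES):
        if sum(c in "GC" for c in tup) == 4:
            out.append("".join(tup))
    return tuple(out)


@dataclass(frozen=True)
class BalancedCodeword:
    """One codebook entry: a balanced 8-mer and its canonical rank."""

    bases: str
    rank: int


class Codebook:
    """Bijection between 14-bit integers and the first 16,384 balanced 8-mers."""

    def __init__(self) -> None:
        self.words: tuple[str, ...] = enumerate_balanced_8mers()[:CODEBOOK_SIZE]
        self._rank = {w: i for i, w in enumerate(self.words)}

    def __len__(self) -> int:
        return len(self.words)

    def word(self, rank: int) -> BalancedCodeword:
        return BalancedCodeword(self.encode(rank), rank)

    def encode(self, value: int) -> str:
        if not 0 <= value < CODEBOOK_SIZE:
            raise ValueError(f"word value {value} outside [0, {CODEBOOK_SIZE})")
        return self.words[value]

    def decode(self, codeword: str) -> int:
        rank = self._rank.get(codeword)
        if rank is not None:
            return rank
        if not is_balanced(codeword):
            raise BalanceError(f"codeword {codeword!r} is not a balanced 8-mer")
        raise OutOfCodebookError(
            f"balanced 8-mer {codeword!r} has rank >= {CODEBOOK_SIZE}"
        )


@lru_cache(maxsize=1)
def default_codebook() -> Codebook:
    return Codebook()


def encode_bits14(value: int) -> str:
    """Map a 14-bit integer to its balanced 8-base codeword."""
    return default_codebook().encode(value)


def decode_codeword(codeword: str) -> int:
    """Inverse of :func:`encode_bits14`.

    Raises :class:`BalanceError` for unbalanced input and
    :class:`OutOfCodebookError` for a balanced 8-mer outside the codebook.
    """
    return default_codebook().decode(codeword)


def check_balance(seq: str, frame_offset: int = 0) -> list[int]:
    """Indices of aligned 8-base windows of ``seq`` whose GC count is not 4.

    Windows are non-overlapping and start at ``frame_offset + 8*i``.  A
    trailing partial window is ignored with a warning.  An empty return
    certifies that the sequence satisfies the balance constraint in the
    given frame.
    """
    if frame_offset < 0 or frame_offset > len(seq):
        raise ValueError("frame_offset outside sequence")
    avail = len(seq) - frame_offset
    if avail % WORD_BASES:
        warnings.warn(
            f"trailing partial window of {avail % WORD_BASES} bases ignored",
            stacklevel=2,
        )
    violations = []
    for i in range(avail // WORD_BASES):
        start = frame_offset + WORD_BASES * i
        if gc_count(seq[start : start + WORD_BASES]) != 4:
            violations.append(i)
    return violations
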