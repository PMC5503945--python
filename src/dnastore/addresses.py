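"""Design of 16-base block addresses.

Each stored DNA block carries a 16-base address prefix that stands in for a
PCR primer: random access selects reads by exact (or near-exact) matches to
this tag.  A useful address set needs three properties at once:

* **GC balance** -- each aligned 8-base half has exactly four G/C bases, so
  an address passes the same balance screen as payload codewords;
* **large mutual Hamming distance** (>= 8 here), so sequencing errors cannot
  convert one address into another;
* **weak correlation** -- no long prefix/suffix self-overlap, which would
  make an address prone to self-priming-like ambiguity, and no appearance
  of any address inside encoded payloads (enforced at encoding time via
  :func:`screen_payload`).

The set is constructed algebraically from two binary component codes rather
than by search.  Both components are the first-order Reed-Muller code
RM(1,4): length 16, 32 codewords, minimum distance 8.  A *GC-pattern* word
``u`` (a weight-8 RM(1,4) codeword whose two 8-bit halves each have weight
4) marks which positions hold G/C; an *identity* word ``v`` (any RM(1,4)
codeword) picks the base within the class::

    (u, v) = (0,0) -> A   (0,1) -> T   (1,0) -> G   (1,1) -> C

If two addresses differ in ``u`` they differ in GC class in >= 8 positions;
if they share ``u`` and differ in ``v`` they differ within the class in
>= 8 positions -- either way the base-level Hamming distance is >= 8.
Candidates whose length->=4 prefix equals their own suffix are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from ._seq import revcomp

ADDRESS_LEN = 16
MIN_DISTANCE = 8
DEFAULT_MAX_SELF_OVERLAP = 3  # forbid prefix==suffix overlaps of length >= 4

_PSI = {(0, 0): "A", (0, 1): "T", (1, 0): "G", (1, 1): "C"}


class CapacityError(ValueError):
    """More addresses requested than the construction can provide."""


@dataclass(frozen=True)
class Address:
    """A 16-base block identifier."""

    bases: str
    index: int

    def __post_init__(self) -> None:
        if len(self.bases) != ADDRESS_LEN:
            raise ValueError("address must be 16 bases")


def _parity(x: int) -> int:
    return bin(x).count("1") & 1


@lru_cache(maxsize=1)
def _rm14() -> tuple[tuple[int, ...], ...]:
    """The 32 codewords of RM(1,4): i -> parity(a & i) ^ c over i = 0..15."""
    words = []
    for a in range(16):
        for c in (0, 1):
            words.append(tuple(_parity(a & i) ^ c for i in range(16)))
    return tuple(words)


@lru_cache(maxsize=1)
def _gc_pattern_words() -> tuple[tuple[int, ...], ...]:
    """Weight-8 RM(1,4) codewords with weight 4 in each aligned half.

    Position ``i`` lies in the first half iff bit 3 of ``i`` is 0, so the
    restriction of ``parity(a & i) ^ c`` to a half is a non-constant affine
    function (weight 4) exactly when ``a`` has support outside bit 3.
    """
    words = []
    for a in range(16):
        if a & 0b0111 == 0:
            continue
        for c in (0, 1):
            words.append(tuple(_parity(a & i) ^ c for i in range(16)))
    return tuple(words)


def correlation_overlap(a: str, b: str) -> int:
    """Largest k >= 1 with suffix_k(a) == prefix_k(b); 0 if none.

    When the two arguments are the same sequence only *proper* overlaps
    (k < len) are considered, which is the autocorrelation screen.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    kmax = min(len(a), len(b))
    if a == b:
        kmax -= 1
    for k in range(kmax, 0, -1):
        if a[-k:] == b[:k]:
            return k
    return 0


@lru_cache(maxsize=8)
def _address_pool(max_self_overlap: int = DEFAULT_MAX_SELF_OVERLAP) -> tuple[str, ...]:
    # besides the autocorrelation screen, reject reverse-complement
    # collisions: an address equal to the RC of an earlier one (or of
    # itself) would make strand-aware demultiplexing and the payload
    # screen ambiguous
    pool: list[str] = []
    chosen: set[str] = set()
    for u in _gc_pattern_words():
        for v in _rm14():
            bases = "".join(_PSI[(u[i], v[i])] for i in range(ADDRESS_LEN))
            if correlation_overlap(bases, bases) > max_self_overlap:
                continue
            rc = revcomp(bases)
            if rc == bases or rc in chosen:
                continue
            pool.append(bases)
            chosen.add(bases)
    return tuple(pool)


def capacity(max_self_overlap: int = DEFAULT_MAX_SELF_OVERLAP) -> int:
    """Number of addresses the construction yields after the overlap screen."""
    return len(_address_pool(max_self_overlap))


def generate_addresses(
    count: int, max_self_overlap: int = DEFAULT_MAX_SELF_OVERLAP
) -> list[Address]:
    """Deterministic list of ``count`` addresses satisfying all invariants."""
    if count < 1:
        raise ValueError("count must be positive")
    pool = _address_pool(max_self_overlap)
    if count > len(pool):
        raise CapacityError(
            f"requested {count} addresses but the construction provides {len(pool)}"
        )
    return [Address(bases, i) for i, bases in enumerate(pool[:count])]


def screen_payload(
    payload: str, addresses: list[Address] | list[str]
) -> list[tuple[int, int]]:
    """All exact occurrences of any address (or its reverse complement).

    Returns ``(address index, position)`` pairs sorted by position; an empty
    list certifies the address-avoidance constraint for ``payload``.
    """
    hits: list[tuple[int, int]] = []
    for idx, addr in enumerate(addresses):
        bases = addr.bases if isinstance(addr, Address) else addr
        aidx = addr.index if isinstance(addr, Address) else idx
        for needle in (bases, revcomp(bases)):
            start = payload.find(needle)
            while start != -1:
                hits.append((aidx, start))
                start = payload.find(needle, start + 1)
    return sorted(set(hits), key=lambda t: (t[1], t[0]))
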