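"""Small sequence utilities shared across the package."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
GC_BASES = frozenset("GC")

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(BASES):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def to_codes(seq: str) -> np.ndarray:
    """Encode A/C/G/T into uint8 codes 0..3; raises on any other symbol."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    if codes.size and codes.max() > 3:
        bad = chr(int(raw[int(np.argmax(codes > 3))]))
        raise ValueError(f"non-ACGT symbol {bad!r} in sequence")
    return codes


def from_codes(codes: np.ndarray) -> str:
    """Inverse of :func:`to_codes`."""
    return _BASE_ARR[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def gc_count(seq: str) -> int:
    return sum(c in GC_BASES for c in seq)
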