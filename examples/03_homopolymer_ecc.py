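"""Homopolymer check codes: repairing shortened runs from tiny redundancy.

Walks through the canonical example: AATCCCGA loses two bases to become
ATCCGA, and the mod-3 residue syndromes restore the original exactly.
"""

from dnastore import compute_checks, correct_lengths, parse_homopolymers

original = parse_homopolymers("AATCCCGA")
print(f"AATCCCGA parses to runs {original.symbols} lengths {original.lengths}")

check = compute_checks(original, t=2)
print(f"stored checks: {2 * check.t} syndromes over GF({check.prime}): "
      f"{check.syndromes}")

observed = parse_homopolymers("ATCCGA")  # two deletions later
print(f"observed ATCCGA has lengths {observed.lengths}")

fixed = correct_lengths(observed, check)
print(f"corrected lengths {fixed.lengths} -> {fixed.expand()}")
# two bounded-magnitude (here -1) run-length errors were repaired using a
# few dozen bits of classical-side redundancy; corrections only lengthen
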