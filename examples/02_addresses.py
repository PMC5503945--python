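"""Block addresses: balanced, far apart, weakly self-correlated.

Generates a set of 16-base addresses from the two-component Reed-Muller
construction and verifies the distance and screening guarantees that make
exact-match demultiplexing (the in-silico PCR) reliable.
"""

import itertools

from dnastore import capacity, correlation_overlap, generate_addresses, screen_payload

addrs = generate_addresses(17)
print(f"construction capacity: {capacity()} addresses")
print(f"first address:  {addrs[0].bases}")

dmin = min(
    sum(x != y for x, y in zip(a.bases, b.bases))
    for a, b in itertools.combinations(addrs, 2)
)
print(f"minimum pairwise Hamming distance over 17 addresses: {dmin}")
print(f"worst self-overlap (suffix == prefix): "
      f"{max(correlation_overlap(a.bases, a.bases) for a in addrs)}")

payload = "ACGT" * 50 + addrs[3].bases + "TGCA" * 50
hits = screen_payload(payload, addrs)
print(f"screen finds the planted copy of address 3: {hits}")
# the encoder retries its whitening salt until this screen comes back empty
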