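"""The GC-balanced constrained code: 14 bits in, one 8-base codeword out.

Builds the canonical codebook, encodes a couple of values, and verifies
the balance property that every stored window obeys.
"""

import math

from dnastore import check_balance, decode_codeword, encode_bits14, enumerate_balanced_8mers

words = enumerate_balanced_8mers()
print(f"balanced 8-mers: {len(words)}  (C(8,4) * 4^4)")
print(f"coding rate:     {math.log2(len(words)) / 16:.2f} bits per base-pair slot")
print(f"codeword for 0:      {encode_bits14(0)}")
print(f"codeword for 16383:  {encode_bits14(16383)}")
print(f"decode roundtrip ok: {decode_codeword(encode_bits14(12345)) == 12345}")

payload = encode_bits14(1) + encode_bits14(9000) + encode_bits14(16000)
print(f"window balance violations in a 3-codeword payload: {check_balance(payload)}")
# every 8-base window of any codeword concatenation holds exactly 4 G/C,
# which is what keeps synthesis stable and homopolymers short
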