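# dnastore

A random-access DNA data storage codec built for error-prone, portable
(nanopore-class) readout. `dnastore` turns a byte stream into addressed,
synthesis-friendly 1 kb DNA blocks, simulates MinION-like noisy reads of
them, and decodes the pool back to the original bytes — error-free — by
combining multiple-alignment consensus, GC-balance-constrained polishing
and a purpose-built error-correcting code on homopolymer run lengths.

It is intended for researchers prototyping DNA storage pipelines: the
encoder/decoder, the channel model and every intermediate stage are
importable library functions, with a thin CLI for file-level workflows.

## The system in brief

* **Constrained encoding.** 14-bit groups map to 8-base codewords with
  exactly four G/C bases each (16,384 of the 17,920 balanced 8-mers; rate
  log₂17,920/16 ≈ 0.88). A full block is 123 codewords = 1,722 bits in
  984 bases behind a 16-base address — 1,000 bp storing 1.72 bits/base.
* **Addresses.** Built from two binary component codes (both RM(1,4),
  distance 8), giving GC-balanced 16-mers with pairwise Hamming distance
  ≥ 8 and weak self-correlation; a whitening-salt retry guarantees no
  address appears anywhere inside encoded payloads.
* **Channel.** Per-base substitutions/insertions/deletions at roughly
  (85, 20, 45) per kilobase read, with deletion probability boosted
  geometrically inside homopolymers — the signature nanopore error.
* **Decoding.** Exact-address demultiplexing → multi-preset MSA consensus
  → majority-homopolymer aggregation → an extra whole-pool alignment
  round → iterative polishing in which run lengths are re-voted under the
  constraint that every 8-base window stay GC-balanced.
* **Homopolymer check codes.** Runs shortened by one or two bases are
  exactly repaired from ~60 bits of classical-side redundancy per block:
  mod-3 residues of the run-length sequence protected by Reed–Solomon
  style syndromes over GF(1009).

## A worked example

`examples/04_store_and_retrieve.py` stores 900 random bytes and reads
them back through the noisy channel at 50× coverage:

```text
encoded 900 bytes into 5 blocks ([1000, 1000, 1000, 1000, 200] bases)
simulated 250 noisy reads
decoded: 0 byte errors; all blocks validated: True
random access to block 1: 1722 bits via 31 reads, flags: []
```

Each full block holds 1,722 bits in 1,000 bases; the decoder recovered
every byte although each individual read carried on the order of 150
errors, and the random-access query touched only the 31 reads carrying
block 1's address. The other example scripts walk through the constrained
code, the address construction and the homopolymer check code, printing
the counts (17,920 balanced 8-mers, distance-8 address sets, the
`ATCCGA → AATCCCGA` repair) that the library computes.

The same workflow from a shell:

```sh
dnastore encode input.bin blocks.fasta sidecar.json
dnastore simulate blocks.fasta reads.fastq --coverage 50 --seed 1
dnastore decode reads.fastq sidecar.json output.bin --report report.json
dnastore access reads.fastq sidecar.json block5.bin --block-index 5
```

`decode` exits 0 only when every block passed the sidecar validation.

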