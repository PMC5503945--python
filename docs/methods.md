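# Methods

`dnastore` implements a complete store-and-retrieve pipeline for binary
data on synthetic DNA read out by an error-prone nanopore sequencer. This
note documents the model behind each stage, the parameters that matter,
what the synthetic channel does and does not emulate, and the design
choices made where the design was genuinely open.

## The storage code

**Constrained payload code.** Bytes are read MSB-first into a bit stream,
zero-padded to a multiple of 14, and mapped 14 bits at a time onto 8-base
codewords with exactly four bases in {G, C}. There are C(8,4)·4⁴ = 17,920
such 8-mers, so a 2¹⁴-word codebook exists with rate log₂(17,920)/16 ≈
0.88; the codebook is the 16,384 lexicographically smallest balanced
8-mers (A<C<G<T), which makes the bit↔base map canonical without a stored
table. Balancing every aligned 8-window suppresses GC-skewed substrings
(synthesis failures, secondary structure) and caps any single-base run at
8 across codeword boundaries. Full blocks group 123 words = 1,722 bits
into 984 payload bases; with the 16-base address prefix a block is 1,000
bases and carries 1.722 bits/base net.

**Addresses.** Each block's 16-base address is built from two binary
component codes, both the first-order Reed–Muller code RM(1,4) (length
16, minimum distance 8): a weight-8 *GC-pattern* word whose two 8-bit
halves each have weight 4 marks which positions hold G/C, and an
*identity* word picks the base within the class. Distance in either
component forces base-level Hamming distance ≥ 8. Candidates with a
prefix/suffix self-overlap of length ≥ 4, and candidates equal to the
reverse complement of an earlier address (which would make strand-aware
demultiplexing ambiguous), are discarded; the surviving capacity is 160
addresses, far above the 17 needed at the reference scale.

**Address avoidance.** Before mapping, each block's bits are XOR-whitened
with a pseudo-random mask keyed by a per-block salt (PCG64 seeded by the
salt). If any address or its reverse complement occurs anywhere in the
resulting block except the block's own prefix, the salt is incremented
and the block re-encoded. The expected number of retries is ≪ 1; the
postcondition (a provably address-free payload) is verified by an exact
substring screen at encode time.

**Homopolymer check codes.** The residual error mode of the consensus
stage is runs shortened by one or two bases. With magnitude bound L = 2,
run lengths taken mod L+1 = 3 determine the shortening, so the mod-3
residue vector of the block's run lengths is protected with 2t syndromes
S_j = Σᵢ rᵢ(i+1)ʲ over GF(1009) (j = 1..2t, default t = 3 per block,
~60 bits). Any 2t columns of this Vandermonde system are independent, so
error patterns of weight ≤ t decode uniquely; decoding is a small
dictionary-assisted combinatorial search, exact by construction. The
checks are stored in the sidecar (classical media), not appended to the
DNA.

Two extensions use side information the decoder provably has:

* *Mixed-sign reconstruction.* The residue decode fixes each erroneous
  run's length only mod 3; the pure asymmetric rule always lengthens.
  When the one-sided reconstruction contradicts the sidecar's exact block
  length, signs are re-resolved so the lengths sum to that total, which
  repairs e.g. a base transposed between two nearby runs.
* *Structural repair.* If the consensus lost or invented one whole run
  (run count off by ≤ 2), candidate single-run edits are enumerated and
  accepted only if the residues then decode, the total length matches,
  every 8-window is balanced, and every payload codeword is in the
  codebook. Because syndromes are blind to run symbols, syndrome-
  equivalent candidates can exist; ties are broken by total edit distance
  to the reads. The chance of a wrong candidate passing all of these
  checks is negligible.

**Sidecar.** A versioned JSON file carries the exact bit length and, per
block, the address, whitening salt, expected length and check syndromes.
The sidecar is metadata in the few-hundred-bytes range; it is required
for decoding and plays the role of information kept on classical media.

## The synthetic channel

`ChannelParams` corrupts each block position-wise: from one uniform
variate a base is deleted with probability `p_del · boost^(run_len−1)`
(capped at 0.9) or substituted with probability `p_sub` (the stacked
bands make expected per-read counts exactly `L·p`); an insertion of a
uniform base independently follows any position with `p_ins`. Defaults
`p_sub = 0.085, p_ins = 0.020, p_del = 0.045, hp_del_boost = 1.5` put a
1,000-base read at roughly (85, 20, 45) substitutions/insertions/
deletions plus the homopolymer surcharge — the regime of MinION-class
per-read error tables for 1 kb blocks. `max_run_shortening = 2` clips
deletions to at most two per run per read, matching the observation that
nanopore shortening trims runs rather than erasing them. Reads are
emitted on either strand with probability 0.5.

What the channel does *not* emulate: k-mer-specific error tables, quality
scores, signal-level artifacts, chimeric or adapter-bearing reads, and
coverage bias across blocks. Passing tests therefore demonstrate the
pipeline's behaviour under a calibrated, homopolymer-biased i.i.d. indel
channel, not under every failure mode of real flowcells (the FASTQ reader
accepts real data, but no guarantee is implied).

## Consensus reconstruction

**Phase 1 — rough estimates.** Reads containing an exact 16-mer match of
exactly one address (either strand) are demultiplexed to that block;
blocks left with fewer than 3 reads are topped up by near-match address
rescue (infix edit distance ≤ 3, unique best with margin 2). Up to 15
reads — the medoid by pairwise edit distance plus its nearest
neighbours — are star-aligned under each of four scoring presets of the
in-package Gotoh aligner (the presets stand in for running several
external MSA tools with differently tuned parameters). Each preset yields
a per-column plurality consensus; the four consensuses are fused
run-by-run into the *majority-homopolymer* aggregate: runs are matched by
overlapping column extents, any run present in at least one input is
kept, and its length is the mode over the inputs containing it (ties
toward longer, the channel being deletion-dominant). The known address is
then pinned over the estimate's prefix.

**Extra alignment round.** Reads that failed demultiplexing are matched
to the nearest phase-1 estimate by whole-read edit distance (either
strand, runner-up margin 30); this typically raises the usable reads per
block from ~15% of coverage to nearly all of it.

**Phase 2 — iterative polishing.** Up to two rounds of whole-column
re-estimation (star-align all reads to the estimate, per-column plurality
with insertion columns admitted at 35% support) repair locally garbled
stretches; a region whose smoothed per-position insertion pressure
exceeds 8% — several times the channel's insertion rate — is rebuilt
outright as a reference-free mini-consensus of the reads' own segments.
Then run-length voting iterates to a fixed point (≤ 5 rounds): every
read's alignment contributes one observed length per homopolymer run
(interior substitutions anchored by matches still witness the length;
boundary mismatches credit the adjacent run they match), insertions
consistently supported by a majority of covering reads become new runs,
and lengths are chosen by an exact dynamic program over the
(window-phase, partial-window-GC) state that first minimizes unbalanced
8-windows and then maximizes a channel-aware log-likelihood of the
observed length histograms (`LengthPrior`; the mode alone is a biased
estimator on boosted runs, where fewer than half the reads may show the
full length). A substitution sweep and an ML-guarded micro-repair pass
(segment consensus and single-insertion variants over anomaly windows,
accepted only if they strictly lower the summed read–window edit
distance) run between vote rounds; the vote/balance stage always has the
last word. If a block still fails sidecar validation, polishing is
retried under alternate scorings — safe, because a wrong retry cannot
validate.

**Numerical and tie-break conventions.** Alignment ties prefer diagonal
over gap-in-reference over gap-in-read; plurality ties between bases
follow A<C<G<T; base-vs-gap ties keep the base. The alignment band
half-width is 64 plus the length difference (a ~15% error rate on 1 kb
stays well inside). Degenerate inputs — empty read sets, empty sequences,
blocks with zero assigned reads — raise typed errors rather than
propagating silently; a block with no reads is reported by address.

## Problem sizes used

The reference configuration mirrors the system's published operating
point: a 3,633-byte input → 17 blocks (16 × 1,000 bp + 880 bp). The test
suite decodes this at 50 reads/block for three fixed seeds (exact
recovery) and at 100 reads/block for the consensus-error measurement;
the Monte-Carlo channel calibration uses 2,000 reads; the coverage-
monotonicity check uses one block over 20 seeds. These sizes were chosen
to exercise the full system at its natural scale while keeping a complete
run of the suite in the minutes range on one CPU.

## Known limitations

* The decoder's `LengthPrior` defaults mirror the simulator's channel
  calibration; grossly different channels would need the prior (and the
  rescue thresholds) re-estimated from data.
* Homopolymer checks protect run *lengths* only. A consensus substitution
  that survives polishing and happens to produce an in-codebook codeword
  is undetectable by the sidecar; the defense is consensus quality, which
  the coverage-100 tests measure directly.
* Structural ECC repair covers run-count slips of at most 2; denser
  damage is flagged, not silently guessed.
* Random access uses only reads carrying the queried address (exact or
  within 2 edits), so its effective coverage is roughly a third of the
  pool's; at very low coverage the full decode is more robust than
  single-block access.
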