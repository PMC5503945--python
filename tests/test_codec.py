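"""End-to-end encoder/decoder: layout, roundtrips, random access."""

import json

import numpy as np
import pytest

from dnastore._seq import revcomp
from dnastore.addresses import screen_payload
from dnastore.balanced import check_balance
from dnastore.channel import ChannelParams, sample_pool
from dnastore.codec import (
    BlockMissingError,
    CodecConfig,
    bits_to_bytes,
    bytes_to_bits,
    decode_file,
    encode_file,
    encode_payload,
    encode_to_files,
    from_base64,
    make_sidecar,
    random_access_decode,
    read_sidecar,
    to_base64,
)

NOISELESS = ChannelParams(0.0, 0.0, 0.0, 1.0, 2, 0.5)


class TestLayout:
    def test_reference_input_layout(self, encoded_3633):
        """3,633 bytes -> 17 blocks: 16 x 1,000 bp and one 880 bp."""
        blocks, _ = encoded_3633
        lengths = [len(b.sequence) for b in blocks]
        assert len(blocks) == 17
        assert lengths[:16] == [1000] * 16
        assert lengths[16] == 880

    def test_net_density_of_full_block(self, encoded_3633):
        blocks, _ = encoded_3633
        density = blocks[0].n_bits / len(blocks[0].sequence)
        assert round(density, 2) == 1.72

    def test_one_byte_input(self):
        (block,) = encode_file(b"\x42")
        # 8 bits pad to one 14-bit word: a single codeword after the address
        assert len(block.sequence) == 16 + 8

    def test_tail_block_word_arithmetic(self):
        # 1,512 tail bits = 108 words -> 864 payload bases
        assert 1512 // 14 * 8 == 864

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            encode_file(b"")


class TestEncodedConstraints:
    def test_all_payload_windows_balanced(self, encoded_3633):
        blocks, _ = encoded_3633
        for b in blocks:
            assert check_balance(b.sequence, 0) == []

    def test_address_free_payloads(self, encoded_3633):
        blocks, _ = encoded_3633
        addrs = [b.address for b in blocks]
        for b in blocks:
            hits = screen_payload(b.sequence, addrs)
            assert hits == [(b.index, 0)]

    def test_payload_roundtrips_with_salt(self, encoded_3633):
        from dnastore.balanced import decode_codeword
        from dnastore.codec import _bits_to_words, _whiten, _words_to_bits

        blocks, _ = encoded_3633
        b = blocks[0]
        words = [
            decode_codeword(b.payload[i : i + 8])
            for i in range(0, len(b.payload), 8)
        ]
        bits = _whiten(_words_to_bits(words), b.salt)
        assert bits.size == 1722

    def test_encode_payload_rejects_bad_bit_count(self):
        with pytest.raises(ValueError):
            encode_payload(np.zeros(15, np.uint8), [])


class TestNoiselessRoundtrip:
    @pytest.mark.parametrize("n_bytes", [1, 43, 1200])
    def test_identity_through_noiseless_channel(self, n_bytes):
        rng = np.random.default_rng(n_bytes)
        data = rng.integers(0, 256, n_bytes, dtype=np.uint8).tobytes()
        blocks = encode_file(data)
        sidecar = make_sidecar(blocks, len(data) * 8)
        pool = sample_pool([b.sequence for b in blocks], 4, NOISELESS, seed=1)
        result = decode_file(pool, sidecar)
        assert result.data == data
        assert result.ok

    def test_missing_block_reported_by_address(self, encoded_3633):
        blocks, sidecar = encoded_3633
        truth = [b.sequence for b in blocks]
        pool = sample_pool(truth, 3, NOISELESS, seed=2)
        kept = [r for r in pool if r.source_block != 5]
        with pytest.raises(BlockMissingError) as exc:
            decode_file(kept, sidecar)
        assert blocks[5].address.bases in exc.value.addresses


class TestRandomAccess:
    def test_single_block_bits(self, payload_3633, encoded_3633):
        blocks, sidecar = encoded_3633
        truth = [b.sequence for b in blocks]
        pool = sample_pool(truth, 4, NOISELESS, seed=3)
        data, meta = random_access_decode(pool, blocks[5].address, sidecar)
        bits = bytes_to_bits(payload_3633)
        expect = bits_to_bytes(
            bits[meta["bit_offset"] : meta["bit_offset"] + meta["n_bits"]],
            meta["n_bits"],
        )
        assert data == expect
        assert meta["block_index"] == 5
        assert meta["reads_used"] <= 4

    def test_unknown_address_rejected(self, encoded_3633):
        _, sidecar = encoded_3633
        with pytest.raises(KeyError):
            random_access_decode([], "A" * 16, sidecar)

    def test_every_block_consistent_with_full_decode(self):
        rng = np.random.default_rng(77)
        data = rng.integers(0, 256, 400, dtype=np.uint8).tobytes()
        blocks = encode_file(data)
        sidecar = make_sidecar(blocks, len(data) * 8)
        pool = sample_pool([b.sequence for b in blocks], 4, NOISELESS, seed=4)
        full = decode_file(pool, sidecar)
        bits = []
        for b in blocks:
            part, meta = random_access_decode(pool, b.address, sidecar)
            bits.append(bytes_to_bits(part)[: meta["n_bits"]])
        joined = bits_to_bytes(np.concatenate(bits), sidecar["bit_length"])
        assert joined == full.data == data


class TestFileIO:
    def test_fasta_and_sidecar_files(self, payload_3633, tmp_path):
        fasta = str(tmp_path / "blocks.fasta")
        side = str(tmp_path / "blocks.json")
        blocks = encode_to_files(payload_3633, fasta, side)
        sidecar = read_sidecar(side)
        assert sidecar["bit_length"] == len(payload_3633) * 8
        assert len(sidecar["blocks"]) == len(blocks) == 17
        from dnastore.codec import read_sequences_fasta

        seqs = read_sequences_fasta(fasta)
        assert seqs == [b.sequence for b in blocks]

    def test_sidecar_version_checked(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps({"version": 99}))
        with pytest.raises(ValueError):
            read_sidecar(str(bad))


class TestBase64Helpers:
    def test_roundtrip(self):
        data = bytes(range(64))
        assert from_base64(to_base64(data)) == data
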