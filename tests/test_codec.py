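import zlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdstore.alphabet import CompositeAlphabet, enumerate_full_alphabet
from cdstore.channel import ChannelParams, simulate_counts_array
from cdstore.codec import (
    MatrixLayout,
    bits_to_symbols,
    decode_counts,
    encode_bytes,
    letters_frame,
    symbols_to_bits,
    transcode_bytes_to_letters,
    transcode_letters_to_bytes,
)
from cdstore.experiments import build_error_fixture, payload_for_matrices
from cdstore.rscode import RSSpec, get_codec
from cdstore.softdecode import SearchLimits


def lex_subset(k, size):
    """First `size` letters of the full alphabet: fine for codec plumbing
    tests that do not depend on error-rate-based selection."""
    full = enumerate_full_alphabet(k)
    return CompositeAlphabet(k, full.letters[:size])


@pytest.fixture(scope="module")
def layout256():
    return MatrixLayout(alphabet=lex_subset(10, 256), rs_spec=RSSpec(256, 45, 41))


def test_crc32_reference_values():
    assert zlib.crc32(b"") == 0x00000000
    assert zlib.crc32(b"123456789") == 0xCBF43926


def test_layout_geometry(layout256):
    assert layout256.bits_per_symbol == 8
    assert layout256.info_symbols_per_matrix == 410
    assert layout256.payload_bits_per_matrix == 410 * 8 - 32
    assert layout256.symbols_per_matrix == 450


def test_layout_rejects_mismatched_alphabet():
    with pytest.raises(ValueError):
        MatrixLayout(alphabet=lex_subset(10, 128), rs_spec=RSSpec(256, 45, 41))


@pytest.mark.parametrize("k,size", [(1, 4), (6, 64), (8, 128), (10, 256)])
def test_transcode_round_trip(k, size, rng):
    alphabet = lex_subset(k, size)
    data = rng.integers(0, 256, 300, dtype=np.uint8).tobytes()
    letters = transcode_bytes_to_letters(data, alphabet)
    back = transcode_letters_to_bytes(letters, alphabet)
    assert back[: len(data)] == data


def test_transcode_sigma256_is_identity_byte_mapping(rng):
    alphabet = lex_subset(10, 256)
    data = bytes(range(256))
    letters = transcode_bytes_to_letters(data, alphabet)
    assert letters.tolist() == list(range(256))


def test_transcode_sigma64_packs_4_letters_per_3_bytes():
    alphabet = lex_subset(6, 64)
    letters = transcode_bytes_to_letters(b"\xff\x00\xf0", alphabet)
    assert len(letters) == 4
    assert letters.tolist() == [0b111111, 0b110000, 0b000011, 0b110000]


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.binary(min_size=1, max_size=64))
def test_bit_packing_round_trip_property(data):
    for m in (2, 6, 7, 8):
        bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8))
        pad = (-len(bits)) % m
        bits = np.concatenate([bits, np.zeros(pad, dtype=np.uint8)])
        syms = bits_to_symbols(bits, m)
        assert np.array_equal(symbols_to_bits(syms, m), bits)


def test_noiseless_round_trip_10kib(layout256, rng):
    """Exact counts (no base errors, no sampling bias) round-trip a random
    10 KiB payload with every accuracy at 1.0."""
    payload = rng.integers(0, 256, 10 * 1024, dtype=np.uint8).tobytes()
    matrices = encode_bytes(payload, layout256)
    # deterministic readout: depth 30 = 3 reads per mixture unit
    counts = layout256.alphabet.ratio_matrix()[matrices.reshape(-1)] * 3
    decoded, report = decode_counts(
        counts, layout256, mode="hard", ground_truth=matrices
    )
    assert decoded == payload
    assert report.matrices_failed == 0
    assert report.letter_inference_accuracy == 1.0


def test_encode_rejects_bad_input(layout256):
    with pytest.raises(ValueError):
        encode_bytes(b"", layout256)
    with pytest.raises(ValueError):
        decode_counts(np.zeros((7, 4), dtype=int), layout256)


def test_archive_determinism(layout256):
    payload = payload_for_matrices(layout256, 2, seed=5)
    a = encode_bytes(payload, layout256)
    b = encode_bytes(payload, layout256)
    assert np.array_equal(a, b)
    params = ChannelParams(p_error=0.01, depth_N=100, seed=9)
    ca = simulate_counts_array(a.reshape(-1), layout256.alphabet, params)
    cb = simulate_counts_array(b.reshape(-1), layout256.alphabet, params)
    assert np.array_equal(ca, cb)


def test_letters_frame_layout(layout256):
    payload = payload_for_matrices(layout256, 1, seed=5)
    matrices = encode_bytes(payload, layout256)
    frame = letters_frame(matrices, layout256)
    assert len(frame) == 450
    assert frame["block"].max() == 9
    assert frame["pos"].max() == 44
    assert (frame["letter_index"] < 256).all()


def test_soft_recovers_where_hard_fails(s64_setup):
    """At depth 190 the 64-letter archive hard-decodes imperfectly but the
    soft decoder recovers every matrix; soft is never worse than hard."""
    alphabet, library, params = s64_setup
    layout = MatrixLayout(alphabet=alphabet, rs_spec=RSSpec(64, 45, 41))
    payload = payload_for_matrices(layout, 10, seed=3)
    truth = encode_bytes(payload, layout)
    chan = ChannelParams(p_error=0.01, depth_N=190, seed=4)
    counts = simulate_counts_array(truth.reshape(-1), alphabet, chan)
    hard_payload, hard = decode_counts(
        counts, layout, library=library, mode="hard", ground_truth=truth
    )
    soft_payload, soft = decode_counts(
        counts, layout, library=library, mode="soft", ground_truth=truth
    )
    assert soft.matrices_failed <= hard.matrices_failed
    assert soft.matrices_failed == 0
    assert soft_payload == payload


def test_failed_matrices_monotone_in_depth(s64_setup):
    """Deeper sequencing never increases the failed-matrix count."""
    alphabet, library_190, _ = s64_setup
    from cdstore.translib import get_library

    layout = MatrixLayout(alphabet=alphabet, rs_spec=RSSpec(64, 45, 41))
    limits = SearchLimits(max_iterations=2_000)
    payload = payload_for_matrices(layout, 20, seed=13)
    truth = encode_bytes(payload, layout)
    failures = []
    for depth in (50, 100, 190):
        params = ChannelParams(p_error=0.01, depth_N=depth, seed=14)
        library = (
            library_190
            if depth == 190
            else get_library(alphabet, params, method="monte_carlo", n_draws=4_000)
        )
        counts = simulate_counts_array(truth.reshape(-1), alphabet, params)
        _, report = decode_counts(
            counts, layout, library=library, limits=limits, mode="soft"
        )
        failures.append(report.matrices_failed)
    assert failures[0] >= failures[1] >= failures[2]
    assert failures[2] == 0


def test_miscorrecting_block_flagged_and_matrix_recovered(s64_setup):
    """A matrix containing a block built to provoke an RS decoder error must
    either be repaired through validation/re-decoding or counted failed with
    the decoder error detected."""
    alphabet, library, params = s64_setup
    layout = MatrixLayout(alphabet=alphabet, rs_spec=RSSpec(64, 45, 41))
    payload = payload_for_matrices(layout, 1, seed=21)
    truth = encode_bytes(payload, layout)
    chan = ChannelParams(p_error=0.01, depth_N=190, seed=22)
    counts = simulate_counts_array(truth.reshape(-1), alphabet, chan)
    # overwrite block 0 with a 4-error fixture (beyond the hard bound)
    rng = np.random.default_rng(23)
    fixture_counts, _ = build_error_fixture(
        truth[0, :45], alphabet, library, chan, 4, rng
    )
    counts[:45] = fixture_counts
    decoded, report = decode_counts(
        counts, layout, library=library, mode="soft", ground_truth=truth
    )
    assert decoded == payload
    assert report.matrices_failed == 0
    assert report.blocks_soft_decoded >= 1
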