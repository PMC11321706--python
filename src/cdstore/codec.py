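"""End-to-end byte archive over composite letters.

Layout: the byte stream (4-byte big-endian length prefix + payload, zero
padded) is chunked into matrices.  A matrix holds 10 RS(45, 41) blocks; its
410 information symbols carry payload bits plus a CRC32 of those payload
bits in the last 32 information bits (CRC-32/ISO-HDLC, the zlib polynomial,
for bit-exactness).  Each block is systematically RS encoded and symbols
map one-to-one onto letters of a power-of-two composite alphabet (m bits
per letter, big-endian bit order, left-to-right positions).

Decoding runs per block (MAP inference, hard decision, then soft decision
with library validation) and per matrix (CRC32 check; on failure, blocks
suspected of RS decoder errors are re-decoded with their failed codewords
excluded, for a bounded number of passes).  Matrices that still fail are
counted and their payload is zero-filled.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import CompositeAlphabet, bits_per_letter
from .inference import batch_distances, infer_symbols
from .rscode import RSSpec, get_codec
from .softdecode import (
    BlockEvidence,
    SearchLimits,
    SoftDecodeResult,
    derrick_cp_decode,
    position_alternatives,
    validate_against_library,
)
from .translib import TransitionLibrary


@dataclass(frozen=True)
class MatrixLayout:
    """Archive geometry for one (alphabet, RS spec) pair."""

    alphabet: CompositeAlphabet
    rs_spec: RSSpec = RSSpec()
    blocks_per_matrix: int = 10
    crc_bits: int = 32

    def __post_init__(self) -> None:
        if len(self.alphabet) != self.rs_spec.field_order:
            raise ValueError(
                f"alphabet size {len(self.alphabet)} must equal the RS field "
                f"order {self.rs_spec.field_order}"
            )
        if self.blocks_per_matrix < 1:
            raise ValueError("need at least one block per matrix")
        if self.payload_bits_per_matrix <= 0:
            raise ValueError("matrix too small to carry any payload")

    @property
    def bits_per_symbol(self) -> int:
        return bits_per_letter(self.alphabet)

    @property
    def info_symbols_per_matrix(self) -> int:
        return self.blocks_per_matrix * self.rs_spec.k_info

    @property
    def payload_bits_per_matrix(self) -> int:
        return self.info_symbols_per_matrix * self.bits_per_symbol - self.crc_bits

    @property
    def symbols_per_matrix(self) -> int:
        return self.blocks_per_matrix * self.rs_spec.n_code


@dataclass
class DecodeReport:
    """Counters and (with ground truth) accuracy metrics of one decode run."""

    matrices_total: int = 0
    matrices_failed: int = 0
    blocks_soft_decoded: int = 0
    decoder_errors_detected: int = 0
    letter_inference_accuracy: float | None = None
    position_prediction_accuracy: float | None = None
    true_letter_prediction_accuracy: float | None = None
    # raw tallies behind the accuracy ratios
    n_positions: int = 0
    n_letter_correct: int = 0
    n_true_errors_in_soft_blocks: int = 0
    n_true_errors_covered: int = 0
    n_covered_with_truth_in_alternatives: int = 0

    def finalize(self) -> None:
        if self.n_positions:
            self.letter_inference_accuracy = (
                self.n_letter_correct / self.n_positions
            )
        if self.n_true_errors_in_soft_blocks:
            self.position_prediction_accuracy = (
                self.n_true_errors_covered / self.n_true_errors_in_soft_blocks
            )
        if self.n_true_errors_covered:
            self.true_letter_prediction_accuracy = (
                self.n_covered_with_truth_in_alternatives / self.n_true_errors_covered
            )


# ---------------------------------------------------------------------------
# bit plumbing


def bytes_to_bits(data: bytes) -> np.ndarray:
    return np.unpackbits(np.frombuffer(data, dtype=np.uint8))


def bits_to_bytes(bits: np.ndarray) -> bytes:
    bits = np.asarray(bits, dtype=np.uint8)
    pad = (-len(bits)) % 8
    if pad:
        bits = np.concatenate([bits, np.zeros(pad, dtype=np.uint8)])
    return np.packbits(bits).tobytes()


def bits_to_symbols(bits: np.ndarray, m: int) -> np.ndarray:
    """m bits per symbol, big-endian within the symbol."""
    if len(bits) % m:
        raise ValueError("bit count not a multiple of the symbol width")
    weights = 1 << np.arange(m - 1, -1, -1)
    return (np.asarray(bits, dtype=np.int64).reshape(-1, m) * weights).sum(axis=1)


def symbols_to_bits(symbols: np.ndarray, m: int) -> np.ndarray:
    symbols = np.asarray(symbols, dtype=np.int64)
    shifts = np.arange(m - 1, -1, -1)
    return ((symbols[:, None] >> shifts) & 1).astype(np.uint8).reshape(-1)


def transcode_bytes_to_letters(data: bytes, alphabet: CompositeAlphabet) -> np.ndarray:
    """Pack bytes into letter symbol indices (zero-pad to a whole symbol)."""
    m = bits_per_letter(alphabet)
    bits = bytes_to_bits(data)
    pad = (-len(bits)) % m
    if pad:
        bits = np.concatenate([bits, np.zeros(pad, dtype=np.uint8)])
    return bits_to_symbols(bits, m)


def transcode_letters_to_bytes(
    symbols: np.ndarray, alphabet: CompositeAlphabet
) -> bytes:
    """Inverse of transcode_bytes_to_letters (trailing pad bits dropped)."""
    m = bits_per_letter(alphabet)
    bits = symbols_to_bits(symbols, m)
    return bits_to_bytes(bits[: 8 * (len(bits) // 8)])


def _crc32_of_bits(bits: np.ndarray) -> int:
    """CRC-32/ISO-HDLC of a bit vector packed MSB-first (zero-padded)."""
    return zlib.crc32(bits_to_bytes(bits)) & 0xFFFFFFFF


# ---------------------------------------------------------------------------
# encode


def encode_bytes(
    payload: bytes, layout: MatrixLayout
) -> np.ndarray:
    """Encode a byte payload into per-matrix letter symbols.

    Returns an (n_matrices, symbols_per_matrix) array of alphabet symbol
    indices.  The archive stream starts with a 4-byte big-endian length
    prefix so decoding can strip the zero padding of the final matrix.
    """
    if not payload:
        raise ValueError("payload must be non-empty")
    m = layout.bits_per_symbol
    stream = len(payload).to_bytes(4, "big") + payload
    bits = bytes_to_bits(stream)
    ppm = layout.payload_bits_per_matrix
    n_matrices = -(-len(bits) // ppm)
    bits = np.concatenate(
        [bits, np.zeros(n_matrices * ppm - len(bits), dtype=np.uint8)]
    )
    codec = get_codec(layout.rs_spec)
    k = layout.rs_spec.k_info
    out = np.empty((n_matrices, layout.symbols_per_matrix), dtype=np.int64)
    for mi in range(n_matrices):
        chunk = bits[mi * ppm : (mi + 1) * ppm]
        crc = _crc32_of_bits(chunk)
        crc_bits = np.array(
            [(crc >> (31 - b)) & 1 for b in range(32)], dtype=np.uint8
        )
        info_bits = np.concatenate([chunk, crc_bits])
        info_symbols = bits_to_symbols(info_bits, m)
        col = 0
        for bi in range(layout.blocks_per_matrix):
            block_info = [int(s) for s in info_symbols[bi * k : (bi + 1) * k]]
            cw = codec.encode(block_info)
            out[mi, col : col + layout.rs_spec.n_code] = cw
            col += layout.rs_spec.n_code
    return out


def letters_frame(matrices: np.ndarray, layout: MatrixLayout) -> pd.DataFrame:
    """Letter archive as a table: matrix, block, pos, letter_index, ratios."""
    n_code = layout.rs_spec.n_code
    rows = []
    for mi, row in enumerate(matrices):
        for j, sym in enumerate(row):
            letter = layout.alphabet[int(sym)]
            rows.append(
                (mi, j // n_code, j % n_code, int(sym), letter.ratio_string())
            )
    return pd.DataFrame(
        rows, columns=["matrix", "block", "pos", "letter_index", "ratio_string"]
    )


# ---------------------------------------------------------------------------
# decode


def _decode_matrix(
    evidence_blocks: list[BlockEvidence],
    layout: MatrixLayout,
    library: TransitionLibrary | None,
    limits: SearchLimits,
    mode: str,
    report: DecodeReport,
) -> tuple[np.ndarray | None, list[SoftDecodeResult | None]]:
    """Decode one matrix's blocks and verify its CRC32.

    Returns (payload bits or None, per-block results)."""
    spec = layout.rs_spec
    codec = get_codec(spec)
    n_blocks = layout.blocks_per_matrix
    m = layout.bits_per_symbol
    k = spec.k_info
    results: list[SoftDecodeResult | None] = [None] * n_blocks
    codewords: list[list[int] | None] = [None] * n_blocks
    excluded: list[set[tuple[int, ...]]] = [set() for _ in range(n_blocks)]

    def decode_block(bi: int) -> None:
        ev = evidence_blocks[bi]
        if mode == "hard":
            res = codec.decode([int(s) for s in ev.symbols])
            if res is None:
                results[bi] = SoftDecodeResult(
                    "exhausted", None, [], 1, False, set(), (), False
                )
                codewords[bi] = None
            else:
                results[bi] = SoftDecodeResult(
                    "decoded", res[0], [], 1, False, set(), (), False
                )
                codewords[bi] = res[0]
            return
        out = derrick_cp_decode(
            ev,
            library,
            spec,
            limits,
            excluded=excluded[bi],
            validate_m=limits.max_alternatives,
        )
        excluded[bi] |= out.excluded_solutions
        if (
            out.status == "decoded"
            and not out.decoder_error_suspect
            and not validate_against_library(
                out, ev, library, limits.max_alternatives
            )
        ):
            # flag only: the matrix CRC decides whether to re-decode
            out.decoder_error_suspect = True
        results[bi] = out
        codewords[bi] = out.codeword

    def matrix_bits() -> np.ndarray | None:
        if any(cw is None for cw in codewords):
            return None
        info = np.concatenate(
            [np.asarray(cw[:k], dtype=np.int64) for cw in codewords]
        )
        bits = symbols_to_bits(info, m)
        chunk = bits[: layout.payload_bits_per_matrix]
        crc_bits = bits[layout.payload_bits_per_matrix :]
        crc = 0
        for b in crc_bits:
            crc = (crc << 1) | int(b)
        if _crc32_of_bits(chunk) != crc:
            return None
        return chunk

    for bi in range(n_blocks):
        decode_block(bi)
    bits = matrix_bits()
    passes = 0
    while bits is None and mode == "soft" and passes < limits.max_block_passes:
        passes += 1
        if any(cw is None for cw in codewords):
            break  # an exhausted block cannot improve under the same exclusions
        # revisit blocks suspected of decoder errors (or, failing that, any
        # block that needed the soft search), excluding their accepted
        # codewords so the search moves past them
        suspects = [
            bi
            for bi, r in enumerate(results)
            if r is not None and (r.decoder_error_suspect or r.used_soft_search)
        ]
        if not suspects:
            break
        for bi in suspects:
            excluded[bi].add(tuple(codewords[bi]))
            decode_block(bi)
        bits = matrix_bits()

    for r in results:
        if r is not None:
            if r.used_soft_search:
                report.blocks_soft_decoded += 1
            if r.decoder_error_suspect:
                report.decoder_errors_detected += 1
    return bits, results


def decode_counts(
    counts: np.ndarray,
    layout: MatrixLayout,
    library: TransitionLibrary | None = None,
    limits: SearchLimits = SearchLimits(),
    mode: str = "soft",
    ground_truth: np.ndarray | None = None,
) -> tuple[bytes, DecodeReport]:
    """Decode a per-position base-count table back into the byte payload.

    ``counts`` has one row per sequence position (matrix-major, then block,
    then position).  ``mode='hard'`` skips the soft search, for comparison.
    With ``ground_truth`` (the encoded symbol array or its flattened form)
    the report carries the three accuracy metrics: letter inference
    (MAP call = truth, all positions), position prediction (truly erroneous
    positions inside soft-decoded blocks that appear in the final candidate
    set) and true-letter prediction (covered positions whose alternative
    set contains the true letter).
    """
    if mode not in ("hard", "soft"):
        raise ValueError("mode must be 'hard' or 'soft'")
    if mode == "soft" and library is None:
        raise ValueError("soft mode requires a transition library")
    counts = np.asarray(counts, dtype=np.int64)
    spm = layout.symbols_per_matrix
    if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] % spm:
        raise ValueError(
            f"counts must be (n_matrices * {spm}, 4); got {counts.shape}"
        )
    n_matrices = counts.shape[0] // spm
    n_code = layout.rs_spec.n_code
    p_error = library.p_error if library is not None else 0.01

    symbols = infer_symbols(counts, layout.alphabet, p_error)
    distances = batch_distances(counts, symbols, layout.alphabet)
    truth = (
        np.asarray(ground_truth, dtype=np.int64).reshape(-1)
        if ground_truth is not None
        else None
    )
    if truth is not None and len(truth) != len(symbols):
        raise ValueError("ground truth length does not match the counts")

    report = DecodeReport(matrices_total=n_matrices)
    if truth is not None:
        report.n_positions = len(symbols)
        report.n_letter_correct = int((symbols == truth).sum())

    all_bits = []
    for mi in range(n_matrices):
        blocks = []
        for bi in range(layout.blocks_per_matrix):
            lo = mi * spm + bi * n_code
            hi = lo + n_code
            blocks.append(
                BlockEvidence(
                    counts[lo:hi],
                    symbols[lo:hi],
                    distances[lo:hi],
                    layout.alphabet,
                )
            )
        bits, results = _decode_matrix(
            blocks, layout, library, limits, mode, report
        )
        if bits is None:
            report.matrices_failed += 1
            bits = np.zeros(layout.payload_bits_per_matrix, dtype=np.uint8)
        all_bits.append(bits)

        if truth is not None and library is not None:
            for bi, r in enumerate(results):
                if r is None or not r.used_soft_search:
                    continue
                lo = mi * spm + bi * n_code
                cands = set(r.candidate_positions)
                alt_sets = position_alternatives(
                    blocks[bi], library, limits.max_alternatives
                )
                for pos in range(n_code):
                    t = int(truth[lo + pos])
                    inf = int(symbols[lo + pos])
                    if t == inf:
                        continue
                    report.n_true_errors_in_soft_blocks += 1
                    if pos in cands:
                        report.n_true_errors_covered += 1
                        if t in (a for a, _ in alt_sets[pos]):
                            report.n_covered_with_truth_in_alternatives += 1

    stream = bits_to_bytes(np.concatenate(all_bits))
    length = int.from_bytes(stream[:4], "big")
    payload = stream[4 : 4 + length]
    report.finalize()
    return payload, report
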