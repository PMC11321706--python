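"""Iterative soft-decision decoding of composite-letter RS blocks.

When a block carries more letter errors than the RS hard bound t, the soft
decoder exploits two per-position signals: the reliability of each MAP call
(Euclidean distance between observed frequencies and the called letter) and
the transition library's ranked alternative letters.  It ranks the least
reliable positions as candidate error positions, substitutes library
alternatives there, and re-runs hard-decision decoding, walking substitution
paths in descending joint transition probability until RS decoding succeeds
or the iteration budget is spent.

Every RS success is *unverified*: beyond t errors the RS decoder can return
a valid-but-wrong codeword (decoder error).  Candidate solutions are vetted
by transition-library membership — at every position where the decoded
letter differs from the inferred letter, the decoded letter must be among
the inferred letter's top-m library alternatives — and rejected solutions
are excluded so the search continues past them.  Matrix-level CRC32
checking (codec layer) provides the second line of defence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .alphabet import CompositeAlphabet
from .channel import ObservedCounts
from .inference import batch_distances, infer_symbols
from .rscode import RSSpec, get_codec
from .translib import TransitionLibrary


@dataclass(frozen=True)
class SearchLimits:
    """Caps on the substitution search.

    max_positions    largest candidate-position set considered (default 8).
    max_alternatives top-m library alternatives substituted per position
                     (default 2, mirroring two-alternative letter sets).
    max_iterations   RS decode attempts allowed per block (one attempt = one
                     iteration) before the block is given up.
    max_block_passes matrix-level re-decode rounds after a CRC failure.
    """

    max_positions: int = 8
    max_alternatives: int = 2
    max_iterations: int = 100_000
    max_block_passes: int = 3

    def __post_init__(self) -> None:
        if min(self.max_positions, self.max_alternatives, self.max_iterations) < 1:
            raise ValueError("search limits must be >= 1")
        if self.max_block_passes < 0:
            raise ValueError("max_block_passes must be >= 0")


@dataclass
class BlockEvidence:
    """Per-position observations and MAP calls for one RS block."""

    counts: np.ndarray  # (n_code, 4)
    symbols: np.ndarray  # (n_code,) inferred alphabet indices
    distances: np.ndarray  # (n_code,) reliability distances
    alphabet: CompositeAlphabet

    def __post_init__(self) -> None:
        if not (len(self.counts) == len(self.symbols) == len(self.distances)):
            raise ValueError("evidence arrays must have equal length")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        alphabet: CompositeAlphabet,
        p_error: float,
    ) -> "BlockEvidence":
        counts = np.asarray(counts, dtype=np.int64)
        symbols = infer_symbols(counts, alphabet, p_error)
        distances = batch_distances(counts, symbols, alphabet)
        return cls(counts, symbols, distances, alphabet)

    def observed(self, pos: int) -> ObservedCounts:
        row = self.counts[pos]
        return ObservedCounts(tuple(int(c) for c in row), int(row.sum()))

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class SoftDecodeResult:
    status: str  # "decoded" | "exhausted"
    codeword: list[int] | None
    substitutions: list[tuple[int, int, int]]  # (position, from, to)
    iterations_used: int
    decoder_error_suspect: bool
    excluded_solutions: set[tuple[int, ...]] = field(default_factory=set)
    candidate_positions: tuple[int, ...] = ()
    used_soft_search: bool = False


def rank_candidate_positions(evidence: BlockEvidence, d: int) -> list[int]:
    """The ``d`` positions with the largest reliability distance, ordered
    descending; ties break toward the smaller position index."""
    if not 1 <= d <= len(evidence):
        raise ValueError(f"d must lie in [1, {len(evidence)}]")
    order = np.lexsort((np.arange(len(evidence)), -evidence.distances))
    return [int(i) for i in order[:d]]


def _start_candidate_size(spec: RSSpec, limits: SearchLimits) -> int:
    # first-level candidate set: a small margin over the hard bound
    return min(limits.max_positions, max(4, spec.t_correct + 2))


def position_alternatives(
    evidence: BlockEvidence,
    library: TransitionLibrary,
    m: int = 2,
) -> list[list[tuple[int, float]]]:
    """Ranked correction candidates for every position of a block.

    The alternative letter set at position p ranks letters t != inferred_p
    by the posterior of the stored letter given both the observed counts
    and the inference outcome:

        log P(X_p | t)  +  log P(inferred = inferred_p | true = t)

    The first term is the multinomial observation likelihood; the second is
    the transition library's probability of t being misread as the inferred
    letter, which regularises the ranking toward plausible confusions.
    Returns, per position, the top-m (symbol, log-posterior) pairs.
    """
    from .inference import _score_matrix  # local import: avoids cycle at import time

    S = _score_matrix(evidence.counts, evidence.alphabet, library.p_error)
    logT = np.log(np.maximum(library.matrix, 1e-300))
    out = []
    for p in range(len(evidence)):
        inf = int(evidence.symbols[p])
        scores = S[p] + logT[:, inf]
        order = np.argsort(-scores, kind="stable")
        row = [
            (int(t), float(scores[t])) for t in order if int(t) != inf
        ][:m]
        out.append(row)
    return out


def validate_against_library(
    result: SoftDecodeResult,
    evidence: BlockEvidence,
    library: TransitionLibrary,
    m: int = 2,
    alt_sets: list[list[tuple[int, float]]] | None = None,
) -> bool:
    """Alternative-set membership check of a decoded block.

    True iff at every position where the decoded letter differs from the
    inferred letter, the decoded letter belongs to that position's top-m
    alternative letter set.  A False verdict marks a suspected RS decoder
    error; the caller excludes the codeword and re-decodes.
    """
    if result.status != "decoded" or result.codeword is None:
        raise ValueError("can only validate a decoded result")
    if alt_sets is None:
        alt_sets = position_alternatives(evidence, library, m)
    for pos, sym in enumerate(result.codeword):
        inferred = int(evidence.symbols[pos])
        if sym != inferred and sym not in (a for a, _ in alt_sets[pos]):
            return False
    return True


def derrick_cp_decode(
    evidence: BlockEvidence,
    library: TransitionLibrary,
    spec: RSSpec,
    limits: SearchLimits = SearchLimits(),
    excluded: set[tuple[int, ...]] | None = None,
    validate_m: int | None = None,
) -> SoftDecodeResult:
    """Soft-decision decode of one RS block.

    1. Hard-decode the inferred letters; on success return immediately with
       zero substitutions (soft decoding never degrades hard decoding).
    2. Otherwise, for s = 1, 2, ...: take the d least reliable positions
       (d starts just above the hard bound and grows by one per failed
       level), try every size-s combination of them in reliability-rank
       order, and for each combination every assignment of top-m library
       alternatives in descending joint transition probability; substitute,
       hard-decode, and return the first acceptable success.
    3. Stop with status "exhausted" when the iteration budget or the search
       space runs out.

    Solutions in ``excluded`` (e.g. rejected after a CRC failure) are
    skipped.  With ``validate_m`` set, solutions found by the substitution
    search are vetted against the alternative sets in-line; rejected ones
    are excluded so the search continues past suspected decoder errors.
    If the search then exhausts, the first rejected solution is returned
    flagged ``decoder_error_suspect`` rather than nothing — the matrix
    CRC32 is the final arbiter of whether the flag was a false alarm.
    An immediate hard-decision success is never second-guessed here; the
    archive layer validates it and re-decodes only if the CRC fails.
    """
    if len(evidence) != spec.n_code:
        raise ValueError(
            f"evidence length {len(evidence)} != RS block length {spec.n_code}"
        )
    codec = get_codec(spec)
    base = [int(s) for s in evidence.symbols]
    excluded = set(excluded) if excluded else set()
    iterations = 0
    suspect = False
    alt_sets: list[list[tuple[int, float]]] | None = None

    def get_alt_sets() -> list[list[tuple[int, float]]]:
        nonlocal alt_sets
        if alt_sets is None:
            alt_sets = position_alternatives(
                evidence, library, limits.max_alternatives
            )
        return alt_sets

    rejected: list[SoftDecodeResult] = []

    def accept(word, res, subs, cands, validate):
        nonlocal suspect
        cw, _ = res
        key = tuple(cw)
        if key in excluded:
            return None
        result = SoftDecodeResult(
            status="decoded",
            codeword=cw,
            substitutions=subs,
            iterations_used=iterations,
            decoder_error_suspect=suspect,
            excluded_solutions=excluded,
            candidate_positions=cands,
            used_soft_search=bool(subs) or iterations > 1,
        )
        if (
            validate
            and validate_m is not None
            and not validate_against_library(
                result, evidence, library, validate_m, alt_sets=get_alt_sets()
            )
        ):
            excluded.add(key)
            suspect = True
            result.decoder_error_suspect = True
            rejected.append(result)
            return None
        return result

    def exhausted_result(cands):
        # prefer a solution rejected only by the membership check over
        # giving up outright; the flag routes it to CRC-driven re-decoding
        if rejected:
            fallback = rejected[0]
            fallback.iterations_used = iterations
            return fallback
        return SoftDecodeResult(
            status="exhausted",
            codeword=None,
            substitutions=[],
            iterations_used=iterations,
            decoder_error_suspect=suspect,
            excluded_solutions=excluded,
            candidate_positions=cands,
            used_soft_search=True,
        )

    iterations += 1
    res = codec.decode(base)
    if res is not None:
        out = accept(base, res, [], (), validate=False)
        if out is not None:
            return out

    alts = get_alt_sets()
    d0 = _start_candidate_size(spec, limits)
    max_s = limits.max_positions
    for s in range(1, max_s + 1):
        d = min(limits.max_positions, max(s, d0 + s - 1))
        ranked = rank_candidate_positions(evidence, d)
        cands = tuple(ranked)
        for combo in itertools.combinations(range(d), s):
            positions = [ranked[i] for i in combo]
            per_pos = [alts[pos] for pos in positions]
            if any(not c for c in per_pos):
                continue
            assignments = sorted(
                itertools.product(*[range(len(c)) for c in per_pos]),
                key=lambda idxs: -sum(
                    per_pos[i][j][1] for i, j in enumerate(idxs)
                ),
            )
            for idxs in assignments:
                if iterations >= limits.max_iterations:
                    return exhausted_result(cands)
                word = list(base)
                subs = []
                for i, j in enumerate(idxs):
                    pos = positions[i]
                    target = per_pos[i][j][0]
                    word[pos] = target
                    subs.append((pos, base[pos], target))
                iterations += 1
                res = codec.decode(word)
                if res is None:
                    continue
                out = accept(word, res, subs, cands, validate=True)
                if out is not None:
                    return out
    return exhausted_result(
        tuple(
            rank_candidate_positions(evidence, min(limits.max_positions, len(evidence)))
        )
    )


def decode_block_validated(
    evidence: BlockEvidence,
    library: TransitionLibrary,
    spec: RSSpec,
    limits: SearchLimits = SearchLimits(),
    excluded: set[tuple[int, ...]] | None = None,
) -> SoftDecodeResult:
    """Block decoding with the full decoder-error handling loop.

    Runs the soft decoder and vets the accepted solution against the
    per-position alternative sets; a rejected solution is excluded and the
    block re-decoded, up to ``max_block_passes`` extra rounds.  This is the
    standalone-block counterpart of the archive layer's CRC-driven
    re-decoding (no CRC exists at block scope, so membership is the only
    arbiter here)."""
    excluded = set(excluded) if excluded else set()
    m = limits.max_alternatives
    last = None
    for _ in range(limits.max_block_passes + 1):
        res = derrick_cp_decode(
            evidence, library, spec, limits, excluded=excluded, validate_m=m
        )
        excluded |= res.excluded_solutions
        last = res
        if res.status != "decoded":
            return res
        if validate_against_library(res, evidence, library, m):
            return res
        res.decoder_error_suspect = True
        excluded.add(tuple(res.codeword))
    return last
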