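"""Scripted simulation experiments: code-alphabet selection, constructed
error-capability probes, and depth sweeps comparing hard- and soft-decision
decoding.

These drive the same library API a user would: encode a seeded random
payload, push it through the multinomial channel at a given depth, build a
transition library at that depth, and decode.  Fixture construction for the
capability probes perturbs observed counts toward a wrong letter whose
transition row ranks the true letter first, guaranteeing (a) an inference
error at the chosen positions, (b) that those positions rank worst by
reliability distance, and (c) that the true letter sits in the alternative
set — the regime in which the soft decoder's extended correction capability
is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .alphabet import (
    CompositeAlphabet,
    enumerate_full_alphabet,
    select_low_error_subset,
)
from .channel import ChannelParams, base_distribution_matrix, simulate_counts_array
from .codec import MatrixLayout, decode_counts, encode_bytes
from .inference import infer_symbols
from .rscode import RSSpec, get_codec
from .softdecode import (
    BlockEvidence,
    SearchLimits,
    decode_block_validated,
    position_alternatives,
)
from .translib import TransitionLibrary, get_library


def child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def build_code_alphabet(
    k_res: int,
    size: int,
    depth_N: int,
    p_error: float = 0.01,
    selection_draws: int = 4_000,
    seed: int = 0,
) -> CompositeAlphabet:
    """Select the ``size`` lowest-error letters of the full alphabet Phi_k.

    Error rates come from a transition library built on the full alphabet at
    the experiment's target depth (error rates are depth-dependent).  The
    selection library only feeds a ranking, so it uses fewer Monte-Carlo
    draws than a decoding library.
    """
    full = enumerate_full_alphabet(k_res)
    params = ChannelParams(p_error=p_error, depth_N=depth_N, seed=seed)
    lib = get_library(full, params, method="auto", n_draws=selection_draws)
    return select_low_error_subset(full, size, lib)


# ---------------------------------------------------------------------------
# constructed-error fixtures


def _round_counts(target: np.ndarray, depth: int) -> np.ndarray:
    """Largest-remainder rounding of depth * target onto integer counts."""
    raw = target * depth
    base = np.floor(raw).astype(np.int64)
    rem = depth - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def _wrong_letter_for(
    truth: int, library: TransitionLibrary, m: int
) -> int | None:
    """A source letter w != truth whose top alternative is the true letter
    (preferring the most probable such transition), so that substituting
    w's alternatives recovers the truth."""
    alt1 = library.alternative_symbols(1)[:, 0]
    sources = np.flatnonzero(alt1 == truth)
    sources = sources[sources != truth]
    if len(sources):
        return int(sources[np.argmax(library.matrix[truth, sources])])
    altm = library.alternative_symbols(m)
    sources = [w for w in range(len(library.alphabet)) if w != truth and truth in altm[w]]
    if sources:
        return int(max(sources, key=lambda w: library.matrix[truth, w]))
    return None


def build_error_fixture(
    truth_word: np.ndarray,
    alphabet: CompositeAlphabet,
    library: TransitionLibrary,
    params: ChannelParams,
    e: int,
    rng: np.random.Generator,
    m: int = 2,
    max_retries: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts for one RS block with exactly ``e`` constructed letter errors.

    Non-error positions carry channel-sampled counts that infer correctly;
    error positions carry counts blended from the true letter toward a
    wrong letter w just far enough that MAP inference flips to w.  Sitting
    near the decision boundary makes these the least reliable positions of
    the block, and w is chosen so its top library alternative is the truth.

    Returns (counts (n, 4), error_positions).
    """
    n = len(truth_word)
    q = base_distribution_matrix(alphabet, params.p_error)
    for _ in range(max_retries):
        counts = simulate_counts_array(truth_word, alphabet, params, rng=rng)
        inferred = infer_symbols(counts, alphabet, params.p_error)
        clean = np.flatnonzero(inferred == truth_word)
        if len(clean) < n:  # re-draw naturally erroneous positions
            for pos in np.flatnonzero(inferred != truth_word):
                for _ in range(50):
                    counts[pos] = rng.multinomial(
                        params.depth_N, q[truth_word[pos]]
                    )
                    if infer_symbols(counts[pos : pos + 1], alphabet, params.p_error)[0] == truth_word[pos]:
                        break
                else:
                    counts[pos] = _round_counts(q[truth_word[pos]], params.depth_N)
        err_pos = rng.choice(n, size=e, replace=False) if e else np.array([], dtype=int)
        ok = True
        for pos in err_pos:
            t = int(truth_word[pos])
            w = _wrong_letter_for(t, library, m)
            if w is None:
                ok = False
                break
            placed = False
            for lam in np.arange(0.50, 1.0001, 0.02):
                blend = (1 - lam) * q[t] + lam * q[w]
                x = _round_counts(blend / blend.sum(), params.depth_N)
                if infer_symbols(x[None, :], alphabet, params.p_error)[0] == w:
                    counts[pos] = x
                    placed = True
                    break
            if not placed:
                counts[pos] = _round_counts(q[w], params.depth_N)
        if not ok:
            continue
        if e:
            ev = BlockEvidence.from_counts(counts, alphabet, params.p_error)
            # clean positions must rank below every constructed error; re-draw
            # unlucky clean draws (the fixture's defining property is the
            # ranking, not any particular clean realisation)
            threshold = float(ev.distances[err_pos].min())
            err_set = set(int(i) for i in err_pos)
            for pos in range(n):
                if pos in err_set or ev.distances[pos] < threshold:
                    continue
                for _ in range(50):
                    counts[pos] = rng.multinomial(params.depth_N, q[truth_word[pos]])
                    sub = BlockEvidence.from_counts(
                        counts[pos : pos + 1], alphabet, params.p_error
                    )
                    if (
                        sub.symbols[0] == truth_word[pos]
                        and sub.distances[0] < threshold
                    ):
                        break
                else:
                    counts[pos] = _round_counts(q[truth_word[pos]], params.depth_N)
            ev = BlockEvidence.from_counts(counts, alphabet, params.p_error)
            order = np.lexsort((np.arange(n), -ev.distances))
            if set(int(i) for i in order[:e]) != set(int(i) for i in err_pos):
                continue  # a clean position out-ranked an error: resample
            if np.any(ev.symbols[err_pos] == truth_word[err_pos]):
                continue
            alt_sets = position_alternatives(ev, library, m)
            if any(
                int(truth_word[pos]) not in (a for a, _ in alt_sets[pos])
                for pos in err_pos
            ):
                continue  # truth must sit in the alternative set
        return counts, np.sort(err_pos)
    raise RuntimeError(
        f"could not construct a {e}-error fixture within {max_retries} retries"
    )


def run_capability_probe(
    spec: RSSpec,
    alphabet: CompositeAlphabet,
    library: TransitionLibrary,
    limits: SearchLimits,
    e: int,
    n_fixtures: int = 50,
    seed: int = 0,
) -> float:
    """Fraction of constructed ``e``-error blocks the soft decoder recovers
    exactly (decoded to the true codeword)."""
    if not 0 <= e <= spec.n_code:
        raise ValueError("error count must lie in [0, n_code]")
    params = ChannelParams(
        p_error=library.p_error, depth_N=library.depth_N, seed=seed
    )
    codec = get_codec(spec)
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_fixtures):
        info = [int(s) for s in rng.integers(0, spec.field_order, spec.k_info)]
        truth = np.asarray(codec.encode(info), dtype=np.int64)
        counts, _ = build_error_fixture(
            truth, alphabet, library, params, e, rng, m=limits.max_alternatives
        )
        ev = BlockEvidence.from_counts(counts, alphabet, params.p_error)
        res = decode_block_validated(ev, library, spec, limits)
        if res.status == "decoded" and res.codeword == [int(s) for s in truth]:
            ok += 1
    return ok / n_fixtures


def max_correctable_errors(
    spec: RSSpec,
    alphabet: CompositeAlphabet,
    library: TransitionLibrary,
    limits: SearchLimits,
    n_fixtures: int = 50,
    seed: int = 0,
    e_max: int | None = None,
) -> int:
    """Largest e for which every constructed e-error fixture decodes."""
    if e_max is None:
        e_max = limits.max_positions
    best = 0
    for e in range(1, e_max + 1):
        rate = run_capability_probe(
            spec, alphabet, library, limits, e, n_fixtures, seed
        )
        if rate == 1.0:
            best = e
        else:
            break
    return best


# ---------------------------------------------------------------------------
# depth sweeps


@dataclass(frozen=True)
class ExperimentConfig:
    """One sweep: an alphabet, a list of depths, and decode modes."""

    k_res: int
    alphabet_size: int
    depths: tuple[int, ...]
    p_error: float = 0.01
    matrices: int = 20
    seed: int = 0
    modes: tuple[str, ...] = ("hard", "soft")
    limits: SearchLimits = dc_field(default_factory=SearchLimits)
    library_draws: int = 20_000
    selection_draws: int = 4_000
    rs_spec: RSSpec | None = None

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.depths):
            raise ValueError("all depths must be >= 1")
        if self.matrices < 1:
            raise ValueError("need at least one matrix")


def payload_for_matrices(layout: MatrixLayout, n_matrices: int, seed: int) -> bytes:
    """A seeded pseudo-random payload filling exactly ``n_matrices``."""
    n_bytes = (n_matrices * layout.payload_bits_per_matrix) // 8 - 4
    rng = np.random.default_rng(seed)
    return rng.integers(0, 256, n_bytes, dtype=np.uint8).tobytes()


def run_depth_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Tabulate failed matrices and accuracy metrics per (depth, mode)."""
    rs_spec = config.rs_spec or RSSpec(field_order=config.alphabet_size)
    rows = []
    master = np.random.default_rng(config.seed)
    for depth in config.depths:
        alphabet = build_code_alphabet(
            config.k_res,
            config.alphabet_size,
            depth,
            config.p_error,
            config.selection_draws,
            seed=child_seed(master),
        )
        layout = MatrixLayout(alphabet=alphabet, rs_spec=rs_spec)
        lib_params = ChannelParams(
            p_error=config.p_error, depth_N=depth, seed=child_seed(master)
        )
        library = get_library(
            alphabet, lib_params, method="monte_carlo", n_draws=config.library_draws
        )
        payload = payload_for_matrices(layout, config.matrices, child_seed(master))
        truth = encode_bytes(payload, layout)
        chan = ChannelParams(
            p_error=config.p_error, depth_N=depth, seed=child_seed(master)
        )
        counts = simulate_counts_array(truth.reshape(-1), alphabet, chan)
        for mode in config.modes:
            decoded, report = decode_counts(
                counts,
                layout,
                library=library,
                limits=config.limits,
                mode=mode,
                ground_truth=truth,
            )
            rows.append(
                {
                    "alphabet_size": config.alphabet_size,
                    "k": config.k_res,
                    "depth": depth,
                    "mode": mode,
                    "matrices": report.matrices_total,
                    "failed_matrices": report.matrices_failed,
                    "payload_recovered": decoded == payload,
                    "letter_inference_accuracy": report.letter_inference_accuracy,
                    "position_prediction_accuracy": report.position_prediction_accuracy,
                    "true_letter_prediction_accuracy": report.true_letter_prediction_accuracy,
                    "blocks_soft_decoded": report.blocks_soft_decoded,
                    "decoder_errors_detected": report.decoder_errors_detected,
                }
            )
    return pd.DataFrame(rows)
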