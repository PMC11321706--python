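"""MAP inference of composite letters from observed base counts.

With a uniform prior over the alphabet, the posterior argmax reduces to the
likelihood argmax.  The default score is the multinomial log-likelihood

    log P(X | sigma) ~ sum_i X_i log q_i(sigma)          (constants dropped)

where q(sigma) is the channel's expected base distribution.  An exact mode
scores sum_i log C(F_i, X_i) with per-base copy numbers F_i = f * q_i for a
finite effective molecule count f; as f -> infinity the two argmaxes agree,
and the multinomial form is the primary implementation.

Reliability of a call is the Euclidean distance between the normalised
observation X/N and the called letter's mixture sigma/k; large distances
mark candidate error positions for the soft-decision decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .alphabet import CompositeAlphabet, CompositeLetter
from .channel import (
    ObservedCounts,
    base_distribution_matrix,
    expected_base_distribution,
)

#: Alphabet size at or above which infer_letter switches to the pruned
#: extremum-based fast path.  Exhaustive scoring remains the oracle.
FAST_PATH_MIN_SIZE = 128

#: Number of nearest lattice letters scored exactly on the fast path.
FAST_PATH_CANDIDATES = 5


@dataclass(frozen=True)
class LetterCall:
    """An inferred letter with its ranked runner-ups and reliability."""

    inferred: CompositeLetter
    candidates: tuple[tuple[CompositeLetter, float], ...]
    distance: float


def log_score(
    X: ObservedCounts,
    letter: CompositeLetter,
    p_error: float,
    exact_copy_scale: float | None = None,
) -> float:
    """Log-likelihood of the counts under one letter.

    Default: multinomial form sum_i X_i log q_i (letter-independent terms
    dropped).  With ``exact_copy_scale`` = f, the finite-copy binomial
    product sum_i log C(F_i, X_i), F_i = f * q_i, evaluated via log-gamma.
    Zero-probability bases observed with positive counts score -inf.
    """
    q = expected_base_distribution(letter, p_error)
    x = np.asarray(X.counts, dtype=float)
    if exact_copy_scale is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(x > 0, x * np.log(q), 0.0)
        return float(terms.sum())
    F = exact_copy_scale * q
    if np.any(x > F):
        return float("-inf")
    # log C(F, x) with real-valued F via gamma functions
    return float(
        (gammaln(F + 1) - gammaln(x + 1) - gammaln(F - x + 1)).sum()
    )


def reliability_distance(X: ObservedCounts, letter: CompositeLetter) -> float:
    """Euclidean distance between X/N and sigma/k (both on the simplex)."""
    return float(np.linalg.norm(X.frequencies - letter.fractions))


def _score_matrix(
    counts: np.ndarray, alphabet: CompositeAlphabet, p_error: float
) -> np.ndarray:
    """(n_obs, |alphabet|) multinomial log-score matrix."""
    q = base_distribution_matrix(alphabet, p_error)
    with np.errstate(divide="ignore"):
        logq = np.log(q)
    logq[np.isneginf(logq)] = -1e30  # finite stand-in; only reached at p=0
    return counts @ logq.T


def infer_symbols(
    counts: np.ndarray, alphabet: CompositeAlphabet, p_error: float
) -> np.ndarray:
    """Vectorised exhaustive MAP over an (n_obs, 4) count array.

    Returns the (n_obs,) array of alphabet symbol indices.  Ties resolve to
    the first letter in alphabet order (deterministic).
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.shape[0]
    L = len(alphabet)
    # chunk so the intermediate score matrix stays modest in memory
    chunk = max(1, int(5e7) // max(L, 1))
    if n <= chunk:
        return np.argmax(_score_matrix(counts, alphabet, p_error), axis=1)
    out = np.empty(n, dtype=np.int64)
    for start in range(0, n, chunk):
        block = counts[start : start + chunk]
        out[start : start + chunk] = np.argmax(
            _score_matrix(block, alphabet, p_error), axis=1
        )
    return out


def batch_distances(
    counts: np.ndarray, symbols: np.ndarray, alphabet: CompositeAlphabet
) -> np.ndarray:
    """Reliability distances for already-called positions."""
    counts = np.asarray(counts, dtype=float)
    depth = counts.sum(axis=1, keepdims=True)
    freq = counts / depth
    frac = alphabet.ratio_matrix() / alphabet.k_res
    return np.linalg.norm(freq - frac[symbols], axis=1)


def _extremum_candidates(
    X: ObservedCounts, alphabet: CompositeAlphabet, p_error: float, n: int
) -> np.ndarray:
    """Indices of the ``n`` letters nearest the continuous likelihood extremum.

    The unconstrained maximiser of the multinomial score over mixture
    fractions is sigma_hat/k proportional to max(0, (X/N - p/3)/(1 - 4p/3)),
    i.e. the observed frequencies with the uniform error floor removed.
    """
    f = X.frequencies
    adj = np.maximum(0.0, (f - p_error / 3.0) / max(1.0 - 4.0 * p_error / 3.0, 1e-12))
    total = adj.sum()
    target = adj / total if total > 0 else np.full(4, 0.25)
    frac = alphabet.ratio_matrix() / alphabet.k_res
    d2 = ((frac - target) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")
    return order[:n]


def infer_letter(
    X: ObservedCounts,
    alphabet: CompositeAlphabet,
    p_error: float,
    n_candidates: int = 5,
    exhaustive: bool | None = None,
) -> LetterCall:
    """MAP call of a single position with ranked candidates.

    Exhaustive scoring over the whole alphabet is the default for small
    alphabets and always available as the oracle (``exhaustive=True``).  For
    |alphabet| >= 128 the default path prunes to the letters nearest the
    continuous likelihood extremum and scores those exactly, mirroring the
    extremum-then-neighbourhood search that makes large alphabets cheap.

    Ties on the log-score break by smaller reliability distance, then by
    alphabet order.
    """
    if X.depth_N < 1:
        raise ValueError("cannot infer a letter from zero reads")
    if exhaustive is None:
        exhaustive = len(alphabet) < FAST_PATH_MIN_SIZE
    if exhaustive:
        pool = np.arange(len(alphabet))
    else:
        pool = _extremum_candidates(
            X, alphabet, p_error, max(FAST_PATH_CANDIDATES, n_candidates)
        )
    scored = []
    for idx in pool:
        letter = alphabet[int(idx)]
        s = log_score(X, letter, p_error)
        scored.append((-s, reliability_distance(X, letter), int(idx), letter, s))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    top = scored[:n_candidates]
    candidates = tuple((letter, s) for _, _, _, letter, s in top)
    best = candidates[0][0]
    return LetterCall(
        inferred=best,
        candidates=candidates,
        distance=reliability_distance(X, best),
    )


def inference_accuracy(
    true_symbols: np.ndarray,
    counts: np.ndarray,
    alphabet: CompositeAlphabet,
    p_error: float,
) -> float:
    """Fraction of positions whose MAP call matches the true letter."""
    called = infer_symbols(counts, alphabet, p_error)
    return float(np.mean(called == np.asarray(true_symbols)))
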