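"""Letter transition libraries.

For a fixed alphabet, depth N and per-base error rate, the transition
library tabulates, for every source letter sigma_i, the probability that
MAP inference on channel-sampled counts returns each target letter
sigma_j*.  Its diagonal complement is the per-letter error rate; its
off-diagonal ranking supplies the alternative letter sets the soft-decision
decoder substitutes at unreliable positions.

Two constructions are provided.  The exact build enumerates every possible
count vector (C(N+3, 3) of them) and sums multinomial probabilities per
inferred target — feasible at small depths.  The Monte-Carlo build
estimates the same table from seeded simulated draws and is the practical
route at the large depths the codec operates at (e.g. N = 490).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .alphabet import CompositeAlphabet, CompositeLetter
from .channel import ChannelParams, base_distribution_matrix
from .inference import infer_symbols

#: Exact-build feasibility guard: number of (observation, letter) pairs scored.
EXACT_GUARD = 10**8

#: Default Monte-Carlo draws per source letter.  Transition probabilities
#: feed a ranking, not a precise estimate, so modest sampling suffices.
DEFAULT_MC_DRAWS = 20_000


def enumerate_observations(depth_N: int) -> np.ndarray:
    """All 4-part compositions of ``depth_N`` as an (M, 4) array,
    descending lexicographic, M = C(N+3, 3)."""
    if depth_N < 0:
        raise ValueError("depth must be >= 0")
    rows = []
    for a in range(depth_N, -1, -1):
        for c in range(depth_N - a, -1, -1):
            for g in range(depth_N - a - c, -1, -1):
                rows.append((a, c, g, depth_N - a - c - g))
    return np.asarray(rows, dtype=np.int64)


@dataclass(frozen=True)
class TransitionLibrary:
    """Per-letter error rates and ranked transition probabilities."""

    alphabet: CompositeAlphabet
    depth_N: int
    p_error: float
    matrix: np.ndarray  # (L, L) row-stochastic: P(inferred j | true i)
    method: str  # "exact" | "monte_carlo"
    n_draws: int | None = None
    seed: int | None = None

    @property
    def k_res(self) -> int:
        return self.alphabet.k_res

    def row(self, letter: CompositeLetter) -> np.ndarray:
        return self.matrix[self.alphabet.index_of(letter)]

    def error_rate(self, letter: CompositeLetter) -> float:
        i = self.alphabet.index_of(letter)
        return float(1.0 - self.matrix[i, i])

    def ranked_targets(
        self, letter: CompositeLetter
    ) -> list[tuple[CompositeLetter, float]]:
        """All targets by descending probability (ties: alphabet order)."""
        row = self.row(letter)
        order = np.argsort(-row, kind="stable")
        return [(self.alphabet[int(j)], float(row[j])) for j in order]

    def alternatives(
        self, letter: CompositeLetter, m: int = 2
    ) -> list[CompositeLetter]:
        """Top-``m`` correction candidates for an *inferred* letter.

        Ranked by the probability of transitioning *into* the inferred
        letter, i.e. P(inferred = letter | true = source) descending over
        sources != letter: given that inference returned this letter, these
        are the letters most likely to have been stored.
        """
        if letter not in self.alphabet:
            raise KeyError(f"letter {letter} not in library alphabet")
        if m <= 0:
            return []
        j = self.alphabet.index_of(letter)
        col = self.matrix[:, j].copy()
        col[j] = -1.0
        order = np.argsort(-col, kind="stable")
        return [self.alphabet[int(i)] for i in order[:m]]

    def alternative_symbols(self, m: int = 2) -> np.ndarray:
        """(L, m) matrix: row j = top-m alternative sources for inferred
        letter j, ranked by descending transition probability into j."""
        masked = self.matrix.copy()
        np.fill_diagonal(masked, -1.0)
        order = np.argsort(-masked, axis=0, kind="stable")
        return order[:m].T

    def to_json(self) -> str:
        rows = []
        for i in range(len(self.alphabet)):
            order = np.argsort(-self.matrix[i], kind="stable")
            rows.append(
                [[int(j), float(self.matrix[i, j])] for j in order if self.matrix[i, j] > 0]
            )
        return json.dumps(
            {
                "k": self.k_res,
                "N": self.depth_N,
                "p_error": self.p_error,
                "method": self.method,
                "n_draws": self.n_draws,
                "seed": self.seed,
                "alphabet": [list(l.ratios) for l in self.alphabet],
                "rows": rows,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TransitionLibrary":
        obj = json.loads(text)
        k = int(obj["k"])
        alphabet = CompositeAlphabet(
            k_res=k,
            letters=tuple(
                CompositeLetter(tuple(int(x) for x in r), k) for r in obj["alphabet"]
            ),
        )
        L = len(alphabet)
        matrix = np.zeros((L, L))
        for i, row in enumerate(obj["rows"]):
            for j, p in row:
                matrix[i, int(j)] = p
        return cls(
            alphabet=alphabet,
            depth_N=int(obj["N"]),
            p_error=float(obj["p_error"]),
            matrix=matrix,
            method=obj["method"],
            n_draws=obj.get("n_draws"),
            seed=obj.get("seed"),
        )


def _multinomial_logpmf(counts: np.ndarray, q: np.ndarray) -> np.ndarray:
    """(M,) log pmf of each count row under base distribution q."""
    N = counts.sum(axis=1)
    coeff = gammaln(N + 1) - gammaln(counts + 1).sum(axis=1)
    with np.errstate(divide="ignore"):
        logq = np.log(q)
    logq = np.where(np.isneginf(logq), -1e30, logq)
    return coeff + counts @ logq


def build_library_exact(
    alphabet: CompositeAlphabet, params: ChannelParams
) -> TransitionLibrary:
    """Exact transition table by enumerating every observable count vector."""
    L = len(alphabet)
    M = math.comb(params.depth_N + 3, 3)
    if M * L > EXACT_GUARD:
        raise ValueError(
            f"exact enumeration would score {M * L:.2e} pairs "
            f"(> {EXACT_GUARD:.0e}); use build_library_mc at this depth"
        )
    obs = enumerate_observations(params.depth_N)
    inferred = infer_symbols(obs, alphabet, params.p_error)
    q = base_distribution_matrix(alphabet, params.p_error)
    matrix = np.zeros((L, L))
    for i in range(L):
        probs = np.exp(_multinomial_logpmf(obs, q[i]))
        matrix[i] = np.bincount(inferred, weights=probs, minlength=L)
    # enumeration is complete, so rows sum to 1 up to float roundoff
    matrix /= matrix.sum(axis=1, keepdims=True)
    return TransitionLibrary(
        alphabet=alphabet,
        depth_N=params.depth_N,
        p_error=params.p_error,
        matrix=matrix,
        method="exact",
    )


def build_library_mc(
    alphabet: CompositeAlphabet,
    params: ChannelParams,
    n_draws: int = DEFAULT_MC_DRAWS,
) -> TransitionLibrary:
    """Monte-Carlo transition table from seeded channel draws."""
    if n_draws < 1_000:
        raise ValueError("need at least 1000 draws per letter")
    L = len(alphabet)
    rng = params.rng()
    q = base_distribution_matrix(alphabet, params.p_error)
    matrix = np.zeros((L, L))
    for i in range(L):
        draws = rng.multinomial(params.depth_N, q[i], size=n_draws)
        inferred = infer_symbols(draws, alphabet, params.p_error)
        matrix[i] = np.bincount(inferred, minlength=L) / n_draws
    return TransitionLibrary(
        alphabet=alphabet,
        depth_N=params.depth_N,
        p_error=params.p_error,
        matrix=matrix,
        method="monte_carlo",
        n_draws=n_draws,
        seed=params.seed,
    )


_CACHE: dict[tuple, TransitionLibrary] = {}


def get_library(
    alphabet: CompositeAlphabet,
    params: ChannelParams,
    method: str = "auto",
    n_draws: int = DEFAULT_MC_DRAWS,
) -> TransitionLibrary:
    """Build (or fetch from the in-process cache) a transition library.

    ``method='auto'`` uses the exact build when the enumeration guard allows
    it and Monte-Carlo otherwise.  Library builds dominate runtime, so they
    are cached by (alphabet, N, p_error, method, n_draws, seed).
    """
    M = math.comb(params.depth_N + 3, 3)
    if method == "auto":
        method = "exact" if M * len(alphabet) <= EXACT_GUARD else "monte_carlo"
    alpha_hash = hashlib.sha256(alphabet.to_json().encode()).hexdigest()[:16]
    key = (
        alpha_hash,
        params.depth_N,
        params.p_error,
        method,
        n_draws if method == "monte_carlo" else None,
        params.seed if method == "monte_carlo" else None,
    )
    if key not in _CACHE:
        if method == "exact":
            _CACHE[key] = build_library_exact(alphabet, params)
        else:
            _CACHE[key] = build_library_mc(alphabet, params, n_draws)
    return _CACHE[key]
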