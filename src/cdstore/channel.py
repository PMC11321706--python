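"""Synthesis/storage/sequencing channel model.

A stored composite letter sigma is read back as a vector of base counts
X = (X_A, X_C, X_G, X_T) summing to the sequencing depth N.  Two effects
shape X: multinomial sampling of reads from the mixture, and a lumped
per-base substitution-style error rate p_error that moves a fraction of
each base's probability mass uniformly onto the other three bases:

    q_i = (sigma_i / k) * (1 - p_error) + (p_error / 3) * (1 - sigma_i / k)

Positions are sampled independently; indels are not modelled separately
(the per-base rate lumps all error types).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import BASES, CompositeAlphabet, CompositeLetter


@dataclass(frozen=True)
class ChannelParams:
    """Channel configuration.

    p_error      per-base error probability (default 0.01, the rate the
                 simulation study assumes).
    depth_N      reads sampled per position.
    copy_scale_f effective molecule count; used only by the exact
                 binomial-product likelihood oracle, where per-base copy
                 numbers are F_i = copy_scale_f * q_i.
    seed         RNG seed for reproducible sampling.
    """

    p_error: float = 0.01
    depth_N: int = 10
    copy_scale_f: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_error < 1.0:
            raise ValueError("p_error must lie in [0, 1)")
        if self.depth_N < 0:
            raise ValueError("depth_N must be >= 0")
        if self.copy_scale_f < self.depth_N:
            raise ValueError("copy_scale_f must be >= depth_N")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class ObservedCounts:
    """Per-position observed base counts at a given depth."""

    counts: tuple[int, int, int, int]
    depth_N: int

    def __post_init__(self) -> None:
        if len(self.counts) != 4 or any(c < 0 for c in self.counts):
            raise ValueError("counts must be 4 non-negative integers")
        if sum(self.counts) != self.depth_N:
            raise ValueError(
                f"counts {self.counts} must sum to the depth {self.depth_N}"
            )

    @property
    def frequencies(self) -> np.ndarray:
        if self.depth_N == 0:
            raise ValueError("no reads observed: frequencies undefined at depth 0")
        return np.asarray(self.counts, dtype=float) / self.depth_N

    def __str__(self) -> str:
        return "[" + ",".join(str(c) for c in self.counts) + "]"


def expected_base_distribution(
    letter: CompositeLetter, p_error: float
) -> np.ndarray:
    """Probability of observing each base in one read of ``letter``.

    q_i = (sigma_i/k)(1 - p) + (p/3)(1 - sigma_i/k); sums to 1 exactly.
    When p > 0 every component is positive, so no observation has zero
    probability under any letter.
    """
    frac = letter.fractions
    return frac * (1.0 - p_error) + (p_error / 3.0) * (1.0 - frac)


def base_distribution_matrix(
    alphabet: CompositeAlphabet, p_error: float
) -> np.ndarray:
    """(|alphabet|, 4) matrix of expected base distributions."""
    frac = alphabet.ratio_matrix() / alphabet.k_res
    return frac * (1.0 - p_error) + (p_error / 3.0) * (1.0 - frac)


def sample_observed(
    letter: CompositeLetter,
    params: ChannelParams,
    rng: np.random.Generator | None = None,
) -> ObservedCounts:
    """One multinomial draw of ``depth_N`` reads for a single letter."""
    if rng is None:
        rng = params.rng()
    q = expected_base_distribution(letter, params.p_error)
    counts = rng.multinomial(params.depth_N, q)
    return ObservedCounts(tuple(int(c) for c in counts), params.depth_N)


def sample_observed_many(
    letter: CompositeLetter,
    params: ChannelParams,
    n: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """(n, 4) array of independent count draws for one letter."""
    if rng is None:
        rng = params.rng()
    q = expected_base_distribution(letter, params.p_error)
    return rng.multinomial(params.depth_N, q, size=n)


def simulate_sequence(
    letters: Sequence[CompositeLetter],
    params: ChannelParams,
    rng: np.random.Generator | None = None,
) -> list[ObservedCounts]:
    """Independent per-position sampling of a letter sequence."""
    if rng is None:
        rng = params.rng()
    out = []
    for letter in letters:
        q = expected_base_distribution(letter, params.p_error)
        counts = rng.multinomial(params.depth_N, q)
        out.append(ObservedCounts(tuple(int(c) for c in counts), params.depth_N))
    return out


def simulate_counts_array(
    symbols: np.ndarray,
    alphabet: CompositeAlphabet,
    params: ChannelParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorised channel: (L,) symbol indices -> (L, 4) count array."""
    if rng is None:
        rng = params.rng()
    q = base_distribution_matrix(alphabet, params.p_error)[symbols]
    return rng.multinomial(params.depth_N, q)


def counts_to_frame(counts: np.ndarray | Sequence[ObservedCounts]) -> pd.DataFrame:
    """Counts as a table with 0-based positions and one base per column."""
    if not isinstance(counts, np.ndarray):
        counts = np.asarray([c.counts for c in counts], dtype=np.int64)
    df = pd.DataFrame(counts, columns=list(BASES))
    df.insert(0, "pos", np.arange(len(df)))
    return df


def write_counts_tsv(
    counts: np.ndarray | Sequence[ObservedCounts], path
) -> None:
    counts_to_frame(counts).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> np.ndarray:
    """(L, 4) count array from a `pos A C G T` TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [b for b in BASES if b not in df.columns]
    if missing:
        raise ValueError(f"counts table missing base columns {missing}")
    if "pos" in df.columns:
        df = df.sort_values("pos")
    return df[list(BASES)].to_numpy(dtype=np.int64)


def reads_fasta(
    counts: np.ndarray,
    seq_id: str = "seq0",
) -> str:
    """Render a counts table as per-read FASTA.

    Each simulated read is one standard-nucleotide realisation per position
    with exact positional correspondence (no alignment step): read r at
    position p carries the r-th base of the multiset given by the counts.
    """
    counts = np.asarray(counts, dtype=np.int64)
    depth = int(counts[0].sum()) if len(counts) else 0
    if len(counts) and not (counts.sum(axis=1) == depth).all():
        raise ValueError("per-read FASTA export requires uniform depth")
    lines = []
    for r in range(depth):
        seq = []
        for row in counts:
            c = np.cumsum(row)
            seq.append(BASES[int(np.searchsorted(c, r, side="right"))])
        lines.append(f">sim_{seq_id}_{r}")
        lines.append("".join(seq))
    return "\n".join(lines) + ("\n" if lines else "")
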