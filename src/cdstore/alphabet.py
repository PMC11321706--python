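"""Composite DNA letter alphabets.

A composite letter is a position-level mixture of the four nucleotides in a
fixed integer ratio sigma = (sigma_A, sigma_C, sigma_G, sigma_T).  The
resolution k is the sum of the four components; the full alphabet Phi_k of
resolution k contains every 4-part composition of k, C(k+3, 3) letters in
total.  Large power-of-two subsets (64, 128, 256) chosen for low letter
error rate serve as code alphabets for the byte codec.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .translib import TransitionLibrary

BASES = ("A", "C", "G", "T")

#: IUPAC ambiguity codes for the k=2 mixed letters (M = A/C, K = G/T, ...).
IUPAC_K2 = {
    (1, 1, 0, 0): "M",
    (1, 0, 1, 0): "R",
    (1, 0, 0, 1): "W",
    (0, 1, 1, 0): "S",
    (0, 1, 0, 1): "Y",
    (0, 0, 1, 1): "K",
}


@dataclass(frozen=True, order=True)
class CompositeLetter:
    """An integer nucleotide-mixture ratio with resolution ``k_res``."""

    ratios: tuple[int, int, int, int]
    k_res: int

    def __post_init__(self) -> None:
        if len(self.ratios) != 4:
            raise ValueError("a composite letter has exactly 4 ratio parts")
        if any(r < 0 for r in self.ratios):
            raise ValueError("ratio parts must be non-negative")
        if self.k_res < 1:
            raise ValueError("resolution k must be >= 1")
        if sum(self.ratios) != self.k_res:
            raise ValueError(
                f"ratio parts {self.ratios} must sum to the resolution {self.k_res}"
            )

    @property
    def fractions(self) -> np.ndarray:
        """The mixture as a probability vector sigma / k."""
        return np.asarray(self.ratios, dtype=float) / self.k_res

    def entropy(self) -> float:
        """Shannon entropy (nats) of the mixture proportions."""
        p = self.fractions
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    def ratio_string(self) -> str:
        return ",".join(str(r) for r in self.ratios)

    def iupac(self) -> str | None:
        """Single-character shorthand where unambiguous, else None."""
        if self.k_res == 1:
            return BASES[self.ratios.index(1)]
        if self.k_res == 2:
            if max(self.ratios) == 2:
                return BASES[self.ratios.index(2)]
            return IUPAC_K2.get(self.ratios)
        return None

    def __str__(self) -> str:
        return f"({self.ratio_string()})"


def _compositions(total: int, parts: int) -> Iterator[tuple[int, ...]]:
    """All ``parts``-tuples of non-negative ints summing to ``total``,
    lexicographically descending."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total, -1, -1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


@dataclass(frozen=True)
class CompositeAlphabet:
    """An ordered, indexed set of composite letters sharing one resolution."""

    k_res: int
    letters: tuple[CompositeLetter, ...]
    _index: dict[CompositeLetter, int] = field(
        init=False, repr=False, compare=False, hash=False
    )

    def __post_init__(self) -> None:
        if not self.letters:
            raise ValueError("alphabet must contain at least one letter")
        if any(l.k_res != self.k_res for l in self.letters):
            raise ValueError("all letters must share the alphabet resolution")
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("letters must be distinct")
        object.__setattr__(
            self, "_index", {l: i for i, l in enumerate(self.letters)}
        )

    def __len__(self) -> int:
        return len(self.letters)

    def __iter__(self) -> Iterator[CompositeLetter]:
        return iter(self.letters)

    def __getitem__(self, symbol: int) -> CompositeLetter:
        return self.letters[symbol]

    def index_of(self, letter: CompositeLetter) -> int:
        return self._index[letter]

    def __contains__(self, letter: CompositeLetter) -> bool:
        return letter in self._index

    def ratio_matrix(self) -> np.ndarray:
        """(|alphabet|, 4) integer matrix of letter ratios."""
        return np.asarray([l.ratios for l in self.letters], dtype=np.int64)

    def to_json(self) -> str:
        return json.dumps(
            {"k": self.k_res, "letters": [list(l.ratios) for l in self.letters]}
        )

    @classmethod
    def from_json(cls, text: str) -> "CompositeAlphabet":
        obj = json.loads(text)
        k = int(obj["k"])
        letters = tuple(
            CompositeLetter(tuple(int(x) for x in r), k) for r in obj["letters"]
        )
        return cls(k_res=k, letters=letters)


def full_alphabet_size(k_res: int) -> int:
    """|Phi_k| = C(k+3, 3)."""
    return math.comb(k_res + 3, 3)


def enumerate_full_alphabet(k_res: int) -> CompositeAlphabet:
    """The full composite alphabet Phi_k: every 4-part composition of k,
    in descending lexicographic order on (sigma_A, sigma_C, sigma_G, sigma_T).

    The ordering is fixed so serialized alphabets and symbol mappings are
    reproducible across runs.
    """
    if k_res < 1:
        raise ValueError("resolution k must be >= 1")
    letters = tuple(
        CompositeLetter(c, k_res) for c in _compositions(k_res, 4)
    )
    return CompositeAlphabet(k_res=k_res, letters=letters)


def select_low_error_subset(
    full: CompositeAlphabet, size: int, library: "TransitionLibrary"
) -> CompositeAlphabet:
    """The ``size`` letters of ``full`` with the smallest library error rate.

    The result is ordered by ascending error rate (ties broken by descending
    lexicographic ratio order, = the enumeration order) and re-indexed
    0..size-1, so the size-s subset is always a prefix of the size-(s+1)
    subset under the same library.
    """
    if size > len(full):
        raise ValueError(f"requested subset size {size} exceeds |alphabet| = {len(full)}")
    if library.k_res != full.k_res:
        raise ValueError("transition library resolution does not match the alphabet")
    ranked = sorted(
        full.letters,
        key=lambda l: (library.error_rate(l), tuple(-r for r in l.ratios)),
    )
    return CompositeAlphabet(k_res=full.k_res, letters=tuple(ranked[:size]))


def bits_per_letter(alphabet: CompositeAlphabet | int) -> int:
    """log2(|alphabet|) for power-of-two code alphabets.

    Non-power-of-two alphabets (e.g. the full Phi_6 of 84 letters) are
    first-class for simulation and inference but cannot back the byte codec.
    """
    size = alphabet if isinstance(alphabet, int) else len(alphabet)
    m = size.bit_length() - 1
    if size < 2 or (1 << m) != size:
        raise ValueError(
            f"alphabet size {size} is not a power of two and cannot map to whole bits"
        )
    return m
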