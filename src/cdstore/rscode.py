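"""Reed-Solomon codes over GF(2^m) with symbol = composite-letter index.

Systematic RS(n, k) encoding and hard-decision decoding via syndromes,
Berlekamp-Massey, Chien search and Forney's algorithm.  The archive layer
uses RS(45, 41), which corrects up to t = 2 symbol errors per block; the
supported code alphabets are the power-of-two composite alphabets of size
64, 128 and 256 (45 <= field_order - 1 in each case, so the code is a
shortened RS code over the matching field).

Decoding failure is a value, not an exception: with more than t errors the
decoder either reports failure or returns a *different* valid codeword (a
decoder error / miscorrection) — callers must treat success as unverified
and confirm it downstream (transition-library validation, CRC32).

Primitive polynomials are fixed per field for bit-exact reproducibility:
GF(8) x^3+x+1, GF(16) x^4+x+1, GF(32) x^5+x^2+1, GF(64) x^6+x+1,
GF(128) x^7+x^3+1, GF(256) x^8+x^4+x^3+x^2+1.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

PRIMITIVE_POLYS = {
    4: 0b111,          # GF(4):  x^2 + x + 1
    8: 0b1011,         # GF(8):  x^3 + x + 1
    16: 0b10011,       # GF(16): x^4 + x + 1
    32: 0b100101,      # GF(32): x^5 + x^2 + 1
    64: 0b1000011,     # GF(64): x^6 + x + 1
    128: 0b10001001,   # GF(128): x^7 + x^3 + 1
    256: 0b100011101,  # GF(256): x^8 + x^4 + x^3 + x^2 + 1
}


class GF:
    """Arithmetic in GF(2^m) via exp/log tables."""

    def __init__(self, order: int):
        if order not in PRIMITIVE_POLYS:
            raise ValueError(f"unsupported field order {order}")
        self.order = order
        self.prim_poly = PRIMITIVE_POLYS[order]
        n = order - 1
        self.exp = [0] * (2 * n)
        self.log = [0] * order
        x = 1
        for i in range(n):
            self.exp[i] = x
            self.log[x] = i
            x <<= 1
            if x & order:
                x ^= self.prim_poly
        for i in range(n, 2 * n):
            self.exp[i] = self.exp[i - n]

    def mul(self, a: int, b: int) -> int:
        if a == 0 or b == 0:
            return 0
        return self.exp[self.log[a] + self.log[b]]

    def div(self, a: int, b: int) -> int:
        if b == 0:
            raise ZeroDivisionError("division by zero in GF")
        if a == 0:
            return 0
        return self.exp[self.log[a] - self.log[b] + self.order - 1]

    def inv(self, a: int) -> int:
        if a == 0:
            raise ZeroDivisionError("zero has no inverse")
        return self.exp[self.order - 1 - self.log[a]]

    def pow_alpha(self, e: int) -> int:
        """alpha^e for any integer exponent."""
        return self.exp[e % (self.order - 1)]

    # -- polynomials: coefficient lists, highest degree first --

    def poly_mul(self, p: list[int], q: list[int]) -> list[int]:
        out = [0] * (len(p) + len(q) - 1)
        for i, a in enumerate(p):
            if a == 0:
                continue
            la = self.log[a]
            for j, b in enumerate(q):
                if b:
                    out[i + j] ^= self.exp[la + self.log[b]]
        return out

    def poly_eval(self, p: list[int], x: int) -> int:
        y = 0
        for c in p:
            y = self.mul(y, x) ^ c
        return y


@lru_cache(maxsize=None)
def get_field(order: int) -> GF:
    return GF(order)


@dataclass(frozen=True)
class RSSpec:
    """Code parameters: RS(n_code, k_info) over GF(field_order)."""

    field_order: int = 256
    n_code: int = 45
    k_info: int = 41

    def __post_init__(self) -> None:
        if self.n_code > self.field_order - 1:
            raise ValueError(
                f"RS length {self.n_code} exceeds field bound {self.field_order - 1}"
            )
        if not 0 < self.k_info < self.n_code:
            raise ValueError("need 0 < k_info < n_code")

    @property
    def t_correct(self) -> int:
        return (self.n_code - self.k_info) // 2

    @property
    def n_parity(self) -> int:
        return self.n_code - self.k_info


class RSCodec:
    """Encoder/decoder for one RSSpec.

    Generator polynomial g(x) = prod_{j=1..n_parity} (x - alpha^j); the
    first consecutive root is alpha^1 (classical narrow-sense convention).
    """

    def __init__(self, spec: RSSpec):
        self.spec = spec
        self.gf = get_field(spec.field_order)
        g = [1]
        for j in range(1, spec.n_parity + 1):
            g = self.gf.poly_mul(g, [1, self.gf.pow_alpha(j)])
        self.generator = g

    def encode(self, info: list[int]) -> list[int]:
        """Systematic codeword: info symbols then n_parity parity symbols."""
        spec, gf = self.spec, self.gf
        if len(info) != spec.k_info:
            raise ValueError(
                f"expected {spec.k_info} information symbols, got {len(info)}"
            )
        if any(not 0 <= s < spec.field_order for s in info):
            raise ValueError("symbols must be valid field elements")
        rem = list(info) + [0] * spec.n_parity
        g = self.generator
        for i in range(spec.k_info):
            coef = rem[i]
            if coef:
                lc = gf.log[coef]
                for j in range(1, len(g)):
                    if g[j]:
                        rem[i + j] ^= gf.exp[lc + gf.log[g[j]]]
        return list(info) + rem[spec.k_info :]

    def syndromes(self, word: list[int]) -> list[int]:
        """S_j = r(alpha^j) for j = 1..n_parity (all zero iff codeword)."""
        return [
            self.gf.poly_eval(word, self.gf.pow_alpha(j))
            for j in range(1, self.spec.n_parity + 1)
        ]

    def is_codeword(self, word: list[int]) -> bool:
        return all(s == 0 for s in self.syndromes(word))

    def decode(self, received: list[int]) -> tuple[list[int], int] | None:
        """Hard-decision decode: (codeword, n_corrected) or None on failure.

        With more than t symbol errors the return value may be a different
        valid codeword (decoder error); callers verify downstream.
        """
        spec, gf = self.spec, self.gf
        if len(received) != spec.n_code:
            raise ValueError(f"received word must have {spec.n_code} symbols")
        synd = self.syndromes(received)
        if all(s == 0 for s in synd):
            return list(received), 0

        # Berlekamp-Massey for the error locator Lambda(x) (lowest degree first)
        Lambda = [1]
        B = [1]
        Lb = 0
        mgap = 1
        b = 1
        for r in range(spec.n_parity):
            delta = synd[r]
            for i in range(1, len(Lambda)):
                if i <= r and Lambda[i]:
                    delta ^= gf.mul(Lambda[i], synd[r - i])
            if delta == 0:
                mgap += 1
            elif 2 * Lb <= r:
                T = list(Lambda)
                coef = gf.div(delta, b)
                shifted = [0] * mgap + [gf.mul(coef, c) for c in B]
                Lambda = [
                    (Lambda[i] if i < len(Lambda) else 0)
                    ^ (shifted[i] if i < len(shifted) else 0)
                    for i in range(max(len(Lambda), len(shifted)))
                ]
                Lb = r + 1 - Lb
                B = T
                b = delta
                mgap = 1
            else:
                coef = gf.div(delta, b)
                shifted = [0] * mgap + [gf.mul(coef, c) for c in B]
                Lambda = [
                    (Lambda[i] if i < len(Lambda) else 0)
                    ^ (shifted[i] if i < len(shifted) else 0)
                    for i in range(max(len(Lambda), len(shifted)))
                ]
                mgap += 1
        while len(Lambda) > 1 and Lambda[-1] == 0:
            Lambda.pop()
        nu = len(Lambda) - 1
        if nu == 0 or nu > spec.t_correct:
            return None

        # Chien search restricted to the shortened length
        error_positions = []  # list indices (0 = first transmitted symbol)
        for i in range(spec.n_code):
            deg = spec.n_code - 1 - i
            x = gf.pow_alpha(-deg)  # alpha^{-deg}
            acc = 0
            xp = 1
            for c in Lambda:
                acc ^= gf.mul(c, xp)
                xp = gf.mul(xp, x)
            if acc == 0:
                error_positions.append(i)
        if len(error_positions) != nu:
            return None

        # Forney: Omega(x) = S(x) * Lambda(x) mod x^{n_parity}
        Omega = [0] * spec.n_parity
        for i, s in enumerate(synd):
            if s == 0:
                continue
            for j, c in enumerate(Lambda):
                if i + j < spec.n_parity and c:
                    Omega[i + j] ^= gf.mul(s, c)
        corrected = list(received)
        for i in error_positions:
            deg = spec.n_code - 1 - i
            x_inv = gf.pow_alpha(-deg)  # X_i^{-1}
            om = 0
            xp = 1
            for c in Omega:
                om ^= gf.mul(c, xp)
                xp = gf.mul(xp, x_inv)
            # Lambda'(x): odd-degree terms only (characteristic 2)
            lp = 0
            xp = 1
            x2 = gf.mul(x_inv, x_inv)
            for j in range(1, len(Lambda), 2):
                lp ^= gf.mul(Lambda[j], xp)
                xp = gf.mul(xp, x2)
            if lp == 0:
                return None
            corrected[i] ^= gf.div(om, lp)

        if not all(s == 0 for s in self.syndromes(corrected)):
            return None
        return corrected, nu


@lru_cache(maxsize=None)
def get_codec(spec: RSSpec) -> RSCodec:
    return RSCodec(spec)


def rs_encode(info: list[int], spec: RSSpec) -> list[int]:
    return get_codec(spec).encode(info)


def rs_decode_hard(received: list[int], spec: RSSpec) -> tuple[list[int], int] | None:
    return get_codec(spec).decode(received)
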