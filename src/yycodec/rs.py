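"""Byte-symbol Reed-Solomon codes over GF(2^8).

Systematic RS encoding/decoding with the usual primitive polynomial
x^8 + x^4 + x^3 + x^2 + 1 (0x11d).  A code with ``nsym`` parity bytes
corrects up to ``nsym // 2`` byte-symbol errors at unknown positions
(Berlekamp-Massey locator, Chien search, Forney magnitudes).  A
vectorised numpy path encodes and syndrome-checks whole pools of
equal-length messages at once; per-codeword correction runs only for
rows with non-zero syndromes, the rare path in practice.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rs_encode",
    "rs_decode",
    "rs_encode_matrix",
    "rs_syndromes_matrix",
    "RSDecodeError",
]

_PRIM = 0x11D

_EXP = np.zeros(512, dtype=np.int32)
_LOG = np.zeros(256, dtype=np.int32)
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= _PRIM
_EXP[255:510] = _EXP[:255]


class RSDecodeError(ValueError):
    """Codeword has more errors than the code can correct."""


def _mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return int(_EXP[_LOG[a] + _LOG[b]])


def _inv(a: int) -> int:
    if a == 0:
        raise ZeroDivisionError("GF inverse of zero")
    return int(_EXP[255 - _LOG[a]])


def _div(a: int, b: int) -> int:
    return _mul(a, _inv(b)) if a else 0


def _pow(a: int, n: int) -> int:
    return int(_EXP[(_LOG[a] * n) % 255]) if a else 0


def _poly_scale(p: list[int], s: int) -> list[int]:
    return [_mul(c, s) for c in p]


def _poly_add(p: list[int], q: list[int]) -> list[int]:
    r = [0] * max(len(p), len(q))
    r[len(r) - len(p):] = p
    for i, c in enumerate(q):
        r[i + len(r) - len(q)] ^= c
    return r


def _poly_mul(p: list[int], q: list[int]) -> list[int]:
    r = [0] * (len(p) + len(q) - 1)
    for i, pi in enumerate(p):
        if pi:
            for j, qj in enumerate(q):
                r[i + j] ^= _mul(pi, qj)
    return r


def _poly_eval(p: list[int], x: int) -> int:
    """Evaluate polynomial (highest-degree coefficient first) at x."""
    y = 0
    for c in p:
        y = _mul(y, x) ^ c
    return y


def _generator_poly(nsym: int) -> list[int]:
    g = [1]
    for i in range(nsym):
        g = _poly_mul(g, [1, _pow(2, i)])
    return g


_GEN_CACHE: dict[int, list[int]] = {}


def _gen(nsym: int) -> list[int]:
    if nsym not in _GEN_CACHE:
        _GEN_CACHE[nsym] = _generator_poly(nsym)
    return _GEN_CACHE[nsym]


def rs_encode(data: bytes | list[int], nsym: int) -> bytes:
    """Append ``nsym`` parity bytes to ``data`` (systematic encoding)."""
    if nsym < 1 or len(data) + nsym > 255:
        raise ValueError("require 1 <= nsym and len(data) + nsym <= 255")
    gen = _gen(nsym)
    msg = list(data) + [0] * nsym
    for i in range(len(data)):
        coef = msg[i]
        if coef:
            for j in range(1, len(gen)):
                msg[i + j] ^= _mul(gen[j], coef)
    return bytes(data) + bytes(msg[len(data):])


def _syndromes(msg: list[int], nsym: int) -> list[int]:
    return [_poly_eval(msg, _pow(2, i)) for i in range(nsym)]


def rs_decode(codeword: bytes | list[int], nsym: int) -> bytes:
    """Correct up to ``nsym // 2`` byte errors; return the data bytes.

    Raises :class:`RSDecodeError` when the error count exceeds the
    correction capacity; callers flag such frames as unrecoverable
    rather than passing corrupt data through.
    """
    msg = list(codeword)
    synd = _syndromes(msg, nsym)
    if max(synd) == 0:
        return bytes(msg[:-nsym])

    # Berlekamp-Massey: error locator polynomial (descending powers)
    err_loc = [1]
    old_loc = [1]
    for i in range(nsym):
        delta = synd[i]
        for j in range(1, len(err_loc)):
            delta ^= _mul(err_loc[-(j + 1)], synd[i - j])
        old_loc.append(0)
        if delta != 0:
            if len(old_loc) > len(err_loc):
                new_loc = _poly_scale(old_loc, delta)
                old_loc = _poly_scale(err_loc, _inv(delta))
                err_loc = new_loc
            err_loc = _poly_add(err_loc, _poly_scale(old_loc, delta))

    while err_loc and err_loc[0] == 0:
        err_loc = err_loc[1:]
    errs = len(err_loc) - 1
    if errs * 2 > nsym:
        raise RSDecodeError(f"{errs} errors exceed correction capacity {nsym // 2}")

    # Chien search: roots of the locator are alpha^{-p} for coefficient
    # positions p (counted from the right end of the codeword)
    n = len(msg)
    err_pos = []
    for j in range(255):
        if _poly_eval(err_loc, _pow(2, j)) == 0:
            p = (255 - j) % 255
            if p < n:
                err_pos.append(n - 1 - p)
    if len(err_pos) != errs:
        raise RSDecodeError("could not locate errors")

    # Forney: error magnitudes at the located positions
    coef_pos = [n - 1 - p for p in err_pos]
    # errata locator from known positions (product of (1 - x*alpha^i))
    errata_loc = [1]
    for i in coef_pos:
        errata_loc = _poly_mul(errata_loc, _poly_add([1], [_pow(2, i), 0]))
    # error evaluator: synd(x) * errata_loc(x) mod x^(errs+1)
    rev_synd = synd[::-1]
    prod = _poly_mul(rev_synd, errata_loc)
    err_eval = prod[len(prod) - (errs + 1):]

    x_vals = [_pow(2, i) for i in coef_pos]
    for i, xi in enumerate(x_vals):
        xi_inv = _inv(xi)
        loc_prime = 1
        for j, xj in enumerate(x_vals):
            if j != i:
                loc_prime = _mul(loc_prime, 1 ^ _mul(xi_inv, xj))
        if loc_prime == 0:
            raise RSDecodeError("degenerate errata locator")
        # e_i = Omega(X_i^-1) / prod_{j != i} (1 - X_j X_i^-1)
        msg[err_pos[i]] ^= _div(_poly_eval(err_eval, xi_inv), loc_prime)

    if max(_syndromes(msg, nsym)) != 0:
        raise RSDecodeError("correction failed verification")
    return bytes(msg[:-nsym])


# ---------------------------------------------------------------------------
# Vectorised pool paths
# ---------------------------------------------------------------------------

def _mul_vec(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise GF(256) product of two uint8 arrays."""
    out = np.zeros(np.broadcast_shapes(a.shape, b.shape), dtype=np.uint8)
    a, b = np.broadcast_arrays(a, b)
    nz = (a != 0) & (b != 0)
    out[nz] = _EXP[_LOG[a[nz].astype(np.int32)] + _LOG[b[nz].astype(np.int32)]]
    return out


def rs_encode_matrix(data: np.ndarray, nsym: int) -> np.ndarray:
    """Systematic RS encoding of an (n, k) byte matrix -> (n, k + nsym)."""
    data = np.atleast_2d(np.asarray(data, dtype=np.uint8))
    n, k = data.shape
    if nsym < 1 or k + nsym > 255:
        raise ValueError("require 1 <= nsym and k + nsym <= 255")
    gen = _gen(nsym)
    work = np.zeros((n, k + nsym), dtype=np.uint8)
    work[:, :k] = data
    for i in range(k):
        coef = work[:, i].copy()
        for j in range(1, nsym + 1):
            work[:, i + j] ^= _mul_vec(np.full(n, gen[j], dtype=np.uint8), coef)
    work[:, :k] = data
    return work


def rs_syndromes_matrix(codewords: np.ndarray, nsym: int) -> np.ndarray:
    """Syndromes of an (n, m) byte matrix -> (n, nsym); all-zero rows are clean."""
    cw = np.atleast_2d(np.asarray(codewords, dtype=np.uint8))
    n, m = cw.shape
    synd = np.empty((n, nsym), dtype=np.uint8)
    for i in range(nsym):
        alpha = np.full(n, _pow(2, i), dtype=np.uint8)
        acc = np.zeros(n, dtype=np.uint8)
        for col in range(m):
            acc = _mul_vec(acc, alpha) ^ cw[:, col]
        synd[:, i] = acc
    return synd
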