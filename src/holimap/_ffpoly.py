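"""Falling-factorial polynomial algebra.

The moment calculus used throughout the package works in the basis of
falling factorials ``(n)_h = n (n-1) ... (n-h+1)``: combinatorial
mass-action propensities are single falling-factorial terms and factorial
moments are expectations of falling-factorial products.  This module
provides the small exact-arithmetic helpers needed to expand products such
as ``(n)_h * (n + delta)_m`` back into the falling-factorial basis, and to
take expectations over geometric burst jumps.

All conversions go through the ordinary power basis using Stirling
numbers; degrees stay small (below ~20) so float arithmetic on the integer
coefficients is exact.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

_MAX_DEG = 32


@lru_cache(maxsize=1)
def _stirling2() -> np.ndarray:
    """Table of Stirling numbers of the second kind S(p, k)."""
    s = np.zeros((_MAX_DEG + 1, _MAX_DEG + 1))
    s[0, 0] = 1.0
    for p in range(1, _MAX_DEG + 1):
        for k in range(1, p + 1):
            s[p, k] = k * s[p - 1, k] + s[p - 1, k - 1]
    return s


@lru_cache(maxsize=256)
def ff_to_power(h: int) -> tuple[float, ...]:
    """Coefficients (low order first) of (n)_h in the power basis."""
    c = np.array([1.0])
    for i in range(h):
        # multiply by (n - i)
        c = np.convolve(c, np.array([-float(i), 1.0]))
    return tuple(c)


def poly_shift(c: np.ndarray, delta: float) -> np.ndarray:
    """Coefficients of P(n + delta) given coefficients of P(n)."""
    deg = len(c) - 1
    out = np.zeros_like(c, dtype=float)
    for p in range(deg + 1):
        if c[p] == 0.0:
            continue
        for j in range(p, -1, -1):
            # coefficient of n^j in (n + delta)^p is C(p, j) delta^(p-j)
            out[j] += c[p] * _binom(p, j) * delta ** (p - j)
    return out


@lru_cache(maxsize=None)
def _binom(p: int, j: int) -> float:
    if j < 0 or j > p:
        return 0.0
    r = 1.0
    for i in range(j):
        r = r * (p - i) / (i + 1)
    return round(r)


def power_to_ff(c: np.ndarray) -> dict[int, float]:
    """Expand a power-basis polynomial into falling factorials.

    Returns a sparse {order: coefficient} mapping.
    """
    s2 = _stirling2()
    out: dict[int, float] = {}
    for p in range(len(c)):
        if c[p] == 0.0:
            continue
        for k in range(p + 1):
            w = s2[p, k]
            if w != 0.0:
                out[k] = out.get(k, 0.0) + c[p] * w
    return {k: v for k, v in out.items() if v != 0.0}


def prod_ff(h: int, m: int) -> dict[int, float]:
    """(n)_h * (n)_m expanded in the falling-factorial basis."""
    c = np.convolve(np.array(ff_to_power(h)), np.array(ff_to_power(m)))
    return power_to_ff(c)


def prod_ff_shift(h: int, m: int, delta: int) -> dict[int, float]:
    """(n)_h * (n + delta)_m expanded in the falling-factorial basis."""
    if m == 0:
        return {h: 1.0}
    shifted = poly_shift(np.array(ff_to_power(m)), float(delta))
    c = np.convolve(np.array(ff_to_power(h)), shifted)
    return power_to_ff(c)


def prod_ff_burst(h: int, m: int, mean_burst: float) -> dict[int, float]:
    """(n)_h * E_k[(n + k)_m] for geometric k with mean ``mean_burst``.

    Uses the Vandermonde identity (n+k)_m = sum_j C(m,j) (n)_j (k)_{m-j}
    and the geometric factorial moments E[(k)_r] = r! B^r.
    """
    out: dict[int, float] = {}
    fact = 1.0
    # iterate r = m - j
    for j in range(m, -1, -1):
        r = m - j
        w = _binom(m, j) * fact * mean_burst**r
        if w != 0.0:
            for k, v in prod_ff(h, j).items():
                out[k] = out.get(k, 0.0) + w * v
        fact *= r + 1
    return {k: v for k, v in out.items() if v != 0.0}
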