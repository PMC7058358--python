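"""Exact rational linear algebra helpers.

Structural quantities (kernels, ranks, minors) are computed in exact rational
arithmetic; floating point is confined to optimization and simulation.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd

import numpy as np
import sympy as sp


def to_sympy_matrix(M) -> sp.Matrix:
    M = np.asarray(M)
    if M.dtype == object:
        return sp.Matrix(M.shape[0], M.shape[1],
                         lambda i, j: sp.Rational(M[i, j]))
    if np.issubdtype(M.dtype, np.integer):
        return sp.Matrix(M.tolist())
    return sp.Matrix(M.shape[0], M.shape[1],
                     lambda i, j: sp.Rational(Fraction(float(M[i, j])).limit_denominator(10**9)))


def _vec_to_fractions(v: sp.Matrix) -> np.ndarray:
    return np.array([Fraction(int(x.p), int(x.q)) for x in v], dtype=object)


def integer_primitive(v: np.ndarray) -> np.ndarray:
    """Scale a rational vector to a primitive integer vector (gcd 1)."""
    fr = [Fraction(x) for x in v]
    denoms = [f.denominator for f in fr]
    lcm = 1
    for d in denoms:
        lcm = lcm * d // gcd(lcm, d)
    ints = [int(f * lcm) for f in fr]
    g = 0
    for x in ints:
        g = gcd(g, x)
    if g > 1:
        ints = [x // g for x in ints]
    return np.array([Fraction(x) for x in ints], dtype=object)


def nullspace(M) -> list[np.ndarray]:
    """Exact basis of ker M as integer-primitive Fraction vectors."""
    S = to_sympy_matrix(M)
    return [integer_primitive(_vec_to_fractions(v)) for v in S.nullspace()]


def left_nullspace(M) -> list[np.ndarray]:
    return nullspace(np.asarray(M).T)


def rank(M) -> int:
    return to_sympy_matrix(M).rank()


def column_space(M) -> list[np.ndarray]:
    S = to_sympy_matrix(M)
    return [integer_primitive(_vec_to_fractions(v)) for v in S.columnspace()]


def in_row_space(row, M) -> bool:
    """Exact test whether ``row`` lies in the row space of ``M``."""
    S = to_sympy_matrix(M)
    r = to_sympy_matrix(np.asarray(row).reshape(1, -1))
    return S.rank() == S.col_join(r).rank()


def frac_array(M) -> np.ndarray:
    M = np.asarray(M)
    out = np.empty(M.shape, dtype=object)
    flat = out.reshape(-1)
    for idx, x in enumerate(np.asarray(M).reshape(-1)):
        flat[idx] = Fraction(x) if not isinstance(x, Fraction) else x
    return out


def as_float(M) -> np.ndarray:
    return np.asarray(np.asarray(M, dtype=object), dtype=float) if np.asarray(M).dtype == object \
        else np.asarray(M, dtype=float)


def rationalize_in_span(x: np.ndarray, basis: list[np.ndarray],
                        max_den: int = 10**6) -> np.ndarray | None:
    """Snap a float vector known to lie (approximately) in span(basis) to an
    exact rational vector in that span, by rationalizing its coordinates."""
    if not basis:
        return None
    Bf = np.column_stack([as_float(b) for b in basis])
    coords, *_ = np.linalg.lstsq(Bf, np.asarray(x, dtype=float), rcond=None)
    exact = np.array([Fraction(0)] * len(basis[0]), dtype=object)
    for c, b in zip(coords, basis):
        fc = Fraction(float(c)).limit_denominator(max_den)
        exact = exact + np.array([fc * Fraction(v) for v in b], dtype=object)
    resid = as_float(exact) - np.asarray(x, dtype=float)
    if np.max(np.abs(resid)) > 1e-6 * (1.0 + np.max(np.abs(as_float(exact)))):
        return None
    return exact


def exact_det(M) -> Fraction:
    d = to_sympy_matrix(M).det()
    return Fraction(int(d.p), int(d.q))


def int_det(M: np.ndarray) -> int:
    """Determinant of a small integer matrix, exactly (Bareiss)."""
    A = [[int(x) for x in row] for row in np.asarray(M)]
    n = len(A)
    if n == 0:
        return 1
    sign = 1
    prev = 1
    for k in range(n - 1):
        if A[k][k] == 0:
            for i in range(k + 1, n):
                if A[i][k] != 0:
                    A[k], A[i] = A[i], A[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                A[i][j] = (A[i][j] * A[k][k] - A[i][k] * A[k][j]) // prev
        prev = A[k][k]
    return sign * A[n - 1][n - 1]
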