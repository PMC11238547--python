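"""Small spin-algebra helpers shared across modules.

Half-integer spin quantum numbers are carried as *doubled integers*
(``two_s = int(2*s)``) wherever exact comparisons matter; public
dataclasses expose the conventional float values.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache

import numpy as np

__all__ = [
    "clebsch_gordan",
    "ladder_factor",
    "twice",
    "s_from_eigval",
]


def twice(s: float) -> int:
    """Return the doubled-integer representation of a half-integer spin."""
    t = int(round(2 * s))
    if abs(2 * s - t) > 1e-9:
        raise ValueError(f"{s} is not a half-integer")
    return t


@lru_cache(maxsize=None)
def _cg_cached(tj1: int, tm1: int, tj2: int, tm2: int, tj3: int, tm3: int) -> float:
    from sympy.physics.quantum.cg import CG

    half = Fraction(1, 2)
    c = CG(
        Fraction(tj1) * half, Fraction(tm1) * half,
        Fraction(tj2) * half, Fraction(tm2) * half,
        Fraction(tj3) * half, Fraction(tm3) * half,
    )
    return float(c.doit())


def clebsch_gordan(j1: float, m1: float, j2: float, m2: float, j3: float, m3: float) -> float:
    """Clebsch-Gordan coefficient <j1 m1; j2 m2 | j3 m3> (Condon-Shortley)."""
    return _cg_cached(twice(j1), twice(m1), twice(j2), twice(m2), twice(j3), twice(m3))


def ladder_factor(s: float, m: float, up: bool) -> float:
    """Matrix element of s+/s-: s_pm |s m> = f |s m+-1>."""
    sign = 1.0 if up else -1.0
    val = s * (s + 1.0) - m * (m + sign)
    return float(np.sqrt(max(val, 0.0)))


def s_from_eigval(lam: float, tol: float = 1e-8) -> float | None:
    """Map an S^2 eigenvalue to the spin S with lam = S(S+1), or None."""
    s = 0.5 * (-1.0 + np.sqrt(max(1.0 + 4.0 * lam, 0.0)))
    t = round(2 * s)
    if t < 0:
        return None
    s_half = t / 2.0
    if abs(s_half * (s_half + 1.0) - lam) < tol:
        return s_half
    return None
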