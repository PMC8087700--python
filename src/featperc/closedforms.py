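"""Closed-form generating functions for the analytic families.

These expressions are kept deliberately separate from the generic weighted
sums in :mod:`featperc.percolation` so the two routes can be compared in
tests.  Special functions are evaluated either by direct truncated
summation (under the package truncation rule) or by delegating to mpmath's
high-precision implementations; the two evaluators agree to 1e-9.

Note on normalisations: the correlated families live on k >= 1, so the
occupied normalisations involve zeta(s) - 1 = sum_{k>=1} (k+1)^-s rather
than zeta(s).  (With a bare zeta(s) the phi == 1 limit would not generate a
normalised distribution.)
"""

from __future__ import annotations

import math

import mpmath
import numpy as np
from scipy import special

from .errors import DomainError

_SERIES_TOL = 1e-14
_SERIES_CAP = 2_000_000


def lerch_phi(z: float, s: float, a: float, method: str = "series") -> float:
    """Lerch transcendent Phi(z, s, a) = sum_{n>=0} z^n / (n+a)^s.

    ``method="series"`` sums the truncated series directly (z in [0, 1],
    a > 0, with the Hurwitz-zeta shortcut at z = 1); ``method="mpmath"``
    delegates to the arbitrary-precision implementation.
    """
    if not (0.0 <= z <= 1.0):
        raise DomainError(f"series evaluation requires z in [0, 1], got {z}")
    if a <= 0:
        raise DomainError(f"offset a={a} must be positive")
    if method == "mpmath":
        return float(mpmath.lerchphi(z, s, a))
    if z == 1.0:
        if s <= 1.0:
            raise DomainError("Phi(1, s, a) diverges for s <= 1")
        return float(special.zeta(s, a))
    block = 4096
    total = 0.0
    n0 = 0
    while n0 < _SERIES_CAP:
        n = np.arange(n0, n0 + block, dtype=float)
        terms = z ** n / (n + a) ** s
        total += float(terms.sum())
        # geometric bound on the remainder
        rem = terms[-1] * z / (1.0 - z)
        if rem < _SERIES_TOL * max(abs(total), 1.0):
            return total
        n0 += block
    return total


# ---------------------------------------------------------------------------
# independent family (geometric degrees, Pareto features, threshold at F0)
# ---------------------------------------------------------------------------

def _q_factor(alpha: float, F0: float) -> float:
    return 1.0 if math.isinf(F0) else 1.0 - F0 ** (1.0 - alpha)


def independent_g0(u: float, a: float, alpha: float, F0: float = math.inf) -> float:
    return _q_factor(alpha, F0) * (1.0 - a) / (1.0 - a * u)


def independent_g1(u: float, a: float, alpha: float, F0: float = math.inf) -> float:
    return _q_factor(alpha, F0) * ((1.0 - a) / (1.0 - a * u)) ** 2


# ---------------------------------------------------------------------------
# positively correlated family P(k,F) = Z (k+F)^-(2+alpha), threshold at F0
# ---------------------------------------------------------------------------

def positive_g0(u: float, alpha: float, F0: float, method: str = "series") -> float:
    num = lerch_phi(u, alpha + 1.0, 2.0, method) \
        - lerch_phi(u, alpha + 1.0, F0 + 1.0, method)
    return u * num / (special.zeta(alpha + 1.0) - 1.0)


def positive_g1(u: float, alpha: float, F0: float, method: str = "series") -> float:
    num = (lerch_phi(u, alpha, 2.0, method)
           - lerch_phi(u, alpha + 1.0, 2.0, method)
           - lerch_phi(u, alpha, F0 + 1.0, method)
           + F0 * lerch_phi(u, alpha + 1.0, F0 + 1.0, method))
    return num / (special.zeta(alpha) - special.zeta(alpha + 1.0))


# ---------------------------------------------------------------------------
# negatively correlated family P(k,F) = Z (kF+1)^-(alpha+1), threshold at F0
# ---------------------------------------------------------------------------

def negative_g0(u: float, alpha: float, F0: float, norm_sum: float) -> float:
    """(Z/alpha) sum_{k>=1} [(1+k)^-alpha - (1+k F0)^-alpha] u^k / k.

    ``norm_sum`` is sum_{k>=1} 1/(k (k+1)^alpha) (= alpha/Z); the series has
    no standard closed form and is summed directly.
    """
    if u == 0.0:
        return 0.0
    block = 4096
    total = 0.0
    k0 = 1
    while k0 < _SERIES_CAP:
        k = np.arange(k0, k0 + block, dtype=float)
        terms = ((1.0 + k) ** (-alpha) - (1.0 + k * F0) ** (-alpha)) * u ** k / k
        total += float(terms.sum())
        last = abs(terms[-1])
        rem = last * (u / (1.0 - u) if u < 1.0 else (k0 + block) / (alpha - 1.0))
        if rem < _SERIES_TOL * max(abs(total), 1e-30):
            break
        k0 += block
    return total / norm_sum


def negative_g1(u: float, alpha: float, F0: float, method: str = "series") -> float:
    num = lerch_phi(u, alpha, 2.0, method) \
        - F0 ** (-alpha) * lerch_phi(u, alpha, 1.0 + 1.0 / F0, method)
    return num / (special.zeta(alpha) - 1.0)


# ---------------------------------------------------------------------------
# random geometric graph on the unit torus (Eq.-(17)-style binomial forms)
# ---------------------------------------------------------------------------

def rgg_g0(u: float, N: int, r: float, r0: float) -> float:
    base = 1.0 + math.pi * r * r * (u - 1.0) - math.pi * r0 * r0 * u
    return base ** (N - 1) - (1.0 - math.pi * r * r) ** (N - 1)


def rgg_g1(u: float, N: int, r: float, r0: float) -> float:
    base = 1.0 + math.pi * r * r * (u - 1.0) - math.pi * r0 * r0 * u
    return (r - r0) * (r + r0) / (r * r) * base ** (N - 2)


def rgg_branching(N: int, r: float, r0: float) -> float:
    """d g1/du at u = 1."""
    base = 1.0 - math.pi * r0 * r0
    pref = (r - r0) * (r + r0) / (r * r)
    return pref * (N - 2) * math.pi * (r * r - r0 * r0) * base ** (N - 3)
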