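"""Generating-function percolation under degree-feature occupation rules.

For a joint law ``P(k,F)`` and an occupation rule ``phi(k,F)`` the occupied
weight at degree k is ``w_k = p_k int dF phi(k,F) P(F|k)``, from which

    g0(z) = sum_k w_k z^k
    g1(z) = sum_k k w_k z^(k-1) / <k>

The giant-component fraction is ``S = g0(1) - g0(u)`` where ``u`` is the
smallest root of ``u = 1 - g1(1) + g1(u)`` in [0, 1]; the network
percolates iff the branching factor ``g1'(1)`` exceeds one.

Generic evaluation sums the truncated weight vector.  For the independent
family with a degree-blind rule the geometric closed forms are dispatched
instead (method="auto"); ``method="weights"`` forces the generic numeric
path, which the tests use as an independent route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .distributions import JointDegreeFeatureDistribution
from .errors import BracketingError, ConvergenceError, DomainError
from .occupation import OccupationRule

_DAMPING = 0.5
_MAX_DAMPED = 16  # hand off to bracketed root finding after this many sweeps


@dataclass
class PercolationSolution:
    u: float
    S: float
    occupied_fraction: float
    branching_factor: float
    converged: bool
    iterations: int


def _solve_u(g1: Callable[[float], float], g1_at_1: float, branching: float,
             tol: float = 1e-12, max_iter: int = 10_000) -> tuple[float, bool, int]:
    """Smallest fixed point of u = 1 - g1(1) + g1(u) on [0, 1].

    Damped iteration from u0 = 0 (the map is monotone, so iterates approach
    the physical root from below); slow or oscillating progress falls back
    to Brent's method on the bracket [u_n, 1 - delta].
    """
    if tol <= 0:
        raise DomainError(f"tol={tol} must be positive")
    if branching <= 1.0 + 1e-13:
        return 1.0, True, 0
    c = 1.0 - g1_at_1
    u = 0.0
    n_damped = min(_MAX_DAMPED, max_iter)
    for it in range(n_damped):
        nxt = c + g1(u)
        if abs(nxt - u) < tol:
            return float(min(nxt, 1.0)), True, it + 1
        u = (1.0 - _DAMPING) * u + _DAMPING * nxt

    def f(x):
        return x - c - g1(x)

    lo = u if f(u) < 0 else 0.0
    delta = 1e-9
    while delta > 1e-15 and f(1.0 - delta) <= 0.0:
        delta *= 1e-3
    hi = 1.0 - delta
    if f(hi) <= 0.0:
        # root indistinguishable from 1 at double precision
        return 1.0, True, n_damped
    try:
        root, res = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16,
                           maxiter=max_iter, full_output=True)
    except RuntimeError as exc:  # pragma: no cover
        raise ConvergenceError(f"fixed-point solve failed: {exc}", last=u,
                               iterations=n_damped) from exc
    return float(root), res.converged, n_damped + res.iterations


class GeneratingFunctions:
    """g0/g1 evaluator bound to a (distribution, rule) pair."""

    def __init__(self, dist: JointDegreeFeatureDistribution,
                 rule: OccupationRule, method: str = "auto"):
        self.dist = dist
        self.rule = rule
        self.mean_degree = dist.mean_degree
        if self.mean_degree <= 0:
            raise DomainError("mean degree must be positive")
        self._exact = None
        if method not in ("auto", "weights", "closed"):
            raise DomainError(f"unknown method {method!r}")
        if method in ("auto", "closed") and dist.family == "independent" \
                and rule.kind in ("uniform", "feature_upper_threshold",
                                  "feature_lower_threshold"):
            a = dist.params["a"]
            q = float(rule.retained_mass(dist, np.array([0]))[0])
            self._exact = (a, q)
        elif method == "closed":
            raise DomainError("no closed form registered for this pair")
        if self._exact is None:
            k = dist.k
            self._k = k.astype(float)
            self._w = dist.pk * rule.retained_mass(dist)
            self._kw = self._k * self._w

    # -- evaluation --------------------------------------------------------
    def g0(self, z: float) -> float:
        if not (-1e-12 <= z <= 1.0 + 1e-12):
            raise DomainError(f"z={z} outside [0, 1]")
        z = min(max(z, 0.0), 1.0)
        if self._exact is not None:
            a, q = self._exact
            return q * (1.0 - a) / (1.0 - a * z)
        return float(np.dot(self._w, z ** self._k))

    def g1(self, z: float) -> float:
        if not (-1e-12 <= z <= 1.0 + 1e-12):
            raise DomainError(f"z={z} outside [0, 1]")
        z = min(max(z, 0.0), 1.0)
        if self._exact is not None:
            a, q = self._exact
            return q * ((1.0 - a) / (1.0 - a * z)) ** 2
        if z == 0.0:
            # only the k=1 term survives (z^0)
            i = np.nonzero(self._k == 1.0)[0]
            s = float(self._kw[i].sum()) if i.size else 0.0
            return s / self.mean_degree
        return float(np.dot(self._kw, z ** (self._k - 1.0))) / self.mean_degree

    @property
    def occupied_fraction(self) -> float:
        """g0(1): probability that a random node survives the removal."""
        if self._exact is not None:
            return self._exact[1]
        return float(self._w.sum())

    @property
    def g1_at_1(self) -> float:
        if self._exact is not None:
            return self._exact[1]
        return float(self._kw.sum()) / self.mean_degree

    @property
    def branching(self) -> float:
        """g1'(1) = sum_k k (k-1) w_k / <k>; percolation iff > 1."""
        if self._exact is not None:
            a, q = self._exact
            return 2.0 * a * q / (1.0 - a)
        return float(np.dot(self._kw, self._k - 1.0)) / self.mean_degree

    # -- solving -----------------------------------------------------------
    def solve(self, tol: float = 1e-12, max_iter: int = 10_000) -> PercolationSolution:
        u, conv, its = _solve_u(self.g1, self.g1_at_1, self.branching,
                                tol=tol, max_iter=max_iter)
        g01 = self.occupied_fraction
        S = 0.0 if u >= 1.0 else max(0.0, g01 - self.g0(u))
        return PercolationSolution(u=u, S=S, occupied_fraction=g01,
                                   branching_factor=self.branching,
                                   converged=conv, iterations=its)


def solve_generating_functions(g0_fn: Callable, g1_fn: Callable,
                               branching: float,
                               tol: float = 1e-12,
                               max_iter: int = 10_000) -> PercolationSolution:
    """Percolation solve for arbitrary generating-function callables
    (used e.g. by the random-geometric-graph theory)."""
    u, conv, its = _solve_u(g1_fn, g1_fn(1.0), branching, tol=tol,
                            max_iter=max_iter)
    g01 = g0_fn(1.0)
    S = 0.0 if u >= 1.0 else max(0.0, g01 - g0_fn(u))
    return PercolationSolution(u=u, S=S, occupied_fraction=g01,
                               branching_factor=branching,
                               converged=conv, iterations=its)


def derivative_at_one(fn: Callable[[float], float], step: float = 1e-5) -> float:
    """Richardson-extrapolated one-sided derivative of fn at z = 1.

    Fallback for callables without an analytic branching factor; uses
    backward stencils since fn is only defined on [0, 1].
    """
    def backward(h):
        return (3.0 * fn(1.0) - 4.0 * fn(1.0 - h) + fn(1.0 - 2.0 * h)) / (2.0 * h)

    d1, d2 = backward(step), backward(step / 2.0)
    out = (4.0 * d2 - d1) / 3.0
    if not math.isfinite(out):
        raise ConvergenceError("numeric differentiation at z=1 failed", last=out)
    return out


# ---------------------------------------------------------------------------
# stable functional API
# ---------------------------------------------------------------------------

def g0(dist, rule, z, method: str = "auto") -> float:
    return GeneratingFunctions(dist, rule, method=method).g0(z)


def g1(dist, rule, z, method: str = "auto") -> float:
    return GeneratingFunctions(dist, rule, method=method).g1(z)


def solve_fixed_point(dist, rule, tol: float = 1e-12, max_iter: int = 10_000,
                      method: str = "auto") -> float:
    return GeneratingFunctions(dist, rule, method=method).solve(
        tol=tol, max_iter=max_iter).u


def giant_fraction_theory(dist, rule, method: str = "auto",
                          tol: float = 1e-12) -> PercolationSolution:
    return GeneratingFunctions(dist, rule, method=method).solve(tol=tol)


def branching_factor(dist, rule, method: str = "auto") -> float:
    return GeneratingFunctions(dist, rule, method=method).branching


def critical_point_independent(mode: str, *, a: float | None = None,
                               alpha: float | None = None,
                               F0: float = math.inf) -> float:
    """Closed-form critical point of the independent family under an upper
    feature threshold at F0.

    mode="a":     a_c     = 1 / (3 - 2 F0^(1-alpha))       (needs alpha)
    mode="alpha": alpha_c = 1 - log((3a-1)/(2a)) / log F0  (needs a)
    """
    if mode == "a":
        if alpha is None or alpha <= 1.0:
            raise DomainError("mode='a' requires alpha > 1")
        tail = 0.0 if math.isinf(F0) else F0 ** (1.0 - alpha)
        return 1.0 / (3.0 - 2.0 * tail)
    if mode == "alpha":
        if a is None or not (0.0 < a < 1.0):
            raise DomainError("mode='alpha' requires 0 < a < 1")
        ratio = (3.0 * a - 1.0) / (2.0 * a)
        if ratio <= 0.0:
            raise DomainError(
                f"a={a} <= 1/3: no critical alpha exists (log of non-positive)")
        if math.isinf(F0) or F0 <= 1.0:
            raise DomainError("mode='alpha' requires finite F0 > 1")
        return 1.0 - math.log(ratio) / math.log(F0)
    raise DomainError(f"unknown mode {mode!r}")


def find_critical(point_factory: Callable[[float], tuple], lo: float, hi: float,
                  xtol: float = 1e-10, method: str = "weights") -> float:
    """Root of branching(param) - 1 on [lo, hi] by Brent bracketing.

    ``point_factory(value)`` must return a (distribution, rule) pair. The
    generic weights path is the default so the result stays independent of
    any closed-form shortcut.
    """
    def excess(v):
        dist, rule = point_factory(v)
        return GeneratingFunctions(dist, rule, method=method).branching - 1.0

    f_lo, f_hi = excess(lo), excess(hi)
    if f_lo * f_hi > 0:
        raise BracketingError(
            f"branching-1 does not change sign on [{lo}, {hi}] "
            f"(values {f_lo:.3g}, {f_hi:.3g})")
    return float(brentq(excess, lo, hi, xtol=xtol, maxiter=200))


def theory_curve(point_factory: Callable[[float], tuple], grid,
                 param_name: str = "param", method: str = "auto"):
    """Solve the theory at every grid value; returns a TheoryCurve."""
    from .curves import TheoryCurve

    grid = np.asarray(grid, dtype=float)
    S = np.empty(grid.size)
    u = np.empty(grid.size)
    br = np.empty(grid.size)
    for i, v in enumerate(grid):
        dist, rule = point_factory(v)
        sol = GeneratingFunctions(dist, rule, method=method).solve()
        S[i], u[i], br[i] = sol.S, sol.u, sol.branching_factor
    return TheoryCurve(param_name=param_name, grid=grid, S=S, u=u,
                       branching=br)
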