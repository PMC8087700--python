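"""Quantitative robustness comparisons and critical-exponent estimation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError
from .percolation import GeneratingFunctions


def _curve_arrays(curve):
    """Accept (grid, S) tuples or curve objects."""
    if isinstance(curve, tuple):
        return np.asarray(curve[0], float), np.asarray(curve[1], float)
    grid = np.asarray(curve.grid, float)
    s = getattr(curve, "S", None)
    if s is None:
        s = curve.S_mean
    return grid, np.asarray(s, float)


def _common_grid(a, b):
    ga, sa = _curve_arrays(a)
    gb, sb = _curve_arrays(b)
    if ga[0] > ga[-1]:
        ga, sa = ga[::-1], sa[::-1]
    if gb[0] > gb[-1]:
        gb, sb = gb[::-1], sb[::-1]
    lo, hi = max(ga[0], gb[0]), min(ga[-1], gb[-1])
    if hi <= lo:
        raise DomainError("curves are defined on disjoint parameter ranges")
    if ga.size == gb.size and np.allclose(ga, gb):
        return ga, sa, sb
    grid = ga[(ga >= lo - 1e-12) & (ga <= hi + 1e-12)]
    return grid, np.interp(grid, ga, sa), np.interp(grid, gb, sb)


def delta_area(curve_rand, curve_corr) -> float:
    """Trapezoidal area between the randomized and correlated S curves.

    Positive when ignoring the correlation overestimates robustness."""
    grid, s_rand, s_corr = _common_grid(curve_rand, curve_corr)
    return float(np.trapezoid(s_rand - s_corr, grid))


def epsilon_discrepancy(curve_theory, curve_sim) -> float:
    """Trapezoidal integral of |S_theory - S_sim| on the common grid."""
    grid, s_th, s_sim = _common_grid(curve_theory, curve_sim)
    return float(np.trapezoid(np.abs(s_th - s_sim), grid))


@dataclass
class ScalingFit:
    """log S vs log N least-squares fit at the critical point."""

    ratio: float          # beta / nu_bar = -slope
    ratio_se: float
    nu_bar: float         # beta / ratio for the supplied beta
    nu_bar_se: float
    beta_assumed: float
    sizes: np.ndarray
    mean_S: np.ndarray
    se_S: np.ndarray


def fss_exponent(sizes, samples, beta: float = 1.0) -> ScalingFit:
    """Finite-size scaling exponent ratio from per-size S samples.

    ``samples`` maps each size (or aligns positionally) to an array of
    giant-fraction measurements at the critical point; the ratio
    beta/nu_bar is minus the slope of log mean(S) against log N.
    """
    if isinstance(samples, dict):
        sizes = sorted(samples)
        groups = [np.asarray(samples[n], float) for n in sizes]
    else:
        groups = [np.asarray(g, float) for g in samples]
    sizes = np.asarray(sizes, float)
    if sizes.size < 3:
        raise DomainError("finite-size scaling needs >= 3 sizes")
    if any(g.size < 2 for g in groups):
        raise DomainError("each size needs >= 2 samples")
    means = np.array([g.mean() for g in groups])
    ses = np.array([g.std(ddof=1) / np.sqrt(g.size) for g in groups])
    if np.any(means <= 0):
        raise DomainError("non-positive mean S; not at a critical point?")
    res = stats.linregress(np.log(sizes), np.log(means))
    ratio = -res.slope
    ratio_se = res.stderr
    return ScalingFit(ratio=float(ratio), ratio_se=float(ratio_se),
                      nu_bar=float(beta / ratio),
                      nu_bar_se=float(beta * ratio_se / ratio ** 2),
                      beta_assumed=beta, sizes=sizes, mean_S=means, se_S=ses)


def beta_from_theory(point_factory, critical: float, offsets,
                     method: str = "auto") -> float:
    """Order-parameter exponent from the deterministic solver.

    Solves the theory at ``critical + offset`` for each strictly positive
    offset and returns the log-log slope of S against the offset.
    ``point_factory(param)`` returns a (distribution, rule) pair.
    """
    offsets = np.asarray(offsets, dtype=float)
    if np.any(offsets <= 0):
        raise DomainError("offsets must be strictly positive")
    if np.log10(offsets.max() / offsets.min()) < 2.0 - 1e-9:
        raise DomainError("offsets should span at least two decades")
    S = np.empty(offsets.size)
    for i, off in enumerate(offsets):
        dist, rule = point_factory(critical + off)
        S[i] = GeneratingFunctions(dist, rule, method=method).solve().S
        if S[i] <= 0:
            raise DomainError(
                f"S = 0 at offset {off:g}: supplied critical point is wrong")
    slope, _ = np.polyfit(np.log(offsets), np.log(S), 1)
    return float(slope)


def collapse_score(sizes, grids, curves, critical: float, ratio: float,
                   inv_nu_bar: float) -> float:
    """Mean squared vertical spread of finite-size curves rescaled by the
    scaling ansatz (inspection aid; not an optimiser)."""
    xs, ys = [], []
    for N, grid, S in zip(sizes, grids, curves):
        grid = np.asarray(grid, float)
        S = np.asarray(S, float)
        xs.append(np.abs(grid - critical) * N ** inv_nu_bar)
        ys.append(S * N ** ratio)
    lo = max(x.min() for x in xs)
    hi = min(x.max() for x in xs)
    if hi <= lo:
        return float("nan")
    common = np.linspace(lo, hi, 64)
    stack = np.array([np.interp(common, np.sort(x), y[np.argsort(x)])
                      for x, y in zip(xs, ys)])
    return float(np.mean(stack.var(axis=0)))
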