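"""Joint degree-feature distributions.

A :class:`JointDegreeFeatureDistribution` couples a discrete degree law
``p_k`` with a per-degree feature law ``P(F | k)``.  Three analytic families
are provided (independent, positively correlated, negatively correlated),
plus an approximate conditional-Gaussian family built from data (see
:mod:`featperc.jointfit`), a discrete-feature variant, and fully custom
distributions supplied as callables or tables.

All infinite degree sums are truncated at the smallest ``k_max`` whose
cumulative degree mass reaches ``1 - tail_tol`` (hard cap ``K_CAP``); the
achieved tail mass is recorded on the instance.
"""

from __future__ import annotations

import json
import math
from typing import Callable, Sequence

import numpy as np
from scipy import special

from .errors import DomainError, TruncationError

#: default relative tail mass left outside the degree truncation
DEFAULT_TAIL_TOL = 1e-12
#: hard cap on the degree truncation
K_CAP = 1_000_000
#: tail mass above which construction fails outright
TAIL_HARD_LIMIT = 1e-8


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class JointDegreeFeatureDistribution:
    """Base class: joint law of (degree k, feature F).

    Subclasses must populate ``k`` (integer support), ``pk`` (degree
    marginal on that support), ``mean_degree``, ``feature_support`` and
    implement the conditional feature law.  The conditional is exposed
    through three vectorised primitives:

    ``conditional_cdf(k, f)``
        ``P(F <= f | k)`` (equals ``P(F < f)`` for continuous features).
    ``conditional_ppf(k, q)``
        inverse CDF, used by the samplers.
    ``conditional_pdf(k, f)``
        density (or mass, in discrete-feature mode).
    """

    family: str = "custom"
    params: dict

    k: np.ndarray
    pk: np.ndarray
    mean_degree: float
    feature_support: tuple[float, float]
    tail_tol: float = DEFAULT_TAIL_TOL
    tail_mass: float = 0.0
    discrete_features: bool = False

    # -- conditional feature law ------------------------------------------
    def conditional_pdf(self, k, f):
        raise NotImplementedError

    def conditional_cdf(self, k, f):
        raise NotImplementedError

    def conditional_ppf(self, k, q):
        raise NotImplementedError

    # threshold helpers; the strict/non-strict split only matters for
    # discrete features (Heaviside convention theta(0)=1)
    def mass_below(self, k, f):
        """P(F < f | k); retained mass under an upper threshold at f."""
        return self.conditional_cdf(k, f)

    def mass_at_or_above(self, k, f):
        """P(F >= f | k); retained mass under a lower threshold at f."""
        return 1.0 - self.mass_below(k, f)

    # -- joint and marginals ----------------------------------------------
    def joint_pdf(self, k, f):
        """P(k, F): probability mass in k times density in F."""
        k_arr = np.asarray(k)
        idx = np.clip(np.searchsorted(self.k, k_arr), 0, self.k.size - 1)
        pk_k = np.where(self.k[idx] == k_arr, self.pk[idx], 0.0)
        return pk_k * np.asarray(self.conditional_pdf(k, f), dtype=float)

    def degree_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        return self.k, self.pk

    def feature_marginal_pdf(self, f):
        f = np.asarray(f, dtype=float)
        out = np.zeros(f.shape or (1,), dtype=float)
        for kk, pp in zip(self.k, self.pk):
            out += pp * np.asarray(self.conditional_pdf(kk, f))
        return out if f.shape else float(out[0])

    def feature_marginal_mass_below(self, f) -> float:
        """P(F < f) marginalised over degree."""
        return float(np.sum(self.pk * np.asarray(self.mass_below(self.k, f))))

    def conditional_mean_degree(self, f) -> float:
        """<k(F)> = sum_k k P(k,F) / sum_k P(k,F) under the truncation."""
        lo, hi = self.feature_support
        if not (lo <= f <= hi):
            raise DomainError(f"feature value {f} outside support [{lo}, {hi}]")
        w = self.pk * np.asarray(self.conditional_pdf(self.k, f), dtype=float)
        tot = w.sum()
        if tot <= 0:
            raise DomainError(f"joint density vanishes at F={f}")
        return float((self.k * w).sum() / tot)

    # -- sampling ----------------------------------------------------------
    def _degree_cdf(self):
        cdf = getattr(self, "_cached_degree_cdf", None)
        if cdf is None:
            cdf = np.cumsum(self.pk)
            cdf /= cdf[-1]
            self._cached_degree_cdf = cdf
        return cdf

    def sample_degrees(self, n: int, seed=None) -> np.ndarray:
        rng = _as_rng(seed)
        u = rng.random(n)
        return self.k[np.searchsorted(self._degree_cdf(), u)]

    def sample_features_given_degrees(self, degrees, seed=None) -> np.ndarray:
        rng = _as_rng(seed)
        q = rng.random(len(degrees))
        return np.asarray(self.conditional_ppf(np.asarray(degrees), q), dtype=float)

    def sample(self, n: int, seed=None):
        """Draw n (degree, feature) pairs: k ~ p_k, then F ~ P(F|k)."""
        rng = _as_rng(seed)
        ks = self.sample_degrees(n, rng)
        fs = self.sample_features_given_degrees(ks, rng)
        return ks, fs

    def sample_marginal_features(self, n: int, seed=None) -> np.ndarray:
        """Features from the marginal P(F) (degree integrated out)."""
        _, fs = self.sample(n, seed)
        return fs

    # -- bookkeeping -------------------------------------------------------
    def to_spec(self) -> dict:
        return {
            "family": self.family,
            "params": self.params,
            "k_min": int(self.k[0]),
            "k_max": int(self.k[-1]),
            "tail_tol": self.tail_tol,
            "feature_support": list(self.feature_support),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_spec())

    def __repr__(self):  # pragma: no cover
        p = ", ".join(f"{a}={b:.6g}" for a, b in self.params.items())
        return f"<{type(self).__name__} {self.family}({p}) k<= {self.k[-1]}>"


def _check_truncation(tail_mass, tail_tol, family, max_tail=None):
    limit = TAIL_HARD_LIMIT if max_tail is None else max_tail
    if tail_mass > limit:
        raise TruncationError(
            f"{family}: degree cap {K_CAP} leaves tail mass {tail_mass:.3e} "
            f"(> {limit:.0e}); cannot honour tail_tol={tail_tol:.0e}"
        )


# ---------------------------------------------------------------------------
# independent family: geometric degrees x Pareto features
# ---------------------------------------------------------------------------

class IndependentDistribution(JointDegreeFeatureDistribution):
    """p_k = (1-a) a^k for k >= 0, features Pareto(alpha) on [1, inf),
    independent of the degree."""

    family = "independent"

    def __init__(self, a: float, alpha: float, tail_tol: float = DEFAULT_TAIL_TOL,
                 max_tail: float | None = None):
        if not (0.0 < a < 1.0):
            raise DomainError(f"geometric ratio a={a} violates 0 < a < 1")
        if not alpha > 1.0:
            raise DomainError(f"feature exponent alpha={alpha} violates alpha > 1")
        self.a = float(a)
        self.alpha = float(alpha)
        self.params = {"a": self.a, "alpha": self.alpha}
        self.tail_tol = float(tail_tol)
        # geometric tail mass beyond k_max is a^(k_max+1)
        k_max = min(K_CAP, max(8, math.ceil(math.log(tail_tol) / math.log(a))))
        self.k = np.arange(0, k_max + 1)
        self.pk = (1.0 - a) * a ** self.k.astype(float)
        self.tail_mass = float(a ** (k_max + 1))
        _check_truncation(self.tail_mass, tail_tol, self.family, max_tail)
        self.mean_degree = a / (1.0 - a)
        self.feature_support = (1.0, math.inf)

    def conditional_pdf(self, k, f):
        f = np.asarray(f, dtype=float)
        out = np.where(f >= 1.0, (self.alpha - 1.0) * f ** (-self.alpha), 0.0)
        return np.broadcast_to(out, np.broadcast_shapes(np.shape(k), out.shape)).copy()

    def conditional_cdf(self, k, f):
        f = np.asarray(f, dtype=float)
        out = np.where(f >= 1.0, 1.0 - f ** (1.0 - self.alpha), 0.0)
        return np.broadcast_to(out, np.broadcast_shapes(np.shape(k), out.shape)).copy()

    def conditional_ppf(self, k, q):
        q = np.asarray(q, dtype=float)
        out = (1.0 - q) ** (-1.0 / (self.alpha - 1.0))
        return np.broadcast_to(out, np.broadcast_shapes(np.shape(k), out.shape)).copy()


# ---------------------------------------------------------------------------
# positively correlated family: P(k, F) = Z / (k + F)^(2 + alpha)
# ---------------------------------------------------------------------------

class PositiveDistribution(JointDegreeFeatureDistribution):
    """Scale-free joint law with positive degree-feature correlation.

    P(k,F) = Z (k+F)^-(2+alpha) on k >= 1, F in [1, inf), with
    Z = (1+alpha)/(zeta(1+alpha) - 1).  The degree marginal is
    p_k = (k+1)^-(1+alpha) / (zeta(1+alpha) - 1) and the conditional tail
    is P(F > f | k) = ((k+f)/(k+1))^-(1+alpha), inverted analytically for
    sampling.
    """

    family = "positive"

    def __init__(self, alpha: float, k_max: int | None = None,
                 tail_tol: float = DEFAULT_TAIL_TOL,
                 max_tail: float | None = None):
        if not alpha > 1.0:
            raise DomainError(f"exponent alpha={alpha} violates alpha > 1")
        self.alpha = float(alpha)
        self.params = {"alpha": self.alpha}
        self.tail_tol = float(tail_tol)
        zm1 = float(special.zeta(1.0 + alpha) - 1.0)
        self.Z = (1.0 + alpha) / zm1
        if k_max is None:
            # tail: sum_{k>K} (k+1)^-(1+alpha) ~ (K+1)^-alpha / alpha
            k_max = math.ceil((tail_tol * alpha * zm1) ** (-1.0 / alpha))
            k_max = min(K_CAP, max(16, k_max))
        self.k = np.arange(1, k_max + 1)
        self.pk = (self.k + 1.0) ** (-(1.0 + alpha)) / zm1
        self.tail_mass = float(special.zeta(1.0 + alpha, k_max + 2) / zm1)
        _check_truncation(self.tail_mass, tail_tol, self.family, max_tail)
        self.mean_degree = float(
            (special.zeta(alpha) - special.zeta(alpha + 1.0)) / zm1
        )
        self.feature_support = (1.0, math.inf)

    def conditional_pdf(self, k, f):
        k = np.asarray(k, dtype=float)
        f = np.asarray(f, dtype=float)
        # P(F|k) = (1+alpha) (k+1)^(1+alpha) (k+F)^-(2+alpha)
        out = (1.0 + self.alpha) * (k + 1.0) ** (1.0 + self.alpha) \
            * (k + f) ** (-(2.0 + self.alpha))
        return np.where(f >= 1.0, out, 0.0)

    def conditional_cdf(self, k, f):
        k = np.asarray(k, dtype=float)
        f = np.asarray(f, dtype=float)
        sf = ((k + f) / (k + 1.0)) ** (-(1.0 + self.alpha))
        return np.where(f >= 1.0, 1.0 - sf, 0.0)

    def conditional_ppf(self, k, q):
        k = np.asarray(k, dtype=float)
        q = np.asarray(q, dtype=float)
        return (k + 1.0) * (1.0 - q) ** (-1.0 / (1.0 + self.alpha)) - k


# ---------------------------------------------------------------------------
# negatively correlated family: P(k, F) = Z / (k F + 1)^(alpha + 1)
# ---------------------------------------------------------------------------

def _negative_norm_sum(alpha: float) -> float:
    """sum_{k>=1} 1/(k (k+1)^alpha) to near machine precision.

    Split 1/(k(k+1)^alpha) = (k+1)^-(1+alpha) + (k+1)^-(1+alpha)/k; the first
    piece sums to zeta(1+alpha)-1 exactly, the remainder decays like
    k^-(2+alpha) and is summed directly with a Hurwitz-zeta tail bound.
    """
    K = 200_000
    kk = np.arange(1, K + 1, dtype=float)
    rem = np.sum((kk + 1.0) ** (-(1.0 + alpha)) / kk)
    tail = float(special.zeta(2.0 + alpha, K + 2))  # upper estimate, ~1e-13
    return float(special.zeta(1.0 + alpha) - 1.0 + rem + tail)


class NegativeDistribution(JointDegreeFeatureDistribution):
    """Ad hoc anticorrelated joint law P(k,F) = Z (kF+1)^-(alpha+1),
    k >= 1, F in [1, inf), Z = alpha / sum_k 1/(k (k+1)^alpha)."""

    family = "negative"

    def __init__(self, alpha: float, k_max: int | None = None,
                 tail_tol: float = DEFAULT_TAIL_TOL,
                 max_tail: float | None = None):
        if not alpha > 1.0:
            raise DomainError(f"exponent alpha={alpha} violates alpha > 1")
        self.alpha = float(alpha)
        self.params = {"alpha": self.alpha}
        self.tail_tol = float(tail_tol)
        self.norm_sum = _negative_norm_sum(alpha)
        self.Z = alpha / self.norm_sum
        if k_max is None:
            # p_k tail ~ K^-alpha / (alpha * norm_sum)
            k_max = math.ceil((tail_tol * alpha * self.norm_sum) ** (-1.0 / alpha))
            k_max = min(K_CAP, max(16, k_max))
        self.k = np.arange(1, k_max + 1)
        kf = self.k.astype(float)
        self.pk = (kf + 1.0) ** (-alpha) / (kf * self.norm_sum)
        self.tail_mass = max(0.0, 1.0 - float(self.pk.sum()))
        _check_truncation(self.tail_mass, tail_tol, self.family, max_tail)
        self.mean_degree = float((special.zeta(alpha) - 1.0) / self.norm_sum)
        self.feature_support = (1.0, math.inf)

    def conditional_pdf(self, k, f):
        k = np.asarray(k, dtype=float)
        f = np.asarray(f, dtype=float)
        out = self.alpha * k * (k + 1.0) ** self.alpha \
            * (k * f + 1.0) ** (-(1.0 + self.alpha))
        return np.where(f >= 1.0, out, 0.0)

    def conditional_cdf(self, k, f):
        k = np.asarray(k, dtype=float)
        f = np.asarray(f, dtype=float)
        sf = ((k * f + 1.0) / (k + 1.0)) ** (-self.alpha)
        return np.where(f >= 1.0, 1.0 - sf, 0.0)

    def conditional_ppf(self, k, q):
        k = np.asarray(k, dtype=float)
        q = np.asarray(q, dtype=float)
        return ((k + 1.0) * (1.0 - q) ** (-1.0 / self.alpha) - 1.0) / k


# ---------------------------------------------------------------------------
# approximate (conditional-Gaussian) family
# ---------------------------------------------------------------------------

class ApproximateGaussianJoint(JointDegreeFeatureDistribution):
    """P(k,F) = Z h(k) exp(-(F - mu(k))^2 / (2 sigma(k)^2)) on a finite
    degree range with F restricted to a bounded support.

    The Gaussian mass outside the support is renormalised per degree, so
    every conditional is a proper truncated normal.
    """

    family = "approximate"

    def __init__(self, k_values: Sequence[int],
                 mu: Callable, sigma: Callable, height: Callable,
                 feature_support: tuple[float, float] = (0.0, 1.0)):
        self.k = np.asarray(k_values, dtype=int)
        if self.k.size == 0:
            raise DomainError("empty degree range")
        lo, hi = feature_support
        if not hi > lo:
            raise DomainError("feature support must be a non-empty interval")
        kf = self.k.astype(float)
        self._mu = np.asarray(mu(kf), dtype=float)
        self._sigma = np.asarray(sigma(kf), dtype=float)
        self._h = np.asarray(height(kf), dtype=float)
        if np.any(self._sigma <= 0):
            raise DomainError("sigma(k) must be positive on the degree range")
        if np.any(self._h <= 0):
            raise DomainError("h(k) must be positive on the degree range")
        a = (lo - self._mu) / self._sigma
        b = (hi - self._mu) / self._sigma
        self._cdf_lo = special.ndtr(a)
        self._mass = special.ndtr(b) - self._cdf_lo
        if np.any(self._mass <= 0):
            raise DomainError("conditional Gaussian mass vanishes inside support")
        weights = self._h * self._sigma * np.sqrt(2 * np.pi) * self._mass
        total = weights.sum()
        if not np.isfinite(total) or total <= 0:
            raise DomainError("joint law is not normalizable")
        self.Z = 1.0 / total
        self.pk = weights / total
        self.mean_degree = float((self.k * self.pk).sum())
        self.feature_support = (float(lo), float(hi))
        self.tail_mass = 0.0
        self.params = {"k_min": int(self.k[0]), "k_max": int(self.k[-1])}
        self.mu_fn, self.sigma_fn, self.height_fn = mu, sigma, height

    def _idx(self, k):
        k = np.asarray(k)
        idx = np.searchsorted(self.k, k)
        idx = np.clip(idx, 0, self.k.size - 1)
        ok = self.k[idx] == k
        return idx, ok

    def conditional_pdf(self, k, f):
        idx, ok = self._idx(k)
        mu, sg, mass = self._mu[idx], self._sigma[idx], self._mass[idx]
        f = np.asarray(f, dtype=float)
        lo, hi = self.feature_support
        pdf = np.exp(-0.5 * ((f - mu) / sg) ** 2) / (sg * np.sqrt(2 * np.pi) * mass)
        pdf = np.where((f >= lo) & (f <= hi) & ok, pdf, 0.0)
        return pdf

    def conditional_cdf(self, k, f):
        idx, ok = self._idx(k)
        mu, sg = self._mu[idx], self._sigma[idx]
        f = np.asarray(f, dtype=float)
        lo, hi = self.feature_support
        z = special.ndtr((np.clip(f, lo, hi) - mu) / sg)
        out = (z - self._cdf_lo[idx]) / self._mass[idx]
        out = np.clip(out, 0.0, 1.0)
        out = np.where(f < lo, 0.0, np.where(f > hi, 1.0, out))
        return np.where(ok, out, 0.0)

    def conditional_ppf(self, k, q):
        idx, _ = self._idx(k)
        mu, sg = self._mu[idx], self._sigma[idx]
        q = np.asarray(q, dtype=float)
        p = self._cdf_lo[idx] + q * self._mass[idx]
        f = mu + sg * special.ndtri(np.clip(p, 1e-300, 1 - 1e-16))
        return np.clip(f, *self.feature_support)


# ---------------------------------------------------------------------------
# discrete-feature and custom distributions
# ---------------------------------------------------------------------------

class DiscreteFeatureJoint(JointDegreeFeatureDistribution):
    """Joint law with features on a finite grid: table of masses m[k, F]."""

    family = "discrete"

    def __init__(self, k_values, f_values, mass, normalize: bool = True):
        self.k = np.asarray(k_values, dtype=int)
        self.f_values = np.asarray(f_values, dtype=float)
        m = np.asarray(mass, dtype=float)
        if m.shape != (self.k.size, self.f_values.size):
            raise DomainError("mass table shape must be (n_k, n_F)")
        if np.any(m < 0):
            raise DomainError("negative mass in table")
        tot = m.sum()
        if tot <= 0:
            raise DomainError("mass table sums to zero")
        if normalize:
            m = m / tot
        elif abs(tot - 1.0) > 1e-8:
            raise DomainError(f"mass table sums to {tot}, not 1")
        self.mass = m
        self.pk = m.sum(axis=1)
        self.mean_degree = float((self.k * self.pk).sum())
        self.feature_support = (float(self.f_values[0]), float(self.f_values[-1]))
        self.tail_mass = 0.0
        self.discrete_features = True
        self.params = {"n_k": int(self.k.size), "n_F": int(self.f_values.size)}
        with np.errstate(invalid="ignore"):
            cond = np.where(self.pk[:, None] > 0, m / self.pk[:, None], 0.0)
        self._cond = cond
        self._cond_cdf = np.cumsum(cond, axis=1)

    def _idx(self, k):
        k = np.asarray(k)
        idx = np.clip(np.searchsorted(self.k, k), 0, self.k.size - 1)
        return idx, self.k[idx] == k

    def conditional_pdf(self, k, f):
        # mass at grid points (exact matches only)
        idx, ok = self._idx(k)
        f = np.asarray(f, dtype=float)
        j = np.clip(np.searchsorted(self.f_values, f), 0, self.f_values.size - 1)
        hit = np.isclose(self.f_values[j], f)
        return np.where(ok & hit, self._cond[idx, j], 0.0)

    def conditional_cdf(self, k, f):
        idx, ok = self._idx(k)
        f = np.asarray(f, dtype=float)
        j = np.searchsorted(self.f_values, f, side="right") - 1
        out = np.where(j >= 0, self._cond_cdf[idx, np.maximum(j, 0)], 0.0)
        return np.where(ok, out, 0.0)

    def mass_below(self, k, f):
        # strictly below f: theta(0)=1 removal keeps F < F0 only
        idx, ok = self._idx(k)
        f = np.asarray(f, dtype=float)
        j = np.searchsorted(self.f_values, f, side="left") - 1
        out = np.where(j >= 0, self._cond_cdf[idx, np.maximum(j, 0)], 0.0)
        return np.where(ok, out, 0.0)

    def conditional_ppf(self, k, q):
        idx, _ = self._idx(k)
        q = np.asarray(q, dtype=float)
        out = np.empty(np.broadcast_shapes(idx.shape, q.shape))
        idx_b, q_b = np.broadcast_arrays(idx, q)
        for i in np.ndindex(out.shape):
            row = self._cond_cdf[idx_b[i]]
            out[i] = self.f_values[np.searchsorted(row, q_b[i], side="left").clip(0, row.size - 1)]
        return out


class CustomJoint(JointDegreeFeatureDistribution):
    """User-supplied joint law given as callables satisfying the contract.

    Parameters
    ----------
    k_values, pk : degree support and marginal (need not be normalised).
    conditional_cdf, conditional_ppf : vectorised callables ``(k, f) -> q``
        and ``(k, q) -> f``.
    conditional_pdf : optional; required only by density-based routines.
    """

    family = "custom"

    def __init__(self, k_values, pk, conditional_cdf, conditional_ppf,
                 conditional_pdf=None, feature_support=(0.0, math.inf),
                 mean_degree: float | None = None, validate: bool = True):
        self.k = np.asarray(k_values, dtype=int)
        pk = np.asarray(pk, dtype=float)
        if np.any(pk < 0):
            raise DomainError("negative degree mass")
        tot = pk.sum()
        if tot <= 0:
            raise DomainError("degree marginal sums to zero")
        self.tail_mass = abs(1.0 - tot)
        self.pk = pk / tot
        self._cdf_fn = conditional_cdf
        self._ppf_fn = conditional_ppf
        self._pdf_fn = conditional_pdf
        self.feature_support = tuple(map(float, feature_support))
        self.mean_degree = float(mean_degree) if mean_degree is not None \
            else float((self.k * self.pk).sum())
        self.params = {"k_min": int(self.k[0]), "k_max": int(self.k[-1])}
        if validate:
            self._validate()

    def _validate(self):
        lo, hi = self.feature_support
        probe = lo + (min(hi, lo + 10.0) - lo) * np.linspace(0, 1, 7)[1:]
        for kk in self.k[:: max(1, self.k.size // 8)]:
            c = np.asarray(self._cdf_fn(kk, probe), dtype=float)
            if np.any(np.diff(c) < -1e-10) or np.any(c < -1e-10) or np.any(c > 1 + 1e-10):
                raise DomainError(f"conditional CDF invalid at k={kk}")
            q = np.array([0.1, 0.5, 0.9])
            f = np.asarray(self._ppf_fn(kk, q), dtype=float)
            if np.any(f < lo - 1e-9) or np.any(f > hi + 1e-9):
                raise DomainError(f"conditional PPF leaves support at k={kk}")

    def conditional_cdf(self, k, f):
        return self._cdf_fn(k, f)

    def conditional_ppf(self, k, q):
        return self._ppf_fn(k, q)

    def conditional_pdf(self, k, f):
        if self._pdf_fn is None:
            raise DomainError("custom distribution has no conditional density")
        return self._pdf_fn(k, f)


# ---------------------------------------------------------------------------
# public constructors (stable API)
# ---------------------------------------------------------------------------

def make_independent(a: float, alpha: float,
                     tail_tol: float = DEFAULT_TAIL_TOL) -> IndependentDistribution:
    """Independent family: geometric(a) degrees, Pareto(alpha) features."""
    return IndependentDistribution(a, alpha, tail_tol=tail_tol)


def make_positive(alpha: float, k_max: int | None = None,
                  tail_tol: float = DEFAULT_TAIL_TOL,
                  max_tail: float | None = None) -> PositiveDistribution:
    """Positively correlated family P(k,F) = Z (k+F)^-(2+alpha).

    ``max_tail`` overrides the hard limit on the truncated tail mass
    (useful for qualitative sweeps with alpha close to 1, where the cap
    cannot reach the default 1e-8).
    """
    return PositiveDistribution(alpha, k_max=k_max, tail_tol=tail_tol,
                                max_tail=max_tail)


def make_negative(alpha: float, k_max: int | None = None,
                  tail_tol: float = DEFAULT_TAIL_TOL,
                  max_tail: float | None = None) -> NegativeDistribution:
    """Negatively correlated family P(k,F) = Z (kF+1)^-(alpha+1)."""
    return NegativeDistribution(alpha, k_max=k_max, tail_tol=tail_tol,
                                max_tail=max_tail)


def sample_pairs(dist: JointDegreeFeatureDistribution, n: int, seed=None):
    """Draw ``n`` (degree, feature) pairs; reproducible for a fixed seed."""
    if n < 1:
        raise DomainError(f"sample size n={n} must be >= 1")
    return dist.sample(n, seed)


def conditional_mean_degree(dist: JointDegreeFeatureDistribution, f) -> float:
    """Mean degree conditioned on feature value ``f``."""
    return dist.conditional_mean_degree(f)


def shuffled_product(dist: JointDegreeFeatureDistribution) -> CustomJoint:
    """Product of the marginals of ``dist``: same p_k, same P(F), but with
    the degree-feature correlation destroyed.

    The marginal feature CDF is tabulated on a quantile grid and inverted
    by interpolation, which preserves both marginals to interpolation
    accuracy (the tabulation trims degrees carrying < 1e-6 total mass).
    """
    lo, hi = dist.feature_support
    # build marginal CDF on a dense grid of conditional quantiles
    qs = np.concatenate([np.linspace(0, 0.98, 200),
                         1.0 - np.geomspace(0.02, 1e-9, 200)])
    probe_ks = dist.k[np.unique(np.linspace(0, dist.k.size - 1, 12).astype(int))]
    probes = np.unique(np.concatenate([
        np.asarray(dist.conditional_ppf(kk, qs), dtype=float)
        for kk in probe_ks
    ]))
    if probes.size > 800:
        probes = probes[np.unique(np.linspace(0, probes.size - 1, 800).astype(int))]
    # trim the degree support for the tabulation only
    cum = np.cumsum(dist.pk)
    n_trim = int(np.searchsorted(cum, 1.0 - 1e-6)) + 1
    k_t = dist.k[:n_trim]
    pk_t = dist.pk[:n_trim] / dist.pk[:n_trim].sum()
    cdf = np.zeros(probes.size)
    for start in range(0, k_t.size, 4096):
        kc = k_t[start:start + 4096, None]
        wc = pk_t[start:start + 4096]
        cdf += wc @ np.asarray(dist.mass_below(kc, probes[None, :]), dtype=float)
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    probes, cdf = probes[keep], cdf[keep]

    def marg_cdf(k, f):
        return np.interp(np.asarray(f, dtype=float), probes, cdf,
                         left=0.0, right=1.0)

    def marg_ppf(k, q):
        return np.interp(np.asarray(q, dtype=float), cdf, probes,
                         left=probes[0], right=probes[-1])

    return CustomJoint(dist.k, dist.pk, marg_cdf, marg_ppf,
                       feature_support=(lo, hi),
                       mean_degree=dist.mean_degree, validate=False)


def from_spec(spec: dict | str) -> JointDegreeFeatureDistribution:
    """Rebuild an analytic family from its JSON specification."""
    if isinstance(spec, str):
        spec = json.loads(spec)
    family = spec["family"]
    params = spec.get("params", {})
    tol = spec.get("tail_tol", DEFAULT_TAIL_TOL)
    if family == "independent":
        return make_independent(params["a"], params["alpha"], tail_tol=tol)
    if family == "positive":
        return make_positive(params["alpha"], tail_tol=tol)
    if family == "negative":
        return make_negative(params["alpha"], tail_tol=tol)
    raise DomainError(f"cannot rebuild family {family!r} from a spec")
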