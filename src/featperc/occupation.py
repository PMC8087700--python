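"""Occupation rules: the retention probability phi(k, F).

The Heaviside convention is theta(0) = 1.  Concretely:

* ``feature_upper_threshold(F0)`` removes nodes with ``F >= F0`` (retains
  ``F < F0``),
* ``feature_lower_threshold(r0)`` removes nodes with ``F < r0`` (retains
  ``F >= r0``),
* ``degree_upper_threshold(k0)`` removes nodes with ``k > k0``.

For continuous features the boundary has measure zero; the discrete-feature
mode honours the same convention exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import DomainError

_QUAD_NODES = 256


@dataclass(frozen=True)
class OccupationRule:
    kind: str
    phi_const: float | None = None
    k0: int | None = None
    F0: float | None = None
    r0: float | None = None
    custom_phi: Callable | None = field(default=None, compare=False)

    # -- constructors -----------------------------------------------------
    @classmethod
    def uniform(cls, phi: float) -> "OccupationRule":
        if not (0.0 <= phi <= 1.0):
            raise DomainError(f"phi={phi} violates 0 <= phi <= 1")
        return cls(kind="uniform", phi_const=float(phi))

    @classmethod
    def degree_upper_threshold(cls, k0: int) -> "OccupationRule":
        if k0 < 0:
            raise DomainError(f"degree cut k0={k0} must be >= 0")
        return cls(kind="degree_upper_threshold", k0=int(k0))

    @classmethod
    def feature_upper_threshold(cls, F0: float) -> "OccupationRule":
        return cls(kind="feature_upper_threshold", F0=float(F0))

    @classmethod
    def feature_lower_threshold(cls, r0: float) -> "OccupationRule":
        return cls(kind="feature_lower_threshold", r0=float(r0))

    @classmethod
    def custom(cls, phi: Callable) -> "OccupationRule":
        return cls(kind="custom", custom_phi=phi)

    # -- evaluation --------------------------------------------------------
    def phi(self, k, f):
        """phi(k, F), vectorised; values are validated to lie in [0, 1]."""
        k = np.asarray(k)
        f = np.asarray(f, dtype=float)
        if self.kind == "uniform":
            out = np.full(np.broadcast_shapes(k.shape, f.shape), self.phi_const)
        elif self.kind == "degree_upper_threshold":
            out = np.broadcast_to((k <= self.k0).astype(float),
                                  np.broadcast_shapes(k.shape, f.shape)).copy()
        elif self.kind == "feature_upper_threshold":
            out = np.broadcast_to((f < self.F0).astype(float),
                                  np.broadcast_shapes(k.shape, f.shape)).copy()
        elif self.kind == "feature_lower_threshold":
            out = np.broadcast_to((f >= self.r0).astype(float),
                                  np.broadcast_shapes(k.shape, f.shape)).copy()
        elif self.kind == "custom":
            out = np.asarray(self.custom_phi(k, f), dtype=float)
            if np.any(out < -1e-12) or np.any(out > 1 + 1e-12):
                raise DomainError("custom phi(k,F) left the interval [0, 1]")
            out = np.clip(out, 0.0, 1.0)
        else:  # pragma: no cover
            raise DomainError(f"unknown rule kind {self.kind!r}")
        return out

    def retained_mass(self, dist, k=None) -> np.ndarray:
        """c_k = int dF phi(k, F) P(F|k), vectorised over the degree support.

        Dispatches to the analytic conditional CDF/SF for threshold rules;
        custom rules are integrated by Gauss-Legendre quadrature in the
        quantile domain (exact for smooth phi, approximate across jumps).
        """
        if k is None:
            k = dist.k
        k = np.asarray(k)
        if self.kind == "uniform":
            return np.full(k.shape, self.phi_const, dtype=float)
        if self.kind == "degree_upper_threshold":
            return (k <= self.k0).astype(float)
        if self.kind == "feature_upper_threshold":
            return np.asarray(dist.mass_below(k, self.F0), dtype=float)
        if self.kind == "feature_lower_threshold":
            return np.asarray(dist.mass_at_or_above(k, self.r0), dtype=float)
        # custom: int_0^1 phi(k, ppf(k, q)) dq
        q, w = np.polynomial.legendre.leggauss(_QUAD_NODES)
        q = 0.5 * (q + 1.0)
        w = 0.5 * w
        out = np.empty(k.shape, dtype=float)
        for i, kk in np.ndenumerate(k):
            f = np.asarray(dist.conditional_ppf(kk, q), dtype=float)
            out[i] = float(np.dot(w, self.phi(np.full(q.shape, kk), f)))
        return np.clip(out, 0.0, 1.0)

    def to_spec(self) -> dict:
        d = {"kind": self.kind}
        for name in ("phi_const", "k0", "F0", "r0"):
            v = getattr(self, name)
            if v is not None:
                d[name] = v
        return d

    @classmethod
    def from_spec(cls, spec: dict) -> "OccupationRule":
        kind = spec["kind"]
        if kind == "uniform":
            return cls.uniform(spec["phi_const"])
        if kind == "degree_upper_threshold":
            return cls.degree_upper_threshold(spec["k0"])
        if kind == "feature_upper_threshold":
            return cls.feature_upper_threshold(spec["F0"])
        if kind == "feature_lower_threshold":
            return cls.feature_lower_threshold(spec["r0"])
        raise DomainError(f"cannot rebuild rule kind {kind!r} from a spec")
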