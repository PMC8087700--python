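"""Approximate joint degree-feature laws fitted from (k, F) observations.

The construction follows a conditional-Gaussian ansatz: for each observed
degree the feature histogram is summarised by its mean, spread and peak
height; three closed-form families are then fitted to those summaries by
weighted nonlinear least squares, and the fitted functions are assembled
into a proper joint distribution (truncated-normal conditionals on a
bounded feature support, jointly normalised).

Symbolic-regression engines can be plugged in by registering additional
families in :data:`FAMILIES` or passing callables directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .distributions import ApproximateGaussianJoint
from .errors import DomainError, FitError


@dataclass
class Family:
    """A parametric closed-form family for one conditional summary."""

    name: str
    fn: Callable  # fn(k, *params)
    n_params: int
    p0: Sequence[float]
    bounds: tuple = (-np.inf, np.inf)


def _exp_ratio(k, a, b):
    # exp(a / (b - k)); the fitted b sits outside the data range
    with np.errstate(over="ignore", divide="ignore"):
        return np.exp(a / (b - k))


def _inv_quad(k, a, b):
    return a / (k * (b + k))


FAMILIES: dict[str, Family] = {
    "exp_ratio": Family("exp_ratio", _exp_ratio, 2, (1.0, -1.0)),
    "inv_quad": Family("inv_quad", _inv_quad, 2, (1.0, 1.0),
                       ((1e-12, -np.inf), (np.inf, np.inf))),
    "power_law": Family("power_law", lambda k, a, b: a * k ** b, 2, (1.0, 0.5)),
    "linear": Family("linear", lambda k, a, b: a + b * k, 2, (0.0, 1.0)),
    "constant": Family("constant", lambda k, a: a + 0.0 * k, 1, (1.0,)),
}


def resolve_family(family, fitted_mu: Callable | None = None) -> Family:
    if isinstance(family, Family):
        return family
    if callable(family):
        import inspect
        n = len(inspect.signature(family).parameters) - 1
        return Family(getattr(family, "__name__", "user"), family, n, [1.0] * n)
    if family == "exp_ratio_minus_mu":
        if fitted_mu is None:
            raise DomainError("exp_ratio_minus_mu requires the fitted mu")
        return Family("exp_ratio_minus_mu",
                      lambda k, a, b: _exp_ratio(k, a, b) - fitted_mu(k),
                      2, (2.0, -1.0))
    try:
        return FAMILIES[family]
    except KeyError:
        raise DomainError(f"unknown family {family!r}; "
                          f"known: {sorted(FAMILIES)}") from None


def summarize_conditionals(degrees, features, n_bins: int | None = None,
                           feature_range: tuple[float, float] | None = None,
                           n_min: int = 5) -> pd.DataFrame:
    """Per-degree summary of the conditional feature histograms.

    Returns a DataFrame indexed by degree with columns ``count``, ``mean``,
    ``std``, ``peak`` (maximum bin count of the F-histogram at that degree,
    on a common binning) and ``reliable`` (count >= n_min).  Bin count
    defaults to a Freedman-Diaconis-style rule on the pooled features.
    """
    degrees = np.asarray(degrees)
    features = np.asarray(features, dtype=float)
    if degrees.size == 0:
        raise DomainError("empty pair table")
    if degrees.shape != features.shape:
        raise DomainError("degrees and features must have equal length")
    if feature_range is None:
        feature_range = (float(features.min()), float(features.max()))
    if n_bins is None:
        iqr = np.subtract(*np.percentile(features, [75, 25]))
        width = 2.0 * iqr / features.size ** (1.0 / 3.0)
        span = feature_range[1] - feature_range[0]
        n_bins = int(np.clip(np.ceil(span / width) if width > 0 else 50, 10, 400))
    edges = np.linspace(*feature_range, n_bins + 1)
    rows = []
    for k in np.unique(degrees):
        sel = features[degrees == k]
        hist, _ = np.histogram(sel, bins=edges)
        rows.append({
            "k": int(k),
            "count": sel.size,
            "mean": float(sel.mean()),
            "std": float(sel.std(ddof=1)) if sel.size > 1 else 0.0,
            "peak": int(hist.max()),
            "reliable": sel.size >= n_min,
        })
    df = pd.DataFrame(rows).set_index("k")
    df.attrs["bin_edges"] = edges
    df.attrs["bin_width"] = float(edges[1] - edges[0])
    df.attrs["n_pairs"] = int(degrees.size)
    return df


@dataclass
class ConditionalGaussianFit:
    """Fitted mean/spread/peak-height functions of the degree."""

    mu_family: str
    mu_params: np.ndarray
    sigma_family: str
    sigma_params: np.ndarray
    h_family: str
    h_params: np.ndarray
    k_m: int
    k_max: int
    residuals: dict = field(default_factory=dict)
    summary: pd.DataFrame | None = None
    _fns: dict = field(default_factory=dict, repr=False)

    def mu(self, k):
        return self._fns["mu"](np.asarray(k, dtype=float))

    def sigma(self, k):
        return self._fns["sigma"](np.asarray(k, dtype=float))

    def height(self, k):
        return self._fns["h"](np.asarray(k, dtype=float))

    def to_dict(self) -> dict:
        return {
            "mu": {"family": self.mu_family, "params": list(self.mu_params)},
            "sigma": {"family": self.sigma_family,
                      "params": list(self.sigma_params)},
            "h": {"family": self.h_family, "params": list(self.h_params)},
            "k_m": self.k_m,
            "k_max": self.k_max,
            "residual_norms": {n: float(np.linalg.norm(r))
                               for n, r in self.residuals.items()},
        }


def _fit_one(name, family: Family, kk, yy, weights, p0=None):
    p0 = list(p0) if p0 is not None else list(family.p0)
    sigma = 1.0 / np.sqrt(weights)
    try:
        popt, _ = curve_fit(family.fn, kk, yy, p0=p0, sigma=sigma,
                            bounds=family.bounds, maxfev=20_000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"fit of {name} ({family.name}) failed: {exc}",
                       params=p0) from exc
    resid = yy - family.fn(kk, *popt)
    return np.asarray(popt), resid


def fit_conditional_families(summary: pd.DataFrame,
                             mu_family="exp_ratio",
                             sigma_family="exp_ratio_minus_mu",
                             h_family="inv_quad",
                             p0: dict | None = None,
                             use_unreliable: bool = False) -> ConditionalGaussianFit:
    """Weighted least-squares fit of the three conditional summaries.

    Each component is fitted against the per-degree summary produced by
    :func:`summarize_conditionals`, weighted by the per-degree counts.  The
    spread family may reference the already-fitted mean (the
    ``exp_ratio_minus_mu`` ansatz), so mu is fitted first.
    """
    df = summary if use_unreliable else summary[summary["reliable"]]
    if len(df) < 2:
        raise DomainError("need summaries at >= 2 degrees to fit")
    kk = df.index.to_numpy(dtype=float)
    w = df["count"].to_numpy(dtype=float)
    p0 = p0 or {}

    fam_mu = resolve_family(mu_family)
    mu_params, mu_resid = _fit_one("mu", fam_mu, kk, df["mean"].to_numpy(float),
                                   w, p0.get("mu"))
    mu_fn = lambda k: fam_mu.fn(k, *mu_params)

    fam_sg = resolve_family(sigma_family, fitted_mu=mu_fn)
    sg_params, sg_resid = _fit_one("sigma", fam_sg, kk,
                                   df["std"].to_numpy(float), w, p0.get("sigma"))
    sg_fn = lambda k: fam_sg.fn(k, *sg_params)

    fam_h = resolve_family(h_family)
    h_params, h_resid = _fit_one("h", fam_h, kk, df["peak"].to_numpy(float),
                                 w, p0.get("h"))
    h_fn = lambda k: fam_h.fn(k, *h_params)

    return ConditionalGaussianFit(
        mu_family=fam_mu.name, mu_params=mu_params,
        sigma_family=fam_sg.name, sigma_params=sg_params,
        h_family=fam_h.name, h_params=h_params,
        k_m=int(df.index.min()), k_max=int(df.index.max()),
        residuals={"mu": mu_resid, "sigma": sg_resid, "h": h_resid},
        summary=summary,
        _fns={"mu": mu_fn, "sigma": sg_fn, "h": h_fn})


def build_approximate_joint(fit: ConditionalGaussianFit,
                            feature_support: tuple[float, float] = (0.0, 1.0),
                            k_values=None) -> ApproximateGaussianJoint:
    """Assemble P(k,F) = Z h(k) exp(-(F-mu(k))^2 / (2 sigma(k)^2)) on the
    fitted degree range, with truncated-normal conditionals renormalised to
    the feature support."""
    if k_values is None:
        k_values = np.arange(fit.k_m, fit.k_max + 1)
    return ApproximateGaussianJoint(k_values, mu=fit.mu, sigma=fit.sigma,
                                    height=fit.height,
                                    feature_support=feature_support)
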