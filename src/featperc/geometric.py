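"""Random geometric graphs on the unit torus with nearest-neighbour
distance features.

Nodes are placed uniformly on [0,1)^2 with periodic boundaries and linked
when their toroidal distance is below the connection radius ``r``.  The
feature of a node is the distance to its nearest *point* (graph-independent:
the closest other node, whether or not it is within ``r``).  The removal
rule deletes, synchronously on the original configuration, every node whose
nearest neighbour lies closer than ``r0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import closedforms
from .distributions import _as_rng
from .errors import DomainError
from .percolation import PercolationSolution, solve_generating_functions
from .simulation import FeatureNetwork, giant_fraction_sim


@dataclass(frozen=True)
class RGGSpec:
    N: int
    r: float
    r0: float = 0.0

    def __post_init__(self):
        if self.N < 2:
            raise DomainError(f"N={self.N} must be >= 2")
        if not (0.0 <= self.r0 <= self.r < 0.5):
            raise DomainError(
                f"radii must satisfy 0 <= r0 <= r < 0.5, got r0={self.r0}, r={self.r}")


def toroidal_distance(p, q) -> float:
    """Distance on the unit torus [0,1)^2."""
    d = np.abs(np.asarray(p, dtype=float) - np.asarray(q, dtype=float))
    d = np.minimum(d, 1.0 - d)
    return float(np.sqrt((d * d).sum(axis=-1)))


def rgg_build(spec: RGGSpec, seed=None) -> FeatureNetwork:
    """Sample positions, link within r, attach d_min features."""
    rng = _as_rng(seed)
    pos = rng.random((spec.N, 2))
    tree = cKDTree(pos, boxsize=1.0)
    pairs = tree.query_pairs(spec.r, output_type="ndarray")
    dists, _ = tree.query(pos, k=2)
    features = dists[:, 1]
    edges = pairs[pairs[:, 0] != pairs[:, 1]]
    return FeatureNetwork(n=spec.N, edges=np.sort(edges, axis=1),
                          features=features, positions=pos,
                          meta={"family": "rgg", "r": spec.r, "N": spec.N})


def rgg_occupy(net: FeatureNetwork, r0: float) -> np.ndarray:
    """Retention mask F >= r0, evaluated synchronously on the original
    configuration (mutually-close pairs are both removed; no cascading)."""
    if r0 <= 0:
        raise DomainError(f"removal radius r0={r0} must be positive")
    return net.features >= r0


def rgg_theory(spec: RGGSpec, tol: float = 1e-12) -> PercolationSolution:
    """Percolation solution from the closed-form binomial generating
    functions with degree bound k_max = N - 1."""
    N, r, r0 = spec.N, spec.r, spec.r0
    return solve_generating_functions(
        g0_fn=lambda u: closedforms.rgg_g0(u, N, r, r0),
        g1_fn=lambda u: closedforms.rgg_g1(u, N, r, r0),
        branching=closedforms.rgg_branching(N, r, r0),
        tol=tol)


def rgg_theory_curve(N: int, r: float, r0_grid):
    """Theory S over a removal-radius sweep at fixed N and r."""
    from .curves import TheoryCurve

    r0_grid = np.asarray(r0_grid, dtype=float)
    S = np.empty(r0_grid.size)
    u = np.empty(r0_grid.size)
    br = np.empty(r0_grid.size)
    for i, r0 in enumerate(r0_grid):
        sol = rgg_theory(RGGSpec(N=N, r=r, r0=float(r0)))
        S[i], u[i], br[i] = sol.S, sol.u, sol.branching_factor
    return TheoryCurve(param_name="r0", grid=r0_grid, S=S, u=u, branching=br,
                       meta={"family": "rgg", "N": N, "r": r})


def rgg_ensemble_curve(N: int, r: float, r0_grid, reps: int, seed: int):
    """Simulated mean S over a removal-radius sweep.

    One realization serves the whole grid (the removal rule is
    deterministic given the positions), matching the synchronous-removal
    protocol.
    """
    from .curves import EnsembleCurve

    r0_grid = np.asarray(r0_grid, dtype=float)
    samples = np.empty((reps, r0_grid.size))
    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))
        net = rgg_build(RGGSpec(N=N, r=r), rng)
        for j, r0 in enumerate(r0_grid):
            mask = rgg_occupy(net, float(r0)) if r0 > 0 \
                else np.ones(net.n, dtype=bool)
            samples[rep, j] = giant_fraction_sim(net, mask)
    se = samples.std(axis=0, ddof=1) / math.sqrt(reps) if reps > 1 \
        else np.zeros(r0_grid.size)
    return EnsembleCurve(param_name="r0", grid=r0_grid,
                         S_mean=samples.mean(axis=0), S_se=se,
                         n_reps=reps, seed=seed,
                         meta={"family": "rgg", "N": N, "r": r})
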