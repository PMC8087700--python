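"""Configuration-model simulation of feature-enriched percolation.

Networks are wired by uniform stub matching from a degree sequence sampled
from the distribution's degree marginal, then simplified (self-loops
dropped, parallel edges collapsed).  Features are drawn per node from the
conditional law at the node's *sampled* degree.  Giant components are
measured on the retained induced subgraph and normalised by the
pre-removal node count, matching the theory's normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .curves import EnsembleCurve
from .distributions import JointDegreeFeatureDistribution, _as_rng
from .errors import ConvergenceError, DomainError
from .occupation import OccupationRule

_PARITY_RETRIES = 10_000


@dataclass
class FeatureNetwork:
    """An undirected simple graph with one feature value per node."""

    n: int
    edges: np.ndarray                     # (E, 2) int array, i < j, unique
    features: np.ndarray | None = None    # (n,) float
    target_degrees: np.ndarray | None = None
    positions: np.ndarray | None = None   # (n, 2) for spatial graphs
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= self.n):
            raise DomainError("edge endpoint outside [0, n)")

    @property
    def degrees(self) -> np.ndarray:
        """Degree vector of the simplified adjacency."""
        return np.bincount(self.edges.ravel(), minlength=self.n)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def adjacency(self) -> sparse.csr_matrix:
        e = self.edges
        data = np.ones(2 * e.shape[0])
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))


def _simplify(n: int, pairs: np.ndarray) -> np.ndarray:
    """Sort endpoints, drop self-loops, collapse parallel edges."""
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    pairs = np.sort(pairs, axis=1)
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    # unique via linearised codes (faster than np.unique(axis=0))
    codes = pairs[:, 0].astype(np.int64) * n + pairs[:, 1]
    codes = np.unique(codes)
    return np.column_stack([codes // n, codes % n])


def build_network(dist: JointDegreeFeatureDistribution, N: int,
                  seed=None) -> FeatureNetwork:
    """Configuration-model network with per-node features from P(F|k).

    The degree-sequence parity is fixed by resampling the last node's
    degree until the stub count is even, which preserves p_k in
    distribution.
    """
    if N < 2:
        raise DomainError(f"N={N} must be >= 2")
    rng = _as_rng(seed)
    degrees = dist.sample_degrees(N, rng)
    if degrees.sum() % 2 == 1:
        for _ in range(_PARITY_RETRIES):
            degrees[-1] = dist.sample_degrees(1, rng)[0]
            if degrees.sum() % 2 == 0:
                break
        else:
            raise ConvergenceError(
                "could not fix degree-sequence parity by resampling")
    stubs = np.repeat(np.arange(N), degrees)
    rng.shuffle(stubs)
    edges = _simplify(N, stubs.reshape(-1, 2))
    features = dist.sample_features_given_degrees(degrees, rng)
    return FeatureNetwork(n=N, edges=edges, features=features,
                          target_degrees=degrees,
                          meta={"family": dist.family, "params": dist.params})


def shuffle_features(net: FeatureNetwork, seed=None) -> FeatureNetwork:
    """Uniformly permute the feature vector; topology untouched."""
    rng = _as_rng(seed)
    perm = rng.permutation(net.n)
    return FeatureNetwork(n=net.n, edges=net.edges,
                          features=net.features[perm],
                          target_degrees=net.target_degrees,
                          positions=net.positions,
                          meta={**net.meta, "shuffled": True})


def occupy(net: FeatureNetwork, rule: OccupationRule, seed=None) -> np.ndarray:
    """Boolean retention mask: node i kept with probability phi(k_i, F_i)."""
    rng = _as_rng(seed)
    phi = rule.phi(net.degrees, net.features)
    return rng.random(net.n) < phi


def giant_fraction_sim(net: FeatureNetwork, mask: np.ndarray) -> float:
    """Largest connected component of the retained induced subgraph,
    divided by the original node count."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (net.n,):
        raise DomainError("mask length must equal the node count")
    if not mask.any():
        return 0.0
    e = net.edges
    if e.size:
        keep = mask[e[:, 0]] & mask[e[:, 1]]
        e = e[keep]
    if e.size == 0:
        return 1.0 / net.n
    graph = sparse.csr_matrix(
        (np.ones(e.shape[0]), (e[:, 0], e[:, 1])), shape=(net.n, net.n))
    _, labels = connected_components(graph, directed=False)
    sizes = np.bincount(labels[mask])
    return float(sizes.max()) / net.n


def ensemble_curve(point_factory, grid, N: int, reps: int, seed: int,
                   param_name: str = "param") -> EnsembleCurve:
    """Monte-Carlo S over a parameter sweep.

    ``point_factory(value)`` returns a (distribution, rule) pair per grid
    value; each (grid point, replicate) gets an independent stream derived
    from the master seed through ``SeedSequence(seed, spawn_key=(i, rep))``.
    """
    if reps < 1:
        raise DomainError(f"reps={reps} must be >= 1")
    grid = np.asarray(grid, dtype=float)
    means = np.empty(grid.size)
    ses = np.empty(grid.size)
    for i, value in enumerate(grid):
        dist, rule = point_factory(value)
        samples = np.empty(reps)
        for rep in range(reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(i, rep)))
            net = build_network(dist, N, rng)
            mask = occupy(net, rule, rng)
            samples[rep] = giant_fraction_sim(net, mask)
        means[i] = samples.mean()
        ses[i] = samples.std(ddof=1) / np.sqrt(reps) if reps > 1 else 0.0
    return EnsembleCurve(param_name=param_name, grid=grid, S_mean=means,
                         S_se=ses, n_reps=reps, seed=seed,
                         meta={"N": N, "splitting": "SeedSequence(seed, spawn_key=(point, rep))"})


def giant_samples_at_sizes(dist: JointDegreeFeatureDistribution,
                           rule: OccupationRule, sizes, reps: int,
                           seed: int) -> dict[int, np.ndarray]:
    """Per-size samples of S at fixed parameters (finite-size scaling
    input); seeding scheme as in :func:`ensemble_curve`."""
    out = {}
    for i, N in enumerate(sizes):
        samples = np.empty(reps)
        for rep in range(reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(i, rep)))
            net = build_network(dist, int(N), rng)
            mask = occupy(net, rule, rng)
            samples[rep] = giant_fraction_sim(net, mask)
        out[int(N)] = samples
    return out
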