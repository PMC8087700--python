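"""Node features generated by dynamical processes on a fixed network.

Four deterministic (quenched mean-field) models are integrated to their
steady state; the stationary per-node variable, optionally max-normalised,
becomes the feature used for threshold-based percolation experiments.

Models (all rate constants default to 1):

``sis``          dx_i/dt = -t1 x_i + t2 (1 - x_i) sum_j A_ij x_j
``mutualistic``  dx_i/dt = t1 x_i (1 - x_i) + t2 x_i sum_j A_ij x_j/(1+x_j)
``birth_death``  dx_i/dt = -t1 x_i^2 + t2 sum_j A_ij x_j
``mass_action``  dx_i/dt = t1 - t2 x_i - t3 x_i sum_j A_ij x_j
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .curves import EnsembleCurve
from .distributions import _as_rng
from .errors import DomainError, IntegrationError
from .simulation import FeatureNetwork, _simplify, giant_fraction_sim

_MODEL_KINDS = ("sis", "mutualistic", "birth_death", "mass_action")


@dataclass
class DynamicsModel:
    kind: str
    tau1: float = 1.0
    tau2: float = 1.0
    tau3: float = 1.0
    ss_tol: float = 1e-10
    horizon: float = 1e4
    chunk: float = 25.0
    divergence_bound: float = 1e6
    bd_exponents: tuple[float, float] = (2.0, 1.0)  # birth_death depletion/flow

    def __post_init__(self):
        if self.kind not in _MODEL_KINDS:
            raise DomainError(f"unknown dynamics kind {self.kind!r}")
        if min(self.tau1, self.tau2, self.tau3) < 0:
            raise DomainError("rate constants must be >= 0")
        if self.ss_tol <= 0:
            raise DomainError("steady-state tolerance must be positive")

    def jacobian(self, A, x):
        """Sparse Jacobian of the RHS at x (used by the Newton polish)."""
        from scipy import sparse

        t1, t2, t3 = self.tau1, self.tau2, self.tau3
        n = x.size
        I = sparse.identity(n, format="csr")
        D = sparse.diags
        if self.kind == "sis":
            return -t1 * I - t2 * D(A @ x) + t2 * D(1.0 - x) @ A
        if self.kind == "mutualistic":
            y = x / (1.0 + x)
            return t1 * D(1.0 - 2.0 * x) + t2 * D(A @ y) \
                + t2 * D(x) @ A @ D(1.0 / (1.0 + x) ** 2)
        if self.kind == "birth_death":
            p, q = self.bd_exponents
            xc = np.maximum(x, 1e-300)
            return -t1 * p * D(xc ** (p - 1.0)) + t2 * A @ D(q * xc ** (q - 1.0))
        return -t2 * I - t3 * D(A @ x) - t3 * D(x) @ A

    def rhs(self, A):
        t1, t2, t3 = self.tau1, self.tau2, self.tau3
        if self.kind == "sis":
            def f(t, x):
                return -t1 * x + t2 * (1.0 - x) * (A @ x)
        elif self.kind == "mutualistic":
            def f(t, x):
                return t1 * x * (1.0 - x) + t2 * x * (A @ (x / (1.0 + x)))
        elif self.kind == "birth_death":
            p, q = self.bd_exponents
            def f(t, x):
                xc = np.maximum(x, 0.0)
                return -t1 * xc ** p + t2 * (A @ xc ** q)
        else:  # mass_action
            def f(t, x):
                return t1 - t2 * x - t3 * x * (A @ x)
        return f


@dataclass
class SteadyState:
    x: np.ndarray
    converged: bool
    t_final: float
    residual: float


def integrate_to_steady_state(model: DynamicsModel, net: FeatureNetwork,
                              x0=None, seed=None) -> SteadyState:
    """Advance the ODE system until max_i |dx_i/dt| < ss_tol (or the
    horizon is reached, flagged as unconverged).

    The default initial condition is uniform on (0, 1).  SIS states are
    clipped to [0, 1] on return.
    """
    rng = _as_rng(seed)
    A = net.adjacency()
    if x0 is None:
        x0 = rng.random(net.n)
    x = np.asarray(x0, dtype=float).copy()
    if x.shape != (net.n,):
        raise DomainError("x0 length must equal the node count")
    if model.kind == "sis" and (x.min() < 0 or x.max() > 1):
        raise DomainError("SIS initial condition must lie in [0, 1]^N")
    if x.min() < 0:
        raise DomainError("initial condition must be non-negative")
    f = model.rhs(A)

    def admissible(y):
        if not np.all(np.isfinite(y)):
            return False
        if model.kind == "sis":
            return y.min() > -1e-9 and y.max() < 1.0 + 1e-9
        return y.min() > -1e-9

    def polish(y):
        # Newton refinement inside the fixed point's basin; rejected if it
        # leaves the admissible region or fails to shrink the residual
        from scipy.sparse.linalg import spsolve
        for _ in range(30):
            r = f(0.0, y)
            if np.abs(r).max() < model.ss_tol:
                return y, True
            try:
                step = spsolve(model.jacobian(A, y).tocsc(), r)
            except RuntimeError:  # pragma: no cover
                return y, False
            cand = y - step
            if not admissible(cand) or \
                    np.abs(f(0.0, cand)).max() > 0.9 * np.abs(r).max():
                return y, False
            y = cand
        return y, np.abs(f(0.0, y)).max() < model.ss_tol

    t = 0.0
    residual = float(np.abs(f(t, x)).max())
    while t < model.horizon:
        span = min(model.chunk, model.horizon - t)
        sol = solve_ivp(f, (t, t + span), x, method="RK45",
                        rtol=1e-8, atol=1e-10)
        if not sol.success:  # pragma: no cover
            raise IntegrationError(f"{model.kind}: integrator failed: {sol.message}")
        x = sol.y[:, -1]
        t = sol.t[-1]
        worst = float(np.abs(x).max())
        if not np.isfinite(worst) or worst > model.divergence_bound:
            bad = int(np.nanargmax(np.abs(x)))
            raise IntegrationError(
                f"{model.kind}: state diverged at node {bad} (|x|={worst:.3g})")
        residual = float(np.abs(f(t, x)).max())
        if residual < 1e-4:
            polished, ok = polish(x.copy())
            if ok:
                x = polished
                residual = float(np.abs(f(t, x)).max())
                break
        if residual < model.ss_tol:
            break
    converged = residual < model.ss_tol
    if model.kind == "sis":
        x = np.clip(x, 0.0, 1.0)
    return SteadyState(x=x, converged=converged, t_final=t, residual=residual)


def features_from_state(x, normalize: bool = True):
    """Feature vector from a steady state: F = x / max(x) (or raw x).

    Returns ``(features, all_zero_flag)``; an all-zero state yields all-zero
    features with the flag raised instead of an error.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12):
        raise DomainError("steady state must be non-negative")
    top = x.max()
    if top <= 0.0:
        return np.zeros_like(x), True
    return (x / top if normalize else x.copy()), False


def collect_degree_feature_pairs(net: FeatureNetwork, model: DynamicsModel,
                                 reps: int, seed: int,
                                 normalize: bool = True):
    """Pool (k_i, F_i) pairs over independent dynamics realizations.

    Returns (degrees, features) arrays of length n*reps; the degree vector
    is that of the actual graph.
    """
    deg = net.degrees
    ks, fs = [], []
    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))
        ss = integrate_to_steady_state(model, net, seed=rng)
        feats, _ = features_from_state(ss.x, normalize=normalize)
        ks.append(deg)
        fs.append(feats)
    return np.concatenate(ks), np.concatenate(fs)


def dynamics_percolation_experiment(net: FeatureNetwork, model: DynamicsModel,
                                    f0_grid, reps: int, seed: int,
                                    normalize: bool = True) -> EnsembleCurve:
    """Remove nodes with F >= F0 after each dynamics realization and
    measure the giant fraction; one integration serves the whole F0 grid."""
    if reps < 1:
        raise DomainError(f"reps={reps} must be >= 1")
    f0_grid = np.asarray(f0_grid, dtype=float)
    samples = np.empty((reps, f0_grid.size))
    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))
        ss = integrate_to_steady_state(model, net, seed=rng)
        feats, _ = features_from_state(ss.x, normalize=normalize)
        for j, f0 in enumerate(f0_grid):
            samples[rep, j] = giant_fraction_sim(net, feats < f0)
    se = samples.std(axis=0, ddof=1) / math.sqrt(reps) if reps > 1 \
        else np.zeros(f0_grid.size)
    return EnsembleCurve(param_name="F0", grid=f0_grid,
                         S_mean=samples.mean(axis=0), S_se=se,
                         n_reps=reps, seed=seed,
                         meta={"dynamics": model.kind, "normalize": normalize})


# ---------------------------------------------------------------------------
# graph constructors used by the dynamics experiments
# ---------------------------------------------------------------------------

def reshuffled_preferential_attachment(N: int, m: int, seed: int,
                                       swaps_per_edge: int = 10) -> FeatureNetwork:
    """Preferential-attachment graph randomised by degree-preserving
    double-edge swaps (enough to decorrelate: swaps_per_edge * E attempts)."""
    import networkx as nx

    g = nx.barabasi_albert_graph(N, m, seed=int(seed))
    edges = np.array(sorted(tuple(sorted(e)) for e in g.edges()), dtype=np.int64)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    edge_set = set(map(tuple, edges))
    E = edges.shape[0]
    for _ in range(swaps_per_edge * E):
        i, j = rng.integers(0, E, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            new1, new2 = (a, d), (c, b)
        else:
            new1, new2 = (a, c), (b, d)
        new1, new2 = tuple(sorted(new1)), tuple(sorted(new2))
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue
        if new1 in edge_set or new2 in edge_set or new1 == new2:
            continue
        edge_set.discard(tuple(edges[i]))
        edge_set.discard(tuple(edges[j]))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = new1
        edges[j] = new2
    return FeatureNetwork(n=N, edges=edges,
                          meta={"family": "reshuffled_pa", "m": m, "seed": seed})


def project_bipartite(pairs, side: str = "left") -> FeatureNetwork:
    """One-mode projection of a bipartite edge table.

    ``pairs`` is an iterable of (left_id, right_id); two nodes of the chosen
    side are connected iff they share at least one neighbour on the other
    side.  Node ids are relabelled to a dense 0-based range (sorted order);
    the mapping is stored in ``meta['labels']``.
    """
    if side not in ("left", "right"):
        raise DomainError(f"side must be 'left' or 'right', not {side!r}")
    col = 0 if side == "left" else 1
    pairs = [(p[col], p[1 - col]) for p in pairs]
    if not pairs:
        raise DomainError("empty bipartite table")
    labels = sorted({p[0] for p in pairs})
    index = {lab: i for i, lab in enumerate(labels)}
    by_other: dict = {}
    for node, other in pairs:
        by_other.setdefault(other, set()).add(index[node])
    edges = set()
    for members in by_other.values():
        members = sorted(members)
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                edges.add((u, v))
    edge_arr = np.array(sorted(edges), dtype=np.int64).reshape(-1, 2)
    edge_arr = _simplify(len(labels), edge_arr)
    return FeatureNetwork(n=len(labels), edges=edge_arr,
                          meta={"family": "bipartite_projection",
                                "side": side, "labels": labels})
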