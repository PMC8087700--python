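# featperc

Percolation on networks whose nodes carry non-topological **features**:
nodes are retained with a probability `phi(k, F)` that may depend jointly on
their degree `k` and feature value `F`, and the surviving giant component is
computed both **analytically** (generating-function message passing) and by
**Monte-Carlo simulation** (configuration-model ensembles).

The package covers:

- **Joint degree–feature laws** (`featperc.distributions`): an independent
  family (geometric degrees × Pareto features), positively and negatively
  correlated scale-free families with analytic conditional samplers, a
  conditional-Gaussian "approximate" family built from data, a
  discrete-feature mode, and custom laws from tables or callables.
- **Occupation rules** (`featperc.occupation`): uniform random removal,
  degree cuts, feature thresholds (Heaviside convention `theta(0)=1`:
  an upper threshold at `F0` removes `F >= F0`), and custom `phi(k,F)`.
- **Theory** (`featperc.percolation`, `featperc.closedforms`): `g0`/`g1`
  evaluators, the fixed-point solve for `u` and `S = g0(1) - g0(u)`,
  branching factors, closed-form and generic critical points, and
  parameter-sweep theory curves. Closed forms (geometric algebra, Riemann/
  Hurwitz zeta, Lerch transcendent) live alongside a generic truncated-sum
  route; the two are cross-checked in the test suite.
- **Simulation** (`featperc.simulation`): stub-matched configuration-model
  networks with per-node features drawn from `P(F|k)`, feature shuffling,
  stochastic occupation, giant components via sparse connected components,
  and seeded ensemble sweeps.
- **Spatial graphs** (`featperc.geometric`): random geometric graphs on the
  unit torus with nearest-neighbour-distance features, the synchronous
  proximity-removal rule, and the binomial closed-form theory.
- **Dynamics-generated features** (`featperc.dynamics`): SIS, mutualistic,
  birth–death and mass-action ODEs integrated to steady state (RK45 with a
  Newton polish; criterion `max|dx/dt| < 1e-10`); steady states become
  features for threshold percolation experiments.
- **Empirical joint fitting** (`featperc.jointfit`): per-degree conditional
  summaries, weighted least-squares fits of closed-form mean/spread/height
  families (including `exp(a/(b-k))` and `a/(k(b+k))`), and assembly into a
  normalized joint distribution usable by the theory solver.
- **Robustness analysis** (`featperc.analysis`): correlation-impact area
  `delta_area`, theory–simulation discrepancy `epsilon_discrepancy`,
  finite-size-scaling exponent fits, and theory-side order-parameter
  exponent estimation.

## Quick start (library)

```python
import numpy as np
import featperc as fp

dist = fp.make_independent(a=0.5, alpha=3.0)      # p_k=(1-a)a^k, Pareto(3)
rule = fp.OccupationRule.feature_upper_threshold(2.0)   # remove F >= 2

sol = fp.giant_fraction_theory(dist, rule)        # S, u, branching factor
net = fp.build_network(dist, N=100_000, seed=0)   # configuration model
mask = fp.occupy(net, rule, seed=1)
S_sim = fp.giant_fraction_sim(net, mask)

a_c = fp.critical_point_independent("a", alpha=3.0, F0=2.0)   # = 0.4
```

## Command line

The console script `featperc` exposes subcommands `theory`, `simulate`,
`rgg`, `dynamics`, `fit-joint`, `scaling`, `metrics`, `fixtures`. Options
can come from flags or a YAML/JSON `--config` file (flags win); every
output CSV/TSV starts with a `#`-prefixed JSON line recording the
configuration and seed.

```bash
# solid theory curve: S(a) for the independent family under F0 = 2
featperc theory --family independent --alpha 3 --rule feature-upper \
    --f0 2 --sweep a:0.3:0.7:41 --out theory.csv

# matching simulation markers
featperc simulate --family independent --alpha 3 --rule feature-upper \
    --f0 2 --sweep a:0.3:0.7:11 -N 3000 --reps 100 --seed 7 --out sim.csv

# discrepancy between the two curves
featperc metrics --kind epsilon --curve-a theory.csv --curve-b sim.csv

# random geometric graph sweep over the removal radius
featperc rgg -N 1000 -r 0.1 --sweep r0:0.005:0.075:15 --reps 100 \
    --theory-out rgg_theory.csv --sim-out rgg_sim.csv

# SIS features on a reshuffled preferential-attachment graph
featperc dynamics --model sis --pa 2000 3 --sweep F0:0.55:0.95:11 \
    --reps 100 --seed 0 --raw --out sis.csv --pairs-out pairs.tsv

# fit the conditional-Gaussian joint to the collected pairs
featperc fit-joint --pairs pairs.tsv --out fit.json
```

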