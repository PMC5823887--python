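# deltacle

Stochastic spatio-temporal modelling of biomolecular networks with
**δ-corrected chemical Langevin equations**.

Full stochastic reaction–diffusion simulation of even a small signalling
network is computationally expensive, yet ignoring spatial structure
(the well-mixed assumption) can change the predicted dynamics
qualitatively. `deltacle` implements a middle road for the five-reaction
ligand–receptor network

```
R + L ⇌ C   (k_on, k_off)      C → ∅ (k_e)      R → ∅ (k_t)
F(t) → L                       Q_R → R
```

Spatial heterogeneity is idealised as a partition of the reaction volume
into M well-mixed subvolumes and collapsed into a single scalar
correction term

```
δ = Σ_{i≠j} R_i L_j / (R L)  =  1 − Σ_i R_i L_i / (R L),    δ ∈ [0, 1],
```

which discounts only the bimolecular association propensity:
`k_on (1 − δ) R L`. δ = 0 is the well-mixed condition, δ = 1 complete
separation of receptors and ligands (no reaction). Mean/variance matching
of the reaction increments then yields a noisy Langevin system, e.g. for
the receptor count

```
dR = [−k_on(1−δ)RL − k_t R + k_off C + Q_R] dt
     + sqrt(k_on(1−δ)RL + k_t R + k_off C + Q_R) dw_R ,
```

integrated by first-order Euler–Maruyama with δ(t) supplied by a schedule
(constant, piecewise, uniformly resampled, or its own SDE). Because the
Langevin system is orders of magnitude cheaper than a reaction–diffusion
solver, δ(t) can be *estimated from data*: given complex-count
measurements C̃_k, each interval's δ_k solves the 1-D bounded minimisation
`min |C̃_k − C̄_k(δ)|` (golden-section/parabolic search with common random
numbers), or, cheaper still, δ is modelled as Uniform[u_lo, u_hi]
resampled every t_N and the bounds are fitted by grid search.

The package ships the epidermal growth factor receptor (EGFR) network of
the human mammary epithelial cell as its built-in parameter set
(k_off = 0.24/min, K_D = 2.47×10⁻⁹ M × N_av × V_cell, k_on = k_off/K_D,
k_t = 0.02/min, Q_R = 2×10⁵ k_t, k_e = 0.15/min) and four simulators:

| module | what it does |
| --- | --- |
| `deltacle.ode` | deterministic mean-field reference (LSODA) |
| `deltacle.gillespie` | exact well-mixed SSA (direct method, numba) |
| `deltacle.spatial` | compartment SSA on a ring: local reactions + nearest-neighbour hops; records δ(t) exactly from occupancies |
| `deltacle.langevin` | Euler–Maruyama integration of the δ-corrected Langevin system |
| `deltacle.estimate` | per-interval δ estimation and uniform-bounds fitting |

## Worked example

Simulate the ligand-impulse experiment (200,000 resting receptors, an
impulse of 10,000 ligands) with 99% of the receptors crowded onto one
half of the cell surface, then recover δ(t) from the surrogate
measurements:

```python
import numpy as np
from deltacle import (egfr_parameters, WellMixedState, simulate_ode,
                      build_ring_layout, spatial_ensemble,
                      sample_measurements, estimate_delta_sequence)

rates = egfr_parameters()
init = WellMixedState(t=0.0, R=200_000, C=0, L=10_000)

ode = simulate_ode(rates, init, t_end=60.0)                    # well-mixed reference
layout = build_ring_layout(M=16, hop_rate=0.1, hot_fraction=0.99, hot_size=8)
runs = spatial_ensemble(rates, layout, init, t_end=60.0, n=10, seed=1)
meas = sample_measurements(runs, interval=2.0)                  # surrogate wet-lab data
est = estimate_delta_sequence(meas, rates, init, n_ens=100, seed=2)

print(f"ODE complex count at t=10/30/60 min: "
      f"{ode.state_at(10).C:.0f} / {ode.state_at(30).C:.0f} / {ode.state_at(60).C:.0f}")
print(f"spatial complex count (10-run mean): "
      f"{np.mean([r.trajectory.state_at(10).C for r in runs]):.0f} / "
      f"{np.mean([r.trajectory.state_at(30).C for r in runs]):.0f} / "
      f"{np.mean([r.trajectory.state_at(60).C for r in runs]):.0f}")
d = est.deltas
print(f"estimated delta, mean over t in (0,10]: {d[:5].mean():.3f}; "
      f"(10,20]: {d[5:10].mean():.3f}; (50,60]: {d[-5:].mean():.3f}")
```

prints

```
ODE complex count at t=10/30/60 min: 1439 / 848 / 380
spatial complex count (10-run mean): 1270 / 834 / 416
estimated delta, mean over t in (0,10]: 0.129; (10,20]: 0.158; (50,60]: 0.064
```

Receptor crowding suppresses early complex formation by ~12% relative to
the well-mixed prediction; the estimated δ(t) captures exactly that
shortfall — heterogeneity builds up while ligand is locally depleted
around the receptor-rich half and diminishes as diffusion and receptor
turnover homogenise the system. A Langevin run driven by the estimated
piecewise δ reproduces the spatial trajectories at a tiny fraction of the
cost of the compartment simulation.

The same workflows are scriptable from the shell via the `deltacle` CLI
(`simulate-ode`, `simulate-ssa`, `simulate-spatial`, `simulate-langevin`,
`estimate-delta`, `fit-bounds`, `make-fixtures`); see `deltacle --help`.

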