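# Methods

## Model

The package models a five-reaction ligand–receptor network with copy
numbers R (free receptor), L (free ligand) and C (bound complex):
association/dissociation `R + L ⇌ C` (rates k_on, k_off), complex
internalisation `C → ∅` (k_e), receptor internalisation `R → ∅` (k_t),
receptor generation at rate Q_R and an external ligand source F(t).
All rates are per minute and all times are minutes internally; step sizes
conventionally quoted in seconds (the 1 s integration step, the 10 s
resampling period) are converted at the interface as s/60 min, so the
printed rate constants are used unchanged.

The built-in parameter set is the EGFR network of the human mammary
epithelial cell: k_off = 0.24/min, K_D = 2.47×10⁻⁹ M expressed in
molecules via Avogadro's number (6.023×10²³) and the cell volume
4×10⁻¹⁰ L (K_D = 5.95072×10⁵ molecules), k_on = k_off/K_D =
4.0331×10⁻⁷ /(molecule·min), k_t = 0.02/min, Q_R = 2×10⁵ k_t =
4000 molecules/min, k_e = 0.15/min, F ≡ 0. The benchmark experiment is a
ligand impulse: L(0) = 10,000 against the resting receptor pool
R(0) = Q_R/k_t = 200,000, C(0) = 0.

## The spatial correction term

Spatial heterogeneity is idealised as a partition of the reaction volume
into M virtual subvolumes inside which the well-mixed assumption holds.
Writing R_i, L_i for subvolume occupancies, the fraction of
receptor–ligand pairs that do *not* share a subvolume is

    δ = Σ_{i≠j} R_i L_j / (R L) = 1 − Σ_i R_i L_i / (R L) ∈ [0, 1].

The implementation uses the compact right-hand form (O(M) instead of
O(M²)); the test suite checks it against the explicit pairwise sum to
10⁻¹² relative error. Only reactions involving two or more molecules are
affected by spatial structure, so δ discounts the association propensity
alone: `k_on (1 − δ) R L`. Unimolecular propensities are unchanged.

δ is undefined when R L = 0 (`compute_delta` raises); the simulators
never need it there because the association propensity already vanishes,
and recorded δ series contain NaN at such instants.

## Noisy Langevin equations

Matching the mean and variance of the one-step reaction increments gives
a chemical Langevin equation per species: drift equal to the net
propensity balance, noise amplitude equal to the square root of the sum
of the propensities affecting that species, with independent Brownian
increments dw ~ Normal(0, dt) (standard deviation √dt). The √dt
convention is the one required by the variance-matching derivation
(increment variance proportional to dt) and is verified by a
frozen-state Monte-Carlo moment test (10⁵ one-step increments of R,
agreement within 3 standard errors).

Integration is explicit first-order Euler–Maruyama with default step
dt = 1 s. Counts and square-root arguments are clamped at zero after
each step (not reflected or rejected): negative excursions are rare at
the ≥10³–10⁵ copy numbers this model targets, and clamping keeps the
one-step map simple and monotone. Per-realisation RNG streams are
`default_rng(seed + i)`, and each realisation consumes its randomness in
a fixed order (δ-path randomness first, then the species increments), so
a single run and the corresponding ensemble member are bit-identical.

δ(t) is supplied by a schedule: constant; piecewise-constant on
(t_{k−1}, t_k]; uniformly resampled on [u_lo, u_hi] every t_N (default
10 s, validated to be ≥ dt — spatial rearrangement is not faster than
the chemistry); or an SDE dδ = a_δ dt + b_δ dw_δ reflected into [0, 1]
(initial value δ₀, default 0.5, exposed because the underlying
formulation leaves it free).

## Simulators

**ODE.** LSODA with rtol 10⁻⁸ / atol 10⁻⁶ (the system is mildly stiff at
high copy number); output clamped at zero. Halving the tolerances
changes trajectories by < 10⁻⁶ relative.

**Well-mixed SSA.** Gillespie's direct method over the six channels
(numba event loop). Output is the piecewise-constant state sampled on a
regular grid (default 0.1 min) so ensembles align for averaging; the raw
event sequence is available separately.

**Compartment SSA.** A ring of M subvolumes (default 16) with local
reactions and nearest-neighbour hops at `hop_rate` per molecule per
neighbour, identical for all species. Sources deposit into a uniformly
random subvolume. The local association propensity is
`k_on·M·R_i·L_i` — the standard mesoscopic (reaction–diffusion master
equation) volume scaling for a subvolume of size V/M. This choice makes
the surrogate consistent in both limits: with fast hopping the totals
reproduce the well-mixed SSA exactly in distribution, while the recorded
occupancy correction fluctuates around its equal-partition value
1 − 1/M. Alongside δ the simulator records the *effective mixing
deficit* 1 − M·Σ R_iL_i/(RL), the factor by which the total association
flux falls short of well-mixed mass action; the two are strictly
monotone transforms of each other, so rank-based comparisons are
identical for both. A ring is used rather than a meshed surface because
δ depends only on occupancies, not on the embedding; it is the simplest
connected geometry that realises a "99% of receptors on one half of the
surface" scenario.

Defaults: M = 16, hot region = M/2 contiguous compartments holding 99%
of the receptors in the heterogeneous scenario, ligands uniform,
hop_rate = 0.1/min. The hop rate is a free surrogate parameter (no
diffusion coefficients are prescribed by the underlying model); 0.1/min
was chosen from a mean-field analysis of the ring so that the scenario
exhibits the intended phenomenology: local ligand depletion around the
receptor-rich half builds a mixing deficit of ~0.16 on a ~10 min
timescale, and receptor hopping plus receptor turnover (1/k_t = 50 min)
homogenise the system over the hour, so heterogeneity is pronounced
early and slowly diminishes. At 1/min the profile relaxes within ~5 min
and the deficit never exceeds ~0.05, i.e. the scenario would be
essentially well-mixed.

## δ estimation

**Sequential per-interval minimisation.** For each measurement interval
(t_{k−1}, t_k], the estimator searches δ_k ∈ [0, 1] minimising
|C̃_k − C̄_k(δ_k)|, where C̄_k is the mean complex count of n_ens
(default 100) Langevin continuations from the ensemble's own states at
t_{k−1} under constant δ_k. The scalar search is SciPy's bounded
golden-section/parabolic-interpolation minimiser with tolerance 10⁻³ on
δ. The interval's Brownian increments are drawn once and reused for
every candidate δ (common random numbers), which makes the objective a
deterministic and effectively smooth function of δ — the property a
bracketing scalar search needs. After the minimisation the interval is
committed with the optimal δ and the same increments; each realisation
continues from its own endpoint (the ensemble is never reset to the
measurement). n_ens = 100 gives recovery of known constant δ* to ~0.005
mean absolute error at EGFR copy numbers. Residuals above a configurable
threshold are reported as diagnostics, never raised.

**Uniform-bounds fit.** The alternative estimator models δ as
Uniform[u_lo, u_hi] resampled every t_N and scans all grid pairs
0 ≤ u_lo ≤ u_hi ≤ 1 (default step 0.1, 66 pairs), minimising the summed
absolute misfit Σ_k |C̃_k − C̄_k|; ties are broken by the smaller width,
then the smaller u_lo. The same base variates (uniforms and Gaussians)
are shared across pairs, drawn exactly as the ensemble simulator draws
them, so the objective is deterministic and a pair evaluated with the
seed and ensemble size that generated the data reproduces it exactly.

An identifiability caveat: because the Langevin drift is linear in δ,
the ensemble-mean complex count depends on the bounds almost entirely
through their midpoint; the width enters only at second order (relative
effect ~10⁻⁴ at these parameters, far below Monte-Carlo resolution of
the mean). The width is therefore validated as a seed-matched
self-consistency round trip — data generated under (0.3, 0.7) are refit
with the generator's common random numbers, where the true pair attains
objective zero — not as an externally identifiable quantity. Recovering
the width from independent data would require matching trajectory
*variability*, not just means, which is outside this estimator's design.

## Synthetic data and what passing tests show

All measurement data are generated internally: surrogate "wet-lab"
points are ensemble means of the compartment SSA (heterogeneous
scenarios) or of the Langevin model itself (constant-δ* and
uniform-bounds recovery benchmarks). The surrogate captures discrete
stochastic kinetics, spatial occupancy imbalance and diffusive
relaxation, but not continuum geometry (a ring, not a 3-D meshed cell),
not species-specific diffusivities, and not measurement error beyond
finite-ensemble averaging. Recovery results on these data therefore
demonstrate internal consistency of the estimation machinery at
realistic copy numbers, not performance against real microscopy data.

## Benchmark problem sizes

The shipped benchmarks use: 10 SSA realisations and a 100-run δ ≡ 0
Langevin ensemble against the ODE over 60 min (checked at t = 10, 30,
60 min, 2% tolerance on L and C); δ* recovery over δ* ∈ {0.1,…,0.9}
with 10 one-minute intervals and n_ens = 100; bounds fitting on a
10-minute series; and a spatial round trip with 10 ring realisations
over 60 min, measurements every 2 min, Spearman rank correlation > 0.8
between estimated and recorded δ series plus a first-fifth vs last-fifth
decay check. At the t = 60 min checkpoint the complex count is ≈380, so
a 10-run mean has ≈1.5% standard error and the 2% agreement check sits
near the edge of Monte-Carlo resolution; the Langevin check (100 runs)
is comfortably inside it.

## Known limitations

- The network layer is table-driven but ships only this five-reaction
  system; arbitrary networks are out of scope.
- The compartment simulator supports the ring topology only; δ itself is
  defined for any partition.
- The event-driven simulators require a constant ligand source; the ODE
  and Langevin integrators accept any F(t) ≥ 0.
- Sequential δ estimates at late times (small remaining ligand, weak
  sensitivity of C̄ to δ) carry noise of a few times 10⁻² and alternate
  around the true level; interval length trades bias against this noise.
- No joint estimation of kinetic rates with δ, and no identification of
  the SDE coefficients (a_δ, b_δ) beyond exposing them as configuration.
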