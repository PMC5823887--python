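"""Exact well-mixed stochastic simulation (Gillespie's direct method)."""

from __future__ import annotations

import numpy as np

from ._kernels import wellmixed_core, wellmixed_events
from .model import RateConstants, WellMixedState
from .ode import Trajectory

__all__ = ["simulate_gillespie", "gillespie_event_sequence", "gillespie_ensemble_mean"]


def _check_init(init: WellMixedState) -> tuple[int, int, int]:
    counts = (init.R, init.C, init.L)
    if any(c != int(c) or c < 0 for c in counts):
        raise ValueError("SSA initial counts must be nonnegative integers")
    return tuple(int(c) for c in counts)


def simulate_gillespie(
    rates: RateConstants,
    init: WellMixedState,
    t_end: float,
    seed: int,
    dt_out: float = 0.1,
) -> Trajectory:
    """One exact realisation, sampled piecewise-constant onto a regular grid.

    Waiting times are exponential with rate equal to the total propensity
    (well-mixed, delta = 0); channels fire with probability proportional to
    their propensity.  If every propensity vanishes the simulation halts
    cleanly and the final state is held for the rest of the grid.
    Reproducible: the same seed yields the identical event sequence.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    R, C, L = _check_init(init)
    F0 = rates.constant_ligand_source()
    n = int(round(t_end / dt_out))
    grid = init.t + np.linspace(0.0, n * dt_out, n + 1)
    out = wellmixed_core(
        seed, R, C, L, rates.k_on, rates.k_off, rates.k_e, rates.k_t,
        rates.Q_R, F0, init.t, init.t + t_end, grid,
    )
    return Trajectory(grid, out[:, 0], out[:, 1], out[:, 2])


def gillespie_event_sequence(
    rates: RateConstants,
    init: WellMixedState,
    t_end: float,
    seed: int,
    max_events: int = 1_000_000,
):
    """Raw event list: (event times, states after each event as (R, C, L) rows)."""
    R, C, L = _check_init(init)
    F0 = rates.constant_ligand_source()
    times, states, n = wellmixed_events(
        seed, R, C, L, rates.k_on, rates.k_off, rates.k_e, rates.k_t,
        rates.Q_R, F0, init.t, init.t + t_end, max_events,
    )
    return times[:n], states[:n]


def gillespie_ensemble_mean(
    rates: RateConstants,
    init: WellMixedState,
    t_end: float,
    n: int,
    seed: int,
    dt_out: float = 0.1,
) -> tuple[Trajectory, list[Trajectory]]:
    """Mean of ``n`` independent realisations (seeded seed, seed+1, ...).

    Returns the pointwise ensemble-mean trajectory and the realisations.
    """
    if n < 1:
        raise ValueError("need n >= 1 realisations")
    runs = [simulate_gillespie(rates, init, t_end, seed + i, dt_out) for i in range(n)]
    mean = Trajectory(
        runs[0].t,
        np.mean([r.R for r in runs], axis=0),
        np.mean([r.C for r in runs], axis=0),
        np.mean([r.L for r in runs], axis=0),
    )
    return mean, runs
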