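"""Euler--Maruyama integration of the delta-corrected noisy Langevin system.

Each species is updated by drift*dt plus the square root of the sum of its
propensities times an independent Brownian increment:

    dR = [-k_on(1-d)RL - k_t R + k_off C + Q_R] dt
         + sqrt(k_on(1-d)RL + k_t R + k_off C + Q_R) dw_R
    dC = [ k_on(1-d)RL - k_off C - k_e C] dt
         + sqrt(k_on(1-d)RL + k_off C + k_e C) dw_C
    dL = [-k_on(1-d)RL + k_off C + F(t)] dt
         + sqrt(k_on(1-d)RL + k_off C + F(t)) dw_L

with d = delta(t) supplied by a :class:`~deltacle.model.DeltaSchedule`.
Brownian increments are Normal(0, dt) (standard deviation sqrt(dt)), the
scaling required by the mean/variance matching that derives the equation.
Counts and square-root arguments are clamped at zero; negative excursions
are rare at the copy numbers this model targets.

Draw order per realisation is fixed (delta-path randomness first, then the
species increments) so that a single run and the corresponding ensemble
member are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import DeltaSchedule, RateConstants, WellMixedState
from .ode import Trajectory

__all__ = [
    "NoiseIncrements",
    "step_langevin",
    "simulate_langevin",
    "ensemble_mean",
    "DT_DEFAULT",
]

#: Default integration step: 1 second, in minutes.
DT_DEFAULT = 1.0 / 60.0


@dataclass(frozen=True)
class NoiseIncrements:
    """Independent Gaussian increments for one step (mean 0, sd sqrt(dt))."""

    dw_R: float
    dw_C: float
    dw_L: float
    dw_delta: float = 0.0

    @classmethod
    def draw(cls, rng: np.random.Generator, dt: float) -> "NoiseIncrements":
        s = math.sqrt(dt)
        v = rng.normal(0.0, s, 4)
        return cls(*v)


def _drift_and_scale(x: np.ndarray, rates: RateConstants, delta, t: float):
    """Vectorised drift and noise amplitudes for states x of shape (n, 3)."""
    R, C, L = x[:, 0], x[:, 1], x[:, 2]
    a_on = rates.k_on * (1.0 - delta) * R * L
    a_off = rates.k_off * C
    a_e = rates.k_e * C
    a_t = rates.k_t * R
    f = rates.F(t)
    drift = np.stack(
        [
            -a_on - a_t + a_off + rates.Q_R,
            a_on - a_off - a_e,
            -a_on + a_off + f,
        ],
        axis=1,
    )
    scale = np.sqrt(
        np.clip(
            np.stack([a_on + a_t + a_off + rates.Q_R, a_on + a_off + a_e, a_on + a_off + f], axis=1),
            0.0,
            None,
        )
    )
    return drift, scale


def step_langevin(
    state: WellMixedState,
    rates: RateConstants,
    delta: float,
    dt: float,
    noise: NoiseIncrements,
) -> WellMixedState:
    """One explicit first-order Euler step of the noisy Langevin system."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.array([[state.R, state.C, state.L]], dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("state must be finite")
    drift, scale = _drift_and_scale(x, rates, delta, state.t)
    dw = np.array([[noise.dw_R, noise.dw_C, noise.dw_L]])
    y = np.clip(x + drift * dt + scale * dw, 0.0, None)[0]
    return WellMixedState(state.t + dt, y[0], y[1], y[2])


# ----------------------------------------------------------------------
def _delta_path(
    schedule: DeltaSchedule, t0: float, n_steps: int, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-step delta values; element j applies to the step t0+j*dt -> t0+(j+1)*dt."""
    if schedule.mode == "constant":
        return np.full(n_steps, schedule.value)
    if schedule.mode == "piecewise":
        bp, vals = schedule.breakpoints, schedule.values
        t_end = t0 + n_steps * dt
        if bp[0] > t0 + 1e-12 or bp[-1] < t_end - 1e-9:
            raise ValueError("piecewise schedule does not cover the simulation span")
        t_right = t0 + dt * np.arange(1, n_steps + 1)
        k = np.clip(np.searchsorted(bp, t_right - 1e-12, side="left") - 1, 0, vals.size - 1)
        return vals[k]
    if schedule.mode == "uniform_process":
        if schedule.t_N < dt - 1e-12:
            raise ValueError("t_N must be >= dt: spatial fluctuations are not faster than reactions")
        per = max(1, int(round(schedule.t_N / dt)))
        n_seg = -(-n_steps // per)
        u = rng.random(n_seg)
        seg = schedule.u_lo + (schedule.u_hi - schedule.u_lo) * u
        return np.repeat(seg, per)[:n_steps]
    if schedule.mode == "sde":
        dw = rng.normal(0.0, math.sqrt(dt), n_steps)
        path = np.empty(n_steps)
        d = schedule.delta0
        for j in range(n_steps):
            d = d + schedule.a_delta * dt + schedule.b_delta * dw[j]
            # reflect into [0, 1]
            d = d % 2.0
            if d > 1.0:
                d = 2.0 - d
            path[j] = d
        return path
    raise ValueError(f"unknown schedule mode {schedule.mode!r}")


def _realisation_draws(schedule, t0, n_steps, dt, seed):
    """Canonical per-realisation randomness: delta path first, then increments."""
    rng = np.random.default_rng(seed)
    path = _delta_path(schedule, t0, n_steps, dt, rng)
    noise = rng.normal(0.0, math.sqrt(dt), (n_steps, 3))
    return path, noise


def _advance_recorded(x, rates, paths, noise, t0, dt, record_every):
    """Advance states x (n, 3) for n_steps and record every ``record_every`` steps.

    Returns (times, recorded states (n_rec, n, 3), recorded delta (n_rec, n)).
    """
    n_steps = noise.shape[1]
    n_rec = n_steps // record_every + 1
    rec = np.empty((n_rec, x.shape[0], 3))
    rec_d = np.empty((n_rec, x.shape[0]))
    rec[0] = x
    rec_d[0] = paths[:, 0]
    r = 1
    for j in range(n_steps):
        drift, scale = _drift_and_scale(x, rates, paths[:, j], t0 + j * dt)
        x = np.clip(x + drift * dt + scale * noise[:, j, :], 0.0, None)
        if (j + 1) % record_every == 0:
            rec[r] = x
            rec_d[r] = paths[:, j]
            r += 1
    times = t0 + dt * record_every * np.arange(n_rec)
    return times, rec[:r], rec_d[:r]


def _steps_for(t_end: float, dt: float, dt_out: float) -> tuple[int, int]:
    n_steps = max(1, int(round(t_end / dt)))
    record_every = max(1, int(round(dt_out / dt)))
    if n_steps % record_every:
        raise ValueError("t_end must be a whole number of output intervals")
    return n_steps, record_every


def simulate_langevin(
    rates: RateConstants,
    init: WellMixedState,
    schedule: DeltaSchedule,
    t_end: float,
    dt: float = DT_DEFAULT,
    seed: int = 0,
    dt_out: float = 0.1,
) -> Trajectory:
    """One Euler--Maruyama realisation driven by the delta schedule.

    The applied delta is stored alongside the counts (at each recorded time,
    the value in force during the step ending there).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    n_steps, record_every = _steps_for(t_end, dt, dt_out)
    path, noise = _realisation_draws(schedule, init.t, n_steps, dt, seed)
    x0 = np.array([[init.R, init.C, init.L]], dtype=float)
    times, rec, rec_d = _advance_recorded(
        x0, rates, path[None, :], noise[None, :, :], init.t, dt, record_every
    )
    return Trajectory(times, rec[:, 0, 0], rec[:, 0, 1], rec[:, 0, 2], rec_d[:, 0])


def ensemble_mean(
    rates: RateConstants,
    init: WellMixedState,
    schedule: DeltaSchedule,
    t_end: float,
    dt: float = DT_DEFAULT,
    n: int = 100,
    seed: int = 0,
    dt_out: float = 0.1,
) -> Trajectory:
    """Pointwise mean of ``n`` independent realisations (seeds seed..seed+n-1)."""
    if n < 1:
        raise ValueError("need n >= 1 realisations")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    n_steps, record_every = _steps_for(t_end, dt, dt_out)
    paths = np.empty((n, n_steps))
    noise = np.empty((n, n_steps, 3))
    for i in range(n):
        paths[i], noise[i] = _realisation_draws(schedule, init.t, n_steps, dt, seed + i)
    x0 = np.tile(np.array([init.R, init.C, init.L], dtype=float), (n, 1))
    times, rec, rec_d = _advance_recorded(x0, rates, paths, noise, init.t, dt, record_every)
    return Trajectory(
        times, rec.mean(axis=1)[:, 0], rec.mean(axis=1)[:, 1], rec.mean(axis=1)[:, 2],
        rec_d.mean(axis=1),
    )
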