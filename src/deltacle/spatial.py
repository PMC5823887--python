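"""Compartment-based stochastic reaction-diffusion surrogate.

The cell surface is discretised into M well-mixed subvolumes on a ring;
the five network reactions fire locally (association with the
reaction-diffusion-master-equation rate ``k_on * M * R_i * L_i``, so that
fast diffusion recovers the well-mixed dynamics for the totals), sources
deposit into a uniformly random subvolume, and molecules hop to a
nearest neighbour at ``hop_rate`` per molecule per neighbour.

This is a deliberately simple surrogate for a full 3-D mesoscopic
reaction-diffusion solver: the spatial correction term depends only on
subvolume occupancies, not on the embedding geometry, so a ring is the
simplest connected layout that realises scenarios such as "99% of the
receptors on one half of the surface".  Alongside the exact occupancy
correction delta = 1 - S/(R L) (S = sum_i R_i L_i), the simulator records
the *effective mixing deficit* 1 - M S/(R L): the factor by which the total
association flux falls short of the well-mixed mass-action flux.  The two
are strictly monotone transforms of one another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import spatial_core
from .model import MeasurementSeries, RateConstants, SpatialState, WellMixedState
from .ode import Trajectory

__all__ = [
    "CompartmentLayout",
    "build_ring_layout",
    "initial_spatial_state",
    "simulate_spatial_ssa",
    "sample_measurements",
    "SpatialResult",
]


@dataclass(frozen=True)
class CompartmentLayout:
    """Ring of M subvolumes with a contiguous 'hot' receptor region.

    ``hot_fraction`` of the receptors are placed (as evenly as possible) in
    ``hot_size`` contiguous compartments, the remainder spread over the rest;
    ligands and complexes are spread uniformly.  ``hop_rate`` is the
    per-molecule jump rate to one neighbour [1/min], identical for all
    species.
    """

    M: int
    hop_rate: float = 0.1
    hot_fraction: float = 0.5
    hot_size: int | None = None

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("need at least M = 2 subvolumes")
        if self.hop_rate < 0:
            raise ValueError("hop_rate must be >= 0")
        if not 0.0 <= self.hot_fraction <= 1.0:
            raise ValueError("hot_fraction must lie in [0, 1]")
        hs = self.hot_size if self.hot_size is not None else self.M // 2
        if not 1 <= hs < self.M:
            raise ValueError("need 1 <= hot_size < M")
        object.__setattr__(self, "hot_size", hs)

    def adjacency(self) -> list[tuple[int, int]]:
        """Symmetric nearest-neighbour edges of the ring."""
        return [(i, (i + 1) % self.M) for i in range(self.M)]


def build_ring_layout(
    M: int,
    hop_rate: float = 0.1,
    hot_fraction: float = 0.5,
    hot_size: int | None = None,
) -> CompartmentLayout:
    """Ring lattice of M compartments with a contiguous receptor-rich region."""
    return CompartmentLayout(M=M, hop_rate=hop_rate, hot_fraction=hot_fraction, hot_size=hot_size)


def _spread(total: int, n: int) -> np.ndarray:
    """Distribute ``total`` molecules over ``n`` bins as evenly as possible."""
    base, rem = divmod(int(total), n)
    out = np.full(n, base, dtype=np.int64)
    out[:rem] += 1
    return out


def initial_spatial_state(layout: CompartmentLayout, totals: WellMixedState) -> SpatialState:
    """Place totals on the ring: receptors split hot/cold, ligands/complexes uniform."""
    for c in (totals.R, totals.C, totals.L):
        if c != int(c) or c < 0:
            raise ValueError("spatial totals must be nonnegative integers")
    M, hs = layout.M, layout.hot_size
    n_hot = int(round(layout.hot_fraction * totals.R))
    R = np.zeros(M, dtype=np.int64)
    R[:hs] = _spread(n_hot, hs)
    if hs < M:
        R[hs:] = _spread(int(totals.R) - n_hot, M - hs)
    L = _spread(int(totals.L), M)
    C = _spread(int(totals.C), M)
    return SpatialState(totals.t, R, L, C)


@dataclass
class SpatialResult:
    """Gridded totals plus the recorded spatial correction series."""

    trajectory: Trajectory          # totals with delta = exact occupancy correction
    mixing_deficit: np.ndarray      # 1 - M*S/(R*L): shortfall of the association flux
    final_state: SpatialState

    def to_frame(self) -> pd.DataFrame:
        df = self.trajectory.to_frame()
        df = df.rename(columns={"R": "R_total", "C": "C_total", "L": "L_total"})
        df["mixing_deficit"] = self.mixing_deficit
        return df


def simulate_spatial_ssa(
    rates: RateConstants,
    layout: CompartmentLayout,
    totals: WellMixedState,
    t_end: float,
    seed: int,
    dt_out: float = 0.5,
    initial_state: SpatialState | None = None,
) -> SpatialResult:
    """One exact realisation of the compartment SSA.

    Hops conserve totals; only reaction channels change them.  The spatial
    correction is recorded pointwise from the instantaneous occupancies at
    every grid time (NaN whenever one species is absent, where it is
    undefined).  ``initial_state`` overrides the layout's default placement
    (its totals must match ``totals``).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if initial_state is not None:
        if initial_state.M != layout.M:
            raise ValueError("initial_state must have the layout's number of subvolumes")
        tot = initial_state.totals()
        if (tot.R, tot.C, tot.L) != (totals.R, totals.C, totals.L):
            raise ValueError("initial_state totals must match the requested totals")
        state = initial_state
    else:
        state = initial_spatial_state(layout, totals)
    F0 = rates.constant_ligand_source()
    M = layout.M
    n = int(round(t_end / dt_out))
    grid = totals.t + np.linspace(0.0, n * dt_out, n + 1)
    R, L, C = state.R.copy(), state.L.copy(), state.C.copy()
    out = spatial_core(
        seed, R, L, C, rates.k_on * M, rates.k_off, rates.k_e, rates.k_t,
        rates.Q_R, F0, layout.hop_rate, totals.t, totals.t + t_end, grid,
    )
    TR = out[:, 0].astype(float)
    TC = out[:, 1].astype(float)
    TL = out[:, 2].astype(float)
    S = out[:, 3].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rl = TR * TL
        frac = np.where(rl > 0, S / rl, np.nan)
    delta = np.clip(1.0 - frac, 0.0, 1.0)
    deficit = np.clip(1.0 - M * frac, 0.0, 1.0)
    traj = Trajectory(grid, TR, TC, TL, delta)
    final = SpatialState(grid[-1], R, L, C)
    return SpatialResult(traj, deficit, final)


def spatial_ensemble(
    rates: RateConstants,
    layout: CompartmentLayout,
    totals: WellMixedState,
    t_end: float,
    n: int,
    seed: int,
    dt_out: float = 0.5,
) -> list[SpatialResult]:
    """``n`` independent realisations seeded seed, seed+1, ..."""
    if n < 1:
        raise ValueError("need n >= 1 realisations")
    return [simulate_spatial_ssa(rates, layout, totals, t_end, seed + i, dt_out) for i in range(n)]


def sample_measurements(results: list[SpatialResult] | list[Trajectory], interval: float) -> MeasurementSeries:
    """Surrogate wet-lab data: ensemble-mean complex counts every ``interval`` minutes.

    C~_k is the mean over the ensemble of the total complex count at
    t_k = t0 + k * interval, k = 1..N, with N set by the trajectory span.
    """
    if not results:
        raise ValueError("need at least one trajectory")
    if interval <= 0:
        raise ValueError("interval must be positive")
    trajs = [r.trajectory if isinstance(r, SpatialResult) else r for r in results]
    t = trajs[0].t
    for tr in trajs[1:]:
        if tr.t.shape != t.shape or not np.allclose(tr.t, t):
            raise ValueError("ensemble trajectories must share a common time grid")
    t0 = t[0]
    n_meas = int(np.floor((t[-1] - t0) / interval + 1e-9))
    if n_meas < 1:
        raise ValueError("trajectory span shorter than one measurement interval")
    times = t0 + interval * np.arange(1, n_meas + 1)
    idx = []
    for tk in times:
        i = int(np.argmin(np.abs(t - tk)))
        if abs(t[i] - tk) > 1e-6:
            raise ValueError("measurement times must lie on the trajectory grid")
        idx.append(i)
    mean_C = np.mean([tr.C[idx] for tr in trajs], axis=0)
    return MeasurementSeries(times=times, values=mean_C, t0=t0)


def mean_delta_series(results: list[SpatialResult], at_times: np.ndarray | None = None):
    """Ensemble means of the recorded correction and mixing deficit.

    Returns (times, mean delta, mean mixing deficit), optionally restricted
    to the grid points closest to ``at_times``.
    """
    t = results[0].trajectory.t
    delta = np.nanmean([r.trajectory.delta for r in results], axis=0)
    deficit = np.nanmean([r.mixing_deficit for r in results], axis=0)
    if at_times is not None:
        idx = [int(np.argmin(np.abs(t - tk))) for tk in at_times]
        return t[idx], delta[idx], deficit[idx]
    return t, delta, deficit
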