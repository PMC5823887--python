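"""Compartment-based reaction-diffusion surrogate."""

import numpy as np
import pytest

from deltacle import (
    RateConstants,
    SpatialState,
    WellMixedState,
    build_ring_layout,
    sample_measurements,
    simulate_spatial_ssa,
    spatial_ensemble,
)
from deltacle.gillespie import gillespie_ensemble_mean
from deltacle.ode import Trajectory
from deltacle.spatial import initial_spatial_state, mean_delta_series


class TestLayout:
    def test_hot_cold_receptor_split(self):
        layout = build_ring_layout(16, hot_fraction=0.99, hot_size=8)
        s = initial_spatial_state(layout, WellMixedState(0.0, 200_000, 0, 10_000))
        assert s.R[:8].sum() == 198_000
        assert s.R[8:].sum() == 2_000
        np.testing.assert_array_equal(s.L, 625)

    def test_equal_partition_initial_delta(self):
        from deltacle import compute_delta

        layout = build_ring_layout(4, hot_fraction=0.25, hot_size=1)
        s = initial_spatial_state(layout, WellMixedState(0.0, 400, 0, 400))
        assert compute_delta(s) == pytest.approx(0.75)

    def test_adjacency_is_symmetric_connected_ring(self):
        layout = build_ring_layout(6)
        edges = layout.adjacency()
        assert len(edges) == 6
        degree = np.zeros(6, int)
        for a, b in edges:
            degree[a] += 1
            degree[b] += 1
        assert np.all(degree == 2)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_ring_layout(1)
        with pytest.raises(ValueError):
            build_ring_layout(4, hot_size=4)
        with pytest.raises(ValueError):
            build_ring_layout(4, hot_fraction=1.5)


class TestSpatialSSA:
    def test_hops_conserve_totals(self):
        # diffusion only: every total is invariant, only the spread changes
        k = RateConstants(0, 0, 0, 0, 0)
        layout = build_ring_layout(8, hop_rate=5.0, hot_fraction=1.0, hot_size=2)
        res = simulate_spatial_ssa(k, layout, WellMixedState(0.0, 300, 40, 200), 10.0, seed=5)
        np.testing.assert_array_equal(res.trajectory.R, 300)
        np.testing.assert_array_equal(res.trajectory.C, 40)
        np.testing.assert_array_equal(res.trajectory.L, 200)
        d = res.trajectory.delta
        assert np.all((d >= 0) & (d <= 1))

    def test_complete_separation_never_reacts(self, egfr):
        # receptors and ligands in disjoint static compartments: no association
        k = RateConstants(egfr.k_on * 1e3, 0, 0, 0, 0)
        layout = build_ring_layout(2, hop_rate=0.0)
        init = SpatialState(0.0, R=[500, 0], L=[0, 500], C=[0, 0])
        res = simulate_spatial_ssa(
            k, layout, WellMixedState(0.0, 500, 0, 500), 30.0, seed=9, initial_state=init
        )
        np.testing.assert_array_equal(res.trajectory.C, 0)
        np.testing.assert_array_equal(res.trajectory.delta, 1.0)

    def test_fast_hopping_recovers_wellmixed_dynamics(self):
        # large hop rate: totals behave like the exact well-mixed SSA and the
        # occupancy correction hovers at the equal-partition value 1 - 1/M
        k = RateConstants(2e-4, 0.3, 0.1, 0.0, 0.0)
        M = 4
        layout = build_ring_layout(M, hop_rate=50.0, hot_fraction=1.0, hot_size=1)
        totals = WellMixedState(0.0, 400, 0, 200)
        n = 30
        res = spatial_ensemble(k, layout, totals, 5.0, n=n, seed=21, dt_out=0.5)
        mean_C = np.mean([r.trajectory.C for r in res], axis=0)
        ssa_mean, _ = gillespie_ensemble_mean(k, totals, 5.0, n=n, seed=121, dt_out=0.5)
        sd = np.std([r.trajectory.C for r in res], axis=0, ddof=1)
        tol = 4 * np.sqrt(2.0) * sd[1:] / np.sqrt(n) + 1.0
        assert np.all(np.abs(mean_C[1:] - ssa_mean.C[1:]) < tol)
        _, d, _ = mean_delta_series(res)
        assert abs(np.nanmean(d[1:]) - (1 - 1 / M)) < 0.01

    def test_frozen_compartment_matches_wellmixed_ssa(self):
        # hop_rate = 0 with everything in one subvolume is the well-mixed SSA
        # for that subvolume; local bimolecular rate is k_on * M, so compare
        # against the exact SSA run at the same per-volume rate.
        M = 4
        kon = 1e-4
        k_spatial = RateConstants(kon / M, 0.25, 0.1, 0.05, 0.0)
        k_mixed = RateConstants(kon, 0.25, 0.1, 0.05, 0.0)
        layout = build_ring_layout(M, hop_rate=0.0)
        init = SpatialState(0.0, R=[500, 0, 0, 0], L=[300, 0, 0, 0], C=[0, 0, 0, 0])
        totals = WellMixedState(0.0, 500, 0, 300)
        n = 40
        runs = [
            simulate_spatial_ssa(k_spatial, layout, totals, 10.0, seed=400 + i,
                                 dt_out=1.0, initial_state=init)
            for i in range(n)
        ]
        mean_C = np.mean([r.trajectory.C for r in runs], axis=0)
        ssa_mean, ssa_runs = gillespie_ensemble_mean(k_mixed, totals, 10.0, n=n, seed=500, dt_out=1.0)
        sd = np.std([r.C for r in ssa_runs], axis=0, ddof=1)
        tol = 4 * np.sqrt(2.0) * sd[1:] / np.sqrt(n) + 1.0
        assert np.all(np.abs(mean_C[1:] - ssa_mean.C[1:]) < tol)

    def test_heterogeneous_scenario_deficit_rises_then_diminishes(self, egfr, impulse_init):
        layout = build_ring_layout(16, hop_rate=0.1, hot_fraction=0.99, hot_size=8)
        res = simulate_spatial_ssa(egfr, layout, impulse_init, 60.0, seed=2)
        d = res.trajectory.delta
        assert np.all((d[np.isfinite(d)] >= 0) & (d[np.isfinite(d)] <= 1))
        dm = res.mixing_deficit
        t = res.trajectory.t
        early = dm[(t >= 5) & (t <= 15)].mean()
        late = dm[t >= 50].mean()
        assert early > 0.1
        assert late < early / 2


class TestMeasurements:
    def _traj(self, C):
        t = np.arange(len(C), dtype=float)
        return Trajectory(t, np.ones_like(t), np.asarray(C, float), np.ones_like(t))

    def test_constant_trajectory(self):
        meas = sample_measurements([self._traj([7, 7, 7, 7, 7])], interval=1.0)
        np.testing.assert_array_equal(meas.values, 7.0)
        np.testing.assert_array_equal(meas.times, [1, 2, 3, 4])

    def test_mean_of_two(self):
        meas = sample_measurements(
            [self._traj([0, 0, 0]), self._traj([100, 100, 100])], interval=1.0
        )
        np.testing.assert_array_equal(meas.values, 50.0)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            sample_measurements([], interval=1.0)
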