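"""CSV readers/writers, the built-in scenario definitions and fixture generation.

All files are plain UTF-8 CSV with a header row and '.' decimal separator;
the time column is always minutes.  The scenario table reproduces the
package's benchmark experiments at desk scale: the well-mixed impulse
response, the uniform and the 99%/1% receptor-split compartment scenarios,
and the two synthetic delta-recovery benchmarks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import langevin, spatial
from .gillespie import gillespie_ensemble_mean
from .model import DeltaSchedule, MeasurementSeries, RateConstants, WellMixedState, egfr_parameters
from .ode import Trajectory, simulate_ode

__all__ = [
    "read_measurements",
    "write_measurements",
    "egfr_impulse_initial_state",
    "SCENARIOS",
    "make_fixtures",
]

#: Ligand impulse experiment: 200,000 receptors at rest, no complexes,
#: an impulse of 10,000 ligands at t = 0, no external stimulation.
EGFR_INIT = dict(R=200_000, C=0, L=10_000)


def egfr_impulse_initial_state() -> WellMixedState:
    return WellMixedState(t=0.0, **EGFR_INIT)


def read_measurements(path) -> MeasurementSeries:
    df = pd.read_csv(path)
    if not {"time_min", "C_measured"} <= set(df.columns):
        raise ValueError(f"{path}: measurement CSV needs columns time_min, C_measured")
    return MeasurementSeries(df["time_min"].to_numpy(), df["C_measured"].to_numpy())


def write_measurements(meas: MeasurementSeries, path) -> None:
    pd.DataFrame({"time_min": meas.times, "C_measured": meas.values}).to_csv(path, index=False)


def _write_summary(outdir: Path, command: str, seed: int, params: dict, outputs: list[str]) -> None:
    payload = {"command": command, "seed": seed, "parameters": params, "outputs": outputs}
    (outdir / "run_summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ----------------------------------------------------------------------
# scenario generators; each writes its file set into outdir and returns paths

def _fixtures_wellmixed(outdir: Path, seed: int, rates: RateConstants) -> list[str]:
    init = egfr_impulse_initial_state()
    t_end = 60.0
    ode = simulate_ode(rates, init, t_end)
    ode.to_csv(outdir / "ode_reference.csv")
    mean, runs = gillespie_ensemble_mean(rates, init, t_end, n=10, seed=seed)
    mean.to_csv(outdir / "ssa_ensemble_mean.csv")
    files = ["ode_reference.csv", "ssa_ensemble_mean.csv"]
    for i, r in enumerate(runs):
        name = f"ssa_realisation_{i:02d}.csv"
        r.to_csv(outdir / name)
        files.append(name)
    return files


def _fixtures_spatial(outdir: Path, seed: int, rates: RateConstants, hot_fraction: float) -> list[str]:
    init = egfr_impulse_initial_state()
    layout = spatial.build_ring_layout(M=16, hop_rate=0.1, hot_fraction=hot_fraction, hot_size=8)
    results = spatial.spatial_ensemble(rates, layout, init, t_end=60.0, n=10, seed=seed)
    files = []
    for i, r in enumerate(results):
        name = f"spatial_realisation_{i:02d}.csv"
        r.to_frame().to_csv(outdir / name, index=False)
        files.append(name)
    meas = spatial.sample_measurements(results, interval=2.0)
    write_measurements(meas, outdir / "measurements.csv")
    t, d, deficit = spatial.mean_delta_series(results)
    pd.DataFrame({"time_min": t, "delta": d, "mixing_deficit": deficit}).to_csv(
        outdir / "delta_recorded.csv", index=False
    )
    return files + ["measurements.csv", "delta_recorded.csv"]


def _fixtures_constant_delta(outdir: Path, seed: int, rates: RateConstants) -> list[str]:
    init = egfr_impulse_initial_state()
    traj = langevin.ensemble_mean(
        rates, init, DeltaSchedule.constant(0.5), t_end=10.0, n=100, seed=seed, dt_out=1.0
    )
    meas = MeasurementSeries(traj.t[1:], traj.C[1:], t0=0.0)
    write_measurements(meas, outdir / "measurements.csv")
    return ["measurements.csv"]


def _fixtures_uniform_delta(outdir: Path, seed: int, rates: RateConstants) -> list[str]:
    init = egfr_impulse_initial_state()
    sched = DeltaSchedule.uniform_process(0.3, 0.7, t_N=10.0 / 60.0)
    traj = langevin.ensemble_mean(rates, init, sched, t_end=10.0, n=100, seed=seed, dt_out=1.0)
    meas = MeasurementSeries(traj.t[1:], traj.C[1:], t0=0.0)
    write_measurements(meas, outdir / "measurements.csv")
    return ["measurements.csv"]


SCENARIOS = {
    "wellmixed": "ODE reference plus a 10-realisation exact SSA ensemble of the ligand impulse",
    "uniform-spatial": "compartment SSA with uniform receptors and ligands (well-mixed check)",
    "fig3": "compartment SSA with 99% of receptors on one half of the ring, ligands uniform",
    "constant-delta": "Langevin-generated measurements under constant delta* = 0.5",
    "uniform-delta": "Langevin-generated measurements under delta ~ Uniform[0.3, 0.7], t_N = 10 s",
}


def make_fixtures(scenario: str, seed: int, outdir) -> list[Path]:
    """Write the named scenario's config, trajectories and measurement files."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; options: {sorted(SCENARIOS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rates = egfr_parameters()
    if scenario == "wellmixed":
        files = _fixtures_wellmixed(outdir, seed, rates)
    elif scenario == "uniform-spatial":
        files = _fixtures_spatial(outdir, seed, rates, hot_fraction=0.5)
    elif scenario == "fig3":
        files = _fixtures_spatial(outdir, seed, rates, hot_fraction=0.99)
    elif scenario == "constant-delta":
        files = _fixtures_constant_delta(outdir, seed, rates)
    else:
        files = _fixtures_uniform_delta(outdir, seed, rates)
    params = dict(EGFR_INIT)
    params["scenario"] = scenario
    _write_summary(outdir, f"make-fixtures {scenario}", seed, params, files)
    return [outdir / f for f in files] + [outdir / "run_summary.json"]
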