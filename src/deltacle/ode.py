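"""Deterministic reference model: numerical integration of the mean-field ODEs.

    dR/dt = -k_on R L + k_off C - k_t R + Q_R
    dC/dt =  k_on R L - k_off C - k_e C
    dL/dt = -k_on R L + k_off C + F(t)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import RateConstants, WellMixedState

__all__ = ["Trajectory", "simulate_ode"]


@dataclass
class Trajectory:
    """Time-ordered states of the well-mixed system, with optional delta values.

    Columns are total counts; counts are real-valued (ODE/Langevin output)
    or integer-valued cast to float (SSA output sampled on a grid).
    """

    t: np.ndarray
    R: np.ndarray
    C: np.ndarray
    L: np.ndarray
    delta: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("R", "C", "L"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.t.shape == self.R.shape == self.C.shape == self.L.shape):
            raise ValueError("t, R, C, L must have equal shapes")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.delta is not None:
            self.delta = np.asarray(self.delta, dtype=float)
            if self.delta.shape != self.t.shape:
                raise ValueError("delta must align with the time grid")

    def state_at(self, t: float) -> WellMixedState:
        i = int(np.argmin(np.abs(self.t - t)))
        if abs(self.t[i] - t) > 1e-9 + 1e-9 * abs(t):
            raise ValueError(f"t={t} is not on the trajectory grid")
        return WellMixedState(self.t[i], self.R[i], self.C[i], self.L[i])

    def to_frame(self) -> pd.DataFrame:
        data = {"time_min": self.t, "R": self.R, "C": self.C, "L": self.L}
        if self.delta is not None:
            data["delta"] = self.delta
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        delta = df["delta"].to_numpy() if "delta" in df.columns else None
        return cls(df["time_min"].to_numpy(), df["R"].to_numpy(), df["C"].to_numpy(),
                   df["L"].to_numpy(), delta)


def simulate_ode(
    rates: RateConstants,
    init: WellMixedState,
    t_end: float,
    dt_out: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> Trajectory:
    """Integrate the mean-field ODE system from ``init.t`` to ``init.t + t_end``.

    Uses an adaptive stiff-capable integrator (LSODA); output is sampled every
    ``dt_out`` minutes.  Tiny negative undershoots from the integrator are
    clamped to zero on output since counts are physical.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    t0 = init.t

    def rhs(t, y):
        r, c, l = y
        a = rates.k_on * r * l
        return [
            -a + rates.k_off * c - rates.k_t * r + rates.Q_R,
            a - rates.k_off * c - rates.k_e * c,
            -a + rates.k_off * c + rates.F(t),
        ]

    n = int(round(t_end / dt_out))
    t_eval = t0 + np.linspace(0.0, n * dt_out, n + 1)
    if t_eval[-1] < t0 + t_end - 1e-12:
        t_eval = np.append(t_eval, t0 + t_end)
    sol = solve_ivp(
        rhs,
        (t0, t0 + t_end),
        [init.R, init.C, init.L],
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = np.clip(sol.y, 0.0, None)
    return Trajectory(sol.t, y[0], y[1], y[2])
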