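"""Reaction network, domain types, propensities and the spatial correction term.

The network is the five-reaction ligand--receptor system

    R + L <-> C   (k_on, k_off)
    C -> 0        (k_e, complex internalisation)
    R -> 0        (k_t, receptor internalisation)
    F(t) -> L     (external ligand source)
    Q_R  -> R     (receptor generation)

with R, L, C the copy numbers of free receptor, free ligand and bound complex.
Spatial heterogeneity enters through a single scalar correction ``delta`` in
[0, 1] that discounts the bimolecular association propensity:
``k_on * (1 - delta) * R * L``.  ``delta = 0`` is the well-mixed condition,
``delta = 1`` complete spatial separation of receptors and ligands (no
association).  ``delta`` is computed exactly from subvolume occupancies by
:func:`compute_delta`.

All rates are per minute; time is measured in minutes throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RateConstants",
    "WellMixedState",
    "SpatialState",
    "DeltaSchedule",
    "MeasurementSeries",
    "egfr_parameters",
    "propensities",
    "compute_delta",
    "stoichiometry",
    "load_rate_config",
    "SECONDS_PER_MINUTE",
    "AVOGADRO",
]

SECONDS_PER_MINUTE = 60.0

#: Avogadro's number used to convert molar K_D into molecule counts.
AVOGADRO = 6.023e23

#: Reaction channel names, in the fixed order used by every simulator.
CHANNELS = (
    "association",
    "dissociation",
    "complex_internalisation",
    "receptor_internalisation",
    "ligand_source",
    "receptor_source",
)

# Change vectors for (R, C, L), one row per channel in CHANNELS order.
_STOICH = np.array(
    [
        [-1, +1, -1],  # R + L -> C
        [+1, -1, +1],  # C -> R + L
        [0, -1, 0],    # C -> 0
        [-1, 0, 0],    # R -> 0
        [0, 0, +1],    # F(t) -> L
        [+1, 0, 0],    # Q_R -> R
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class RateConstants:
    """Kinetic parameters of the ligand--receptor network.

    Parameters
    ----------
    k_on : float
        Association rate, 1/(molecule * min).
    k_off : float
        Dissociation rate, 1/min.
    k_e : float
        Complex internalisation rate, 1/min.
    k_t : float
        Receptor internalisation rate, 1/min.
    Q_R : float
        Receptor generation rate, molecules/min.
    F : callable, optional
        External ligand source as a function of time [min] returning
        molecules/min.  Defaults to no stimulation, F(t) = 0.
    """

    k_on: float
    k_off: float
    k_e: float
    k_t: float
    Q_R: float
    F: Callable[[float], float] = field(default=lambda t: 0.0)

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_e", "k_t", "Q_R"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def constant_ligand_source(self) -> float:
        """Return F as a constant rate, or raise if F is time-varying.

        The event-driven simulators require a time-homogeneous ligand
        source; the ODE and Langevin integrators accept any F(t).
        """
        probes = [self.F(t) for t in (0.0, 1.0, 17.0, 1e3)]
        if max(probes) != min(probes):
            raise ValueError("event-driven simulation requires a constant ligand source F")
        if probes[0] < 0:
            raise ValueError("F(t) must be >= 0")
        return float(probes[0])


@dataclass
class WellMixedState:
    """Total molecule counts at a time point (integer for SSA, real otherwise)."""

    t: float
    R: float
    C: float
    L: float

    def __post_init__(self) -> None:
        if min(self.R, self.C, self.L) < 0:
            raise ValueError("molecule counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.C, self.L], dtype=float)


@dataclass
class SpatialState:
    """Per-subvolume copy numbers over M well-mixed subvolumes."""

    t: float
    R: np.ndarray
    L: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=np.int64)
        self.L = np.asarray(self.L, dtype=np.int64)
        self.C = np.asarray(self.C, dtype=np.int64)
        if not (self.R.shape == self.L.shape == self.C.shape) or self.R.ndim != 1:
            raise ValueError("R, L, C must be 1-D arrays of equal length")
        if self.R.size < 1:
            raise ValueError("at least one subvolume is required")
        if min(self.R.min(), self.L.min(), self.C.min()) < 0:
            raise ValueError("subvolume counts must be nonnegative")

    @property
    def M(self) -> int:
        return self.R.size

    def totals(self) -> WellMixedState:
        return WellMixedState(self.t, int(self.R.sum()), int(self.C.sum()), int(self.L.sum()))


@dataclass
class DeltaSchedule:
    """A representation of the correction-term trajectory delta(t).

    Four modes are supported:

    ``constant``
        a single value held for all time;
    ``piecewise``
        values ``values[k]`` on the half-open intervals
        ``(breakpoints[k], breakpoints[k+1]]``;
    ``uniform_process``
        delta redrawn ~ Uniform[u_lo, u_hi] every ``t_N`` minutes;
    ``sde``
        d(delta) = a_delta dt + b_delta dw, reflected into [0, 1].
    """

    mode: str
    value: float | None = None
    breakpoints: np.ndarray | None = None
    values: np.ndarray | None = None
    u_lo: float | None = None
    u_hi: float | None = None
    t_N: float | None = None
    a_delta: float | None = None
    b_delta: float | None = None
    delta0: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "constant":
            if self.value is None or not 0.0 <= self.value <= 1.0:
                raise ValueError("constant delta must lie in [0, 1]")
        elif self.mode == "piecewise":
            self.breakpoints = np.asarray(self.breakpoints, dtype=float)
            self.values = np.asarray(self.values, dtype=float)
            if self.breakpoints.size != self.values.size + 1:
                raise ValueError("piecewise schedule needs len(breakpoints) == len(values) + 1")
            if np.any(np.diff(self.breakpoints) <= 0):
                raise ValueError("piecewise breakpoints must be strictly increasing")
            if np.any((self.values < 0) | (self.values > 1)):
                raise ValueError("piecewise delta values must lie in [0, 1]")
        elif self.mode == "uniform_process":
            if not (self.u_lo is not None and self.u_hi is not None and self.t_N is not None):
                raise ValueError("uniform_process needs u_lo, u_hi and t_N")
            if not 0.0 <= self.u_lo <= self.u_hi <= 1.0:
                raise ValueError("need 0 <= u_lo <= u_hi <= 1")
            if self.t_N <= 0:
                raise ValueError("t_N must be positive")
        elif self.mode == "sde":
            if self.a_delta is None or self.b_delta is None:
                raise ValueError("sde mode needs a_delta and b_delta")
            d0 = 0.5 if self.delta0 is None else self.delta0
            if not 0.0 <= d0 <= 1.0:
                raise ValueError("sde initial delta must lie in [0, 1]")
            self.delta0 = d0
        else:
            raise ValueError(f"unknown delta schedule mode {self.mode!r}")

    # ------------------------------------------------------------------
    @classmethod
    def constant(cls, value: float) -> "DeltaSchedule":
        return cls(mode="constant", value=float(value))

    @classmethod
    def piecewise(cls, breakpoints: Sequence[float], values: Sequence[float]) -> "DeltaSchedule":
        return cls(mode="piecewise", breakpoints=breakpoints, values=values)

    @classmethod
    def uniform_process(cls, u_lo: float, u_hi: float, t_N: float) -> "DeltaSchedule":
        """Uniformly resampled delta; ``t_N`` is the resampling period in minutes."""
        return cls(mode="uniform_process", u_lo=float(u_lo), u_hi=float(u_hi), t_N=float(t_N))

    @classmethod
    def sde(cls, a_delta: float, b_delta: float, delta0: float = 0.5) -> "DeltaSchedule":
        return cls(mode="sde", a_delta=float(a_delta), b_delta=float(b_delta), delta0=float(delta0))

    # ------------------------------------------------------------------
    def piecewise_lookup(self, t: float) -> float:
        """Value on the interval (t_{k-1}, t_k] containing ``t`` (piecewise mode)."""
        if self.mode == "constant":
            return float(self.value)
        if self.mode != "piecewise":
            raise ValueError("lookup only defined for constant/piecewise schedules")
        bp = self.breakpoints
        if t <= bp[0] or t > bp[-1]:
            raise ValueError(f"t={t} outside schedule span ({bp[0]}, {bp[-1]}]")
        k = int(np.searchsorted(bp, t, side="left")) - 1
        return float(self.values[k])


@dataclass
class MeasurementSeries:
    """Sampled complex-count observations (t_k, C~_k), k = 1..N, with t_0 the start."""

    times: np.ndarray
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size or self.times.size < 1:
            raise ValueError("need N >= 1 measurements with matching times")
        if np.any(np.diff(self.times) <= 0) or self.times[0] <= self.t0:
            raise ValueError("measurement times must be strictly increasing and > t0")
        if np.any(self.values < 0):
            raise ValueError("measured complex counts must be >= 0")

    def __len__(self) -> int:
        return self.times.size


# ----------------------------------------------------------------------
def egfr_parameters() -> RateConstants:
    """The EGFR ligand--receptor parameter set of the human mammary epithelial cell.

    k_off = 0.24/min; K_D = 2.47e-9 M converted to molecule counts via
    Avogadro's number and the cell volume V_cell = 4e-10 L; k_on = k_off/K_D;
    k_t = 0.02/min; Q_R = 2e5 * k_t; k_e = 0.15/min; no external ligand
    stimulation (F = 0).
    """
    k_off = 0.24
    K_D = 2.47e-9 * AVOGADRO * 4e-10  # molecules
    k_t = 0.02
    return RateConstants(
        k_on=k_off / K_D,
        k_off=k_off,
        k_e=0.15,
        k_t=k_t,
        Q_R=2e5 * k_t,
    )


def propensities(state: WellMixedState, rates: RateConstants, delta: float = 0.0) -> np.ndarray:
    """Per-unit-time propensities of the six channels, in ``CHANNELS`` order.

    Only the bimolecular association channel is discounted by the spatial
    correction: ``k_on * (1 - delta) * R * L``.  Unimolecular channels are
    unaffected by spatial heterogeneity.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must lie in [0, 1], got {delta}")
    if min(state.R, state.C, state.L) < 0:
        raise ValueError("molecule counts must be nonnegative")
    f = rates.F(state.t)
    if f < 0:
        raise ValueError("F(t) must be >= 0")
    return np.array(
        [
            rates.k_on * (1.0 - delta) * state.R * state.L,
            rates.k_off * state.C,
            rates.k_e * state.C,
            rates.k_t * state.R,
            f,
            rates.Q_R,
        ]
    )


def compute_delta(spatial: SpatialState) -> float:
    """Exact spatial correction term from subvolume occupancies.

    delta = (sum over i != j of R_i L_j) / (R L) = 1 - (sum_i R_i L_i)/(R L),
    with R, L the totals.  Equals 0 when every receptor-ligand pair shares a
    subvolume and 1 when no pair does.

    Raises
    ------
    ValueError
        if either species is entirely absent (R L = 0); the correction is
        undefined there.  Simulators never need it in that case because the
        association propensity already vanishes.
    """
    R = float(spatial.R.sum())
    L = float(spatial.L.sum())
    if R <= 0 or L <= 0:
        raise ValueError("delta is undefined when R = 0 or L = 0")
    cross = float(np.dot(spatial.R.astype(float), spatial.L.astype(float)))
    delta = 1.0 - cross / (R * L)
    # guard against rounding just outside [0, 1]
    return min(1.0, max(0.0, delta))


def stoichiometry() -> np.ndarray:
    """Integer change vectors for (R, C, L), one row per channel in ``CHANNELS`` order."""
    return _STOICH.copy()


# ----------------------------------------------------------------------
def load_rate_config(path) -> RateConstants:
    """Load rate constants from a flat YAML/JSON key-value file.

    Recognised keys: k_on, k_off, k_e, k_t, Q_R, F_const, and optionally
    K_D or (K_D_molar, N_av, V_cell) from which k_on is derived when k_on
    is absent.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    known = {"k_on", "k_off", "k_e", "k_t", "Q_R", "F_const", "K_D", "K_D_molar", "N_av", "V_cell"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "k_on" in raw:
        k_on = float(raw["k_on"])
    elif "K_D" in raw:
        k_on = float(raw["k_off"]) / float(raw["K_D"])
    elif "K_D_molar" in raw:
        n_av = float(raw.get("N_av", AVOGADRO))
        v_cell = float(raw["V_cell"])
        k_on = float(raw["k_off"]) / (float(raw["K_D_molar"]) * n_av * v_cell)
    else:
        raise ValueError("config must provide k_on, K_D or K_D_molar (+V_cell)")
    f_const = float(raw.get("F_const", 0.0))
    if f_const < 0:
        raise ValueError("F_const must be >= 0")
    return RateConstants(
        k_on=k_on,
        k_off=float(raw["k_off"]),
        k_e=float(raw["k_e"]),
        k_t=float(raw["k_t"]),
        Q_R=float(raw["Q_R"]),
        F=lambda t, _f=f_const: _f,
    )
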