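"""Scenario integration over decades, plus a fixed-step verification oracle
and disease-event detection.

Time is integrated in days; reporting boundaries convert with 365 d/year.
The default integrator is scipy's LSODA (adaptive, stiffness-switching),
which copes with the disparate time scales of the model (stem-cell
divisions every ~100 d against terminal death rates of order 1/d).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import NoSteadyStateError, healthy_steady_state, rhs_counts, signals_from_counts
from .params import LayoutError, ModelParams, ParamError, SystemState

__all__ = [
    "DAYS_PER_YEAR",
    "SimulationError",
    "ScenarioConfig",
    "Trajectory",
    "simulate",
    "euler_oracle",
    "detect_manifestation",
    "healthy_plus_seed",
]

DAYS_PER_YEAR = 365.0


class SimulationError(RuntimeError):
    """Integration failed; the message carries the solver diagnostic."""


def healthy_plus_seed(params: ModelParams, n_cells: float = 1.0) -> SystemState:
    """Healthy equilibrium of the normal lineage with ``n_cells`` malignant
    stem cells added to the first MDS compartment."""
    state = healthy_steady_state(params, "normal")
    counts = state.counts.copy()
    mds = params.lineage("mds")
    counts[params.index("mds", mds.compartments[0].name)] = float(n_cells)
    return SystemState(t=0.0, counts=counts)


@dataclass
class ScenarioConfig:
    """Everything needed to run one scenario.

    ``initial`` may be an explicit :class:`SystemState` or the string
    ``"healthy_plus_seed"``, in which case ``seed_cells`` malignant stem
    cells are added to the healthy equilibrium.
    """

    params: ModelParams
    initial: SystemState | str = "healthy_plus_seed"
    seed_cells: float = 1.0
    horizon_years: float = 55.0
    output_interval_days: float = 30.0
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-8

    def validate(self) -> None:
        self.params.validate()
        if not self.horizon_years > 0:
            raise ParamError("horizon must be positive")
        if not 0 < self.output_interval_days <= self.horizon_years * DAYS_PER_YEAR:
            raise ParamError("output grid must be positive and fit in the horizon")

    def initial_state(self) -> SystemState:
        if isinstance(self.initial, SystemState):
            self.initial.check(self.params)
            return self.initial.copy()
        if self.initial == "healthy_plus_seed":
            return healthy_plus_seed(self.params, self.seed_cells)
        raise ParamError(f"unknown initial condition {self.initial!r}")


@dataclass
class Trajectory:
    """Time-indexed states, signals and detected events of one scenario."""

    params: ModelParams
    times: np.ndarray            # days, strictly increasing
    counts: np.ndarray           # (n_times, n_compartments)
    s_p: np.ndarray
    s_a: np.ndarray
    events: dict = field(default_factory=dict)
    solver_stats: dict = field(default_factory=dict)

    @property
    def times_years(self) -> np.ndarray:
        return self.times / DAYS_PER_YEAR

    def state_at(self, i: int) -> SystemState:
        return SystemState(t=float(self.times[i]), counts=self.counts[i].copy())

    def series(self, lineage: str, compartment: str) -> np.ndarray:
        return self.counts[:, self.params.index(lineage, compartment)]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"{lin}:{name}": self.counts[:, j]
                for j, (lin, name) in enumerate(self.params.labels())}
        frame = pd.DataFrame({"t_days": self.times, "t_years": self.times_years, **cols})
        frame["s_p"] = self.s_p
        frame["s_a"] = self.s_a
        return frame

    def check_invariants(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise SimulationError("trajectory times must be strictly increasing")
        if np.any(self.counts < 0):
            raise SimulationError("trajectory contains negative counts")


def _integrate(config: ScenarioConfig) -> Trajectory:
    config.validate()
    layout = config.params.layout()
    y0 = config.initial_state().counts
    t_end = config.horizon_years * DAYS_PER_YEAR
    t_eval = np.arange(0.0, t_end + 0.5 * config.output_interval_days,
                       config.output_interval_days)
    t_eval[-1] = min(t_eval[-1], t_end)

    sol = solve_ivp(
        lambda t, y: rhs_counts(y, layout),
        (0.0, t_end),
        y0,
        method=config.method,
        t_eval=t_eval,
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        raise SimulationError(
            f"solver failed at t = {sol.t[-1] if len(sol.t) else 0.0:.2f} d: {sol.message}"
        )
    if not np.all(np.isfinite(sol.y)):
        raise SimulationError("solver produced non-finite counts (overflow/NaN)")

    counts = sol.y.T.copy()
    # the exact solution is nonnegative; the integrator may undershoot by
    # O(atol) near zero, which we clip, but larger negatives are a bug
    floor = -10.0 * (config.atol + config.rtol * counts.max())
    if counts.min() < floor:
        raise SimulationError(
            f"solution went negative beyond tolerance (min {counts.min():.3e})"
        )
    np.clip(counts, 0.0, None, out=counts)

    sig = [signals_from_counts(c, layout) for c in counts]
    traj = Trajectory(
        params=config.params,
        times=sol.t.copy(),
        counts=counts,
        s_p=np.array([s.s_p for s in sig]),
        s_a=np.array([s.s_a for s in sig]),
        solver_stats={"nfev": int(sol.nfev), "method": config.method,
                      "rtol": config.rtol, "atol": config.atol},
    )
    traj.check_invariants()
    return traj


def simulate(config: ScenarioConfig) -> Trajectory:
    """Integrate a scenario and annotate clinical-manifestation onset.

    Manifestation (if a normal mature pool and the mds lineage exist) is
    recorded in ``trajectory.events["manifestation_years"]``.
    """
    traj = _integrate(config)
    labels = [lin.label for lin in config.params.lineages]
    if "normal" in labels:
        try:
            _normal_mature_index(config.params)
            t_m = detect_manifestation(traj)
        except (ParamError, KeyError, NoSteadyStateError):
            return traj
        if t_m is not None:
            traj.events["manifestation_years"] = t_m
    return traj


def euler_oracle(config: ScenarioConfig, step: float) -> Trajectory:
    """Fixed-step explicit-Euler integration, the simulator's independent
    verification oracle.

    First-order accurate; converges to the adaptive solution as ``step``
    shrinks.  A step producing negative counts is rejected as unstable
    (heuristic: the step must be small against the fastest rate, roughly
    ``step * max(d, p_max) < 1``).
    """
    config.validate()
    if step <= 0:
        raise ParamError("step must be positive")
    layout = config.params.layout()
    y = config.initial_state().counts.astype(float)
    t_end = config.horizon_years * DAYS_PER_YEAR
    out_dt = config.output_interval_days
    n_steps = int(np.ceil(t_end / step))

    times = [0.0]
    states = [y.copy()]
    next_out = out_dt
    t = 0.0
    for _ in range(n_steps):
        h = min(step, t_end - t)
        y = y + h * rhs_counts(y, layout)
        t += h
        if y.min() < -1e-9 * max(y.max(), 1.0):
            raise SimulationError(
                f"explicit Euler unstable at t = {t:.2f} d (negative counts); "
                "use a smaller step"
            )
        np.clip(y, 0.0, None, out=y)
        if t + 1e-9 >= next_out or t >= t_end - 1e-12:
            times.append(t)
            states.append(y.copy())
            next_out += out_dt
    counts = np.vstack(states)
    sig = [signals_from_counts(c, layout) for c in counts]
    return Trajectory(
        params=config.params,
        times=np.asarray(times),
        counts=counts,
        s_p=np.array([s.s_p for s in sig]),
        s_a=np.array([s.s_a for s in sig]),
        solver_stats={"method": "fixed_euler", "step": step, "n_steps": n_steps},
    )


def _normal_mature_index(params: ModelParams) -> int:
    normal = params.lineage("normal")
    term = normal.compartments[-1]
    if term.divides or not term.in_pb:
        raise ParamError("normal lineage has no mature peripheral-blood pool")
    return params.index("normal", term.name)


def detect_manifestation(
    traj: Trajectory,
    threshold_fraction: float = 0.5,
    baseline: Optional[float] = None,
) -> Optional[float]:
    """First time (years) the normal mature pool drops below
    ``threshold_fraction`` of its healthy steady-state value.

    Linear interpolation between output samples; ``None`` if never crossed.
    ``baseline`` defaults to the analytic healthy equilibrium of the
    trajectory's parameters.
    """
    idx = _normal_mature_index(traj.params)
    if baseline is None:
        ref = healthy_steady_state(traj.params, "normal")
        baseline = float(ref.counts[idx])
    if baseline <= 0:
        raise ParamError("healthy baseline mature count must be positive")
    level = threshold_fraction * baseline
    mature = traj.counts[:, idx]
    below = mature < level
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(traj.times[0] / DAYS_PER_YEAR)
    t0, t1 = traj.times[i - 1], traj.times[i]
    c0, c1 = mature[i - 1], mature[i]
    t_cross = t0 + (level - c0) * (t1 - t0) / (c1 - c0)
    return float(t_cross / DAYS_PER_YEAR)
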