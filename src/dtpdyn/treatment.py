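"""Intermittent-treatment engine.

Runs the population model under periodic dosing cycle by cycle, detects
convergence to a stable periodic orbit, scans (therapeutic time, drug
holiday) grids for the min-max schedule optimization, and sweeps the
epigenetic-noise and selection-strength parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .grid import Grid
from .params import CellularParams, DoseSchedule, EpigeneticParams
from .population import (
    PopulationSolver,
    PopulationState,
    stationary_init,
    simulate,
)
from .singlecell import simulate_singlecell

__all__ = [
    "PeriodicSummary",
    "ScheduleGridResult",
    "run_intermittent",
    "optimize_schedule",
    "noise_sweep",
    "alpha_sweep",
]


@dataclass(frozen=True)
class PeriodicSummary:
    """Extremes of the relative tumor size over the converged cycle."""

    max_size: float
    min_size: float
    n_cycles_to_converge: int
    converged: bool
    #: relative size at the end of the dosed part of the converged cycle,
    #: the quantity constrained by the schedule optimization
    end_of_treatment_size: float = float("nan")


@dataclass
class ScheduleGridResult:
    """Grid scan of cycle maxima over (tau_on, tau_off) with feasibility."""

    tau_on_values: NDArray
    tau_off_values: NDArray
    max_size: NDArray       # shape (n_tau_on, n_tau_off)
    min_size: NDArray
    feasible: NDArray       # end-of-treatment size below the start size
    optimum: tuple[float, float] | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ton in enumerate(self.tau_on_values):
            for j, toff in enumerate(self.tau_off_values):
                rows.append(
                    (
                        ton,
                        toff,
                        self.max_size[i, j],
                        self.min_size[i, j],
                        bool(self.feasible[i, j]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["tau_on", "tau_off", "max_size", "min_size", "feasible"]
        )


def run_intermittent(
    ep: EpigeneticParams,
    cp: CellularParams,
    tau_on: float,
    tau_off: float,
    c_on: float = 0.9,
    dt: float = 0.01,
    state: PopulationState | None = None,
    grid: Grid | None = None,
    mass_frac: float = 0.08,
    rel_tol: float = 0.01,
    max_cycles: int = 40,
    record: bool = False,
) -> tuple[pd.DataFrame | None, PeriodicSummary]:
    """Integrate periodic dosing until the cycle maxima stabilize.

    The cycle is declared stable when the relative change of consecutive
    cycle maxima stays below ``rel_tol`` for two consecutive cycles.
    ``tau_off = 0`` degenerates to the continuous high-dose run.
    """
    if grid is None:
        grid = state.grid if state is not None else Grid()
    if state is None:
        state = stationary_init(ep, cp, grid, mass_frac=mass_frac)
    else:
        state = state.copy()
    state.t = 0.0
    schedule = DoseSchedule.intermittent(tau_on, tau_off, c_on=c_on)
    solver = PopulationSolver(ep, cp, grid, schedule, dt)
    baseline = state.Q_hat
    period = tau_on + tau_off if tau_off > 0.0 else tau_on
    steps_per_cycle = int(round(period / dt))
    steps_on = int(round(tau_on / dt))

    traj_t: list[float] = []
    traj_rel: list[float] = []
    maxima: list[float] = []
    minima: list[float] = []
    end_sizes: list[float] = []
    converged = False
    n_cycles = 0

    for cycle in range(max_cycles):
        cyc_max = -np.inf
        cyc_min = np.inf
        end_of_on = np.nan
        for s in range(steps_per_cycle):
            state = solver.step(state)
            rel = state.Q_hat / baseline
            cyc_max = max(cyc_max, rel)
            cyc_min = min(cyc_min, rel)
            if s + 1 == steps_on:
                end_of_on = rel
            if record:
                traj_t.append(state.t)
                traj_rel.append(rel)
        maxima.append(cyc_max)
        minima.append(cyc_min)
        end_sizes.append(end_of_on)
        n_cycles = cycle + 1
        if len(maxima) >= 3:
            d1 = abs(maxima[-1] - maxima[-2]) / maxima[-2]
            d2 = abs(maxima[-2] - maxima[-3]) / maxima[-3]
            if d1 < rel_tol and d2 < rel_tol:
                converged = True
                break

    summary = PeriodicSummary(
        max_size=float(maxima[-1]),
        min_size=float(minima[-1]),
        n_cycles_to_converge=n_cycles,
        converged=converged,
        end_of_treatment_size=float(end_sizes[-1]),
    )
    traj = (
        pd.DataFrame({"t": traj_t, "rel_size": traj_rel}) if record else None
    )
    return traj, summary


def optimize_schedule(
    ep: EpigeneticParams,
    cp: CellularParams,
    tau_on_grid,
    tau_off_grid,
    c_on: float = 0.9,
    dt: float = 0.01,
    grid: Grid | None = None,
    mass_frac: float = 0.08,
    max_cycles: int = 40,
) -> ScheduleGridResult:
    """Min-max scan: minimize the converged-cycle maximum size.

    A schedule is feasible when the size at the end of its dosed phase (on
    the converged cycle) stays below the pre-treatment size.  Ties are
    broken toward the longer drug holiday.  The shared preheated start
    state is built once and reused across the grid.
    """
    tau_on_grid = np.asarray(list(tau_on_grid), dtype=float)
    tau_off_grid = np.asarray(list(tau_off_grid), dtype=float)
    if grid is None:
        grid = Grid()
    base = stationary_init(ep, cp, grid, mass_frac=mass_frac)

    shape = (tau_on_grid.size, tau_off_grid.size)
    max_size = np.full(shape, np.nan)
    min_size = np.full(shape, np.nan)
    feasible = np.zeros(shape, dtype=bool)
    for i, ton in enumerate(tau_on_grid):
        for j, toff in enumerate(tau_off_grid):
            _, summ = run_intermittent(
                ep,
                cp,
                ton,
                toff,
                c_on=c_on,
                dt=dt,
                state=base,
                max_cycles=max_cycles,
            )
            max_size[i, j] = summ.max_size
            min_size[i, j] = summ.min_size
            feasible[i, j] = (
                summ.converged and summ.end_of_treatment_size < 1.0
            )

    optimum = None
    if feasible.any():
        masked = np.where(feasible, max_size, np.inf)
        best = np.inf
        for i in range(shape[0]):
            for j in range(shape[1]):
                # strict improvement, or a tie resolved toward longer holiday
                if masked[i, j] < best - 1e-12 or (
                    optimum is not None
                    and abs(masked[i, j] - best) <= 1e-12
                    and tau_off_grid[j] > optimum[1]
                ):
                    best = masked[i, j]
                    optimum = (float(tau_on_grid[i]), float(tau_off_grid[j]))
    return ScheduleGridResult(
        tau_on_grid, tau_off_grid, max_size, min_size, feasible, optimum
    )


def noise_sweep(
    ep_base: EpigeneticParams,
    cp: CellularParams,
    eta0_values,
    schedule_or_dose,
    t_end: float = 60.0,
    dt: float = 0.01,
    grid: Grid | None = None,
    mass_frac: float = 0.08,
    singlecell_t_end: float | None = None,
) -> pd.DataFrame:
    """Sweep the inverse epigenetic noise eta0.

    For each value: population run (recovery time = first time the relative
    size re-attains 1 after its nadir; maximum size over the run) and
    single-cell run (late-time resistant probability).  Under an
    intermittent schedule the cell-type probabilities oscillate with the
    dosing cycle, so the reported value is the maximum over the last full
    cycle rather than an arbitrary mid-cycle snapshot.
    """
    if grid is None:
        grid = Grid()
    rows = []
    for eta0 in eta0_values:
        ep = replace(ep_base, eta0=float(eta0))
        if isinstance(schedule_or_dose, DoseSchedule):
            schedule = schedule_or_dose
        else:
            schedule = DoseSchedule.constant(float(schedule_or_dose))
        traj = simulate(
            ep, cp, schedule, t_end, dt=dt, grid=grid, mass_frac=mass_frac
        )
        i_nadir = int(np.argmin(traj.rel_size))
        after = traj.rel_size[i_nadir:]
        rec_idx = np.nonzero(after >= 1.0)[0]
        recovery = float(traj.t[i_nadir + rec_idx[0]]) if rec_idx.size else np.nan
        sc_t_end = singlecell_t_end if singlecell_t_end is not None else t_end
        probs = simulate_singlecell(
            ep, cp, schedule, sc_t_end, dt=dt, grid=grid
        )
        if schedule.mode == "intermittent":
            last_cycle = probs[probs["t"] > sc_t_end - schedule.period]
            p_res = float(last_cycle["P_resistant"].max())
        else:
            p_res = float(probs["P_resistant"].iloc[-1])
        rows.append(
            (float(eta0), recovery, float(traj.rel_size.max()), p_res)
        )
    return pd.DataFrame(
        rows, columns=["eta0", "recovery_time", "max_size", "P_resistant_final"]
    )


def alpha_sweep(
    ep_base: EpigeneticParams,
    cp: CellularParams,
    alpha_scale_values,
    schedule: DoseSchedule,
    t_end: float = 60.0,
    dt: float = 0.01,
    grid: Grid | None = None,
) -> pd.DataFrame:
    """Scale the selection strength (alpha0 and k jointly) and record the
    final resistant probability of the single-cell model."""
    if grid is None:
        grid = Grid()
    rows = []
    for scale in alpha_scale_values:
        s = float(scale)
        ep = replace(ep_base, alpha0=ep_base.alpha0 * s, k=ep_base.k * s)
        probs = simulate_singlecell(ep, cp, schedule, t_end, dt=dt, grid=grid)
        rows.append((s, float(probs["P_resistant"].iloc[-1])))
    return pd.DataFrame(rows, columns=["alpha_scale", "P_resistant_final"])
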