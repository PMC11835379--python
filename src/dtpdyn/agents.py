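"""Discrete-time stochastic simulation of individual cells.

Each cell carries a heritable trait ``x`` and a phenotype ``y``.  Per step a
cell divides with probability ``beta(x, Q_hat)*dt``, dies with probability
``gamma(y, c)*dt``, and otherwise rests: its phenotype takes an
Euler-Maruyama step of the adaptation drift with diffusion ``sigma``,
reflected into the unit interval by folding.  Daughters redraw their trait
from the inheritance kernel and keep the mother's phenotype.  The simulator
serves as an independent stochastic check on the density solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from . import kernels
from .params import CellularParams, DoseSchedule, EpigeneticParams
from .population import X_THRESHOLD, Y_THRESHOLD, PopulationState

__all__ = [
    "AgentPopulation",
    "init_agents_from_state",
    "step_agents",
    "run_agents",
]


@dataclass
class AgentPopulation:
    """Collection of cells plus the bookkeeping to map counts to Q_hat."""

    x: NDArray
    y: NDArray
    t: float = 0.0
    weight: float = 1.0  # contribution of one cell to the total Q_hat
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0), repr=False
    )

    @property
    def size(self) -> int:
        return self.x.size

    @property
    def Q_hat(self) -> float:
        return self.size * self.weight

    def copy(self) -> "AgentPopulation":
        # note: the generator state is shared, not copied
        return AgentPopulation(
            self.x.copy(), self.y.copy(), self.t, self.weight, self.rng
        )

    def fractions(self) -> tuple[float, float, float]:
        if self.size == 0:
            raise ValueError("empty population has no cell-type fractions")
        naive = self.y < Y_THRESHOLD
        high_x = self.x > X_THRESHOLD
        n = self.size
        p_naive = naive.sum() / n
        p_dtp = (~naive & high_x).sum() / n
        p_res = (~naive & ~high_x).sum() / n
        return float(p_naive), float(p_dtp), float(p_res)


def init_agents_from_state(
    state: PopulationState, n0: int, seed: int
) -> AgentPopulation:
    """Sample ``n0`` cells from a grid state, matching its total size.

    Cells are drawn per grid cell proportional to mass and jittered
    uniformly inside the cell; each agent carries weight ``Q_hat/n0`` so the
    agent total matches the continuum total.
    """
    if n0 < 1:
        raise ValueError("need at least one initial cell")
    rng = np.random.default_rng(seed)
    grid = state.grid
    p = state.Q.ravel()
    p = p / p.sum()
    idx = rng.choice(p.size, size=n0, p=p)
    ix, iy = np.unravel_index(idx, state.Q.shape)
    x = grid.x[ix] + (rng.random(n0) - 0.5) * grid.dx
    y = grid.y[iy] + (rng.random(n0) - 0.5) * grid.dy
    np.clip(x, 1e-9, 1.0 - 1e-9, out=x)
    np.clip(y, 0.0, 1.0, out=y)
    return AgentPopulation(
        x, y, t=0.0, weight=state.Q_hat / n0, rng=rng
    )


def _reflect_unit(y: NDArray) -> NDArray:
    """Fold values back into [0, 1] (zero-flux reflecting walls)."""
    y = np.mod(y, 2.0)
    return np.where(y > 1.0, 2.0 - y, y)


def step_agents(
    pop: AgentPopulation,
    ep: EpigeneticParams,
    cp: CellularParams,
    schedule: DoseSchedule,
    dt: float,
) -> AgentPopulation:
    """Advance every cell by one step (synchronous update).

    The crowding factor uses the total at the start of the step.  At most
    one event per cell per step, so ``dt`` must keep the summed event
    probability below one for every cell.
    """
    if pop.size == 0:
        return AgentPopulation(pop.x, pop.y, pop.t + dt, pop.weight, pop.rng)
    c = kernels.dose_at(schedule, pop.t)
    alpha = kernels.alpha_of_dose(ep, c)
    rng = pop.rng

    p_div = np.asarray(kernels.beta_rate(pop.x, pop.Q_hat, cp)) * dt
    p_die = np.asarray(kernels.death_rate(pop.y, c, cp)) * dt
    p_max = (p_div + p_die).max()
    if p_max >= 1.0:
        raise ValueError(
            f"dt={dt} too large: per-cell event probability {p_max:.3f} >= 1"
        )

    u = rng.random(pop.size)
    dies = u < p_die
    divides = ~dies & (u < p_die + p_div)
    rests = ~dies & ~divides

    # resting cells: Euler-Maruyama phenotype update with folding reflection
    y_new = pop.y.copy()
    if rests.any():
        xr = pop.x[rests]
        yr = pop.y[rests]
        drift = np.asarray(kernels.adaptation_velocity(xr, yr, c, cp))
        noise = (
            np.sqrt(2.0 * cp.sigma * dt) * rng.standard_normal(xr.size)
            if cp.sigma > 0.0
            else 0.0
        )
        y_new[rests] = _reflect_unit(yr + drift * dt + noise)

    # daughters: two per mother, trait redrawn, phenotype inherited
    if divides.any():
        mothers_z = pop.x[divides]
        mothers_y = pop.y[divides]
        z2 = np.repeat(mothers_z, 2)
        daughters_x = np.asarray(
            kernels.sample_daughter_ctp(z2, alpha, ep, rng)
        )
        daughters_y = np.repeat(mothers_y, 2)
    else:
        daughters_x = np.empty(0)
        daughters_y = np.empty(0)

    keep = rests
    x_out = np.concatenate([pop.x[keep], daughters_x])
    y_out = np.concatenate([y_new[keep], daughters_y])
    return AgentPopulation(x_out, y_out, pop.t + dt, pop.weight, rng)


def run_agents(
    ep: EpigeneticParams,
    cp: CellularParams,
    schedule: DoseSchedule,
    n0: int,
    t_end: float,
    dt: float = 0.01,
    seed: int = 0,
    init_state: PopulationState | None = None,
    record_every: float = 0.5,
    snapshot_times: tuple[float, ...] = (),
) -> pd.DataFrame:
    """Full stochastic trajectory of counts and cell-type fractions.

    Starts from ``n0`` cells sampled from ``init_state`` (a drug-free
    stationary state is built if omitted).  Extinction is a valid terminal
    outcome and is flagged in the result's attrs.  Optional per-cell
    snapshots (t, x, y) are collected at the requested times.
    """
    if init_state is None:
        from .grid import Grid
        from .population import stationary_init

        init_state = stationary_init(ep, cp, Grid())
    pop = init_agents_from_state(init_state, n0, seed)
    baseline = pop.Q_hat

    n_steps = int(round(t_end / dt))
    stride = max(1, int(round(record_every / dt)))
    rows = []
    snapshots: list[pd.DataFrame] = []
    snap_left = sorted(snapshot_times)

    def record(p: AgentPopulation) -> None:
        if p.size > 0:
            fr = p.fractions()
        else:
            fr = (np.nan, np.nan, np.nan)
        rows.append((p.t, p.size, p.Q_hat / baseline, *fr))

    record(pop)
    extinct = False
    for i in range(1, n_steps + 1):
        pop = step_agents(pop, ep, cp, schedule, dt)
        if snap_left and pop.t >= snap_left[0] - 0.5 * dt:
            snap_left.pop(0)
            snapshots.append(
                pd.DataFrame({"t": pop.t, "x": pop.x, "y": pop.y})
            )
        if pop.size == 0:
            extinct = True
            record(pop)
            break
        if i % stride == 0 or i == n_steps:
            record(pop)

    out = pd.DataFrame(
        rows,
        columns=["t", "N", "rel_size", "frac_naive", "frac_dtp", "frac_resistant"],
    )
    out.attrs["extinct"] = extinct
    out.attrs["snapshots"] = snapshots
    out.attrs["final_population"] = pop
    return out
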