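"""Deterministic solver for the phenotype-structured population model.

The state is a nonnegative matrix ``Q[i, j]`` of cell numbers per grid cell
over (trait ``x_i``, phenotype ``y_j``).  One time step applies, in order:
upwind advection of the phenotype, zero-flux central diffusion, an exact
exponential death factor, and the mitosis redistribution integral evaluated
with a precomputed (dose-keyed) inheritance matrix.  Each sub-operator is
positivity preserving for CFL-compliant steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from . import kernels
from .grid import Grid
from .params import CellularParams, DoseSchedule, EpigeneticParams

__all__ = [
    "PopulationState",
    "CellTypeFractions",
    "Trajectory",
    "PopulationSolver",
    "CFLError",
    "bump_init",
    "stationary_init",
    "step_population",
    "total_population_derivative",
    "classify_fractions",
    "preheat",
    "simulate",
]

X_THRESHOLD = 0.15
Y_THRESHOLD = 0.5


class CFLError(RuntimeError):
    """Raised when a step size violates the explicit stability bound."""


@dataclass
class PopulationState:
    """Grid-discretized population ``Q(x, y, t)`` with its total size."""

    Q: NDArray
    t: float
    grid: Grid

    @property
    def Q_hat(self) -> float:
        """Total cell number: the quadrature of Q over the unit square."""
        return float(self.Q.sum() * self.grid.dx * self.grid.dy)

    def copy(self) -> "PopulationState":
        return PopulationState(self.Q.copy(), self.t, self.grid)

    def trait_marginal(self, normalized: bool = True) -> NDArray:
        """Trait (x) marginal; normalized to integrate to one by default."""
        m = self.Q.sum(axis=1) * self.grid.dy
        if normalized:
            tot = m.sum() * self.grid.dx
            if tot <= 0.0:
                raise ValueError("empty population has no trait marginal")
            m = m / tot
        return m


@dataclass(frozen=True)
class CellTypeFractions:
    """Mass fractions of the three classification regions."""

    naive: float
    dtp: float
    resistant: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.naive, self.dtp, self.resistant)


@dataclass
class Trajectory:
    """Recorded time series of a population simulation."""

    t: NDArray
    Q_hat: NDArray
    rel_size: NDArray
    frac_naive: NDArray
    frac_dtp: NDArray
    frac_resistant: NDArray
    trait_marginals: NDArray | None = None
    final_state: PopulationState | None = field(default=None, repr=False)
    baseline: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "Q_hat": self.Q_hat,
                "rel_size": self.rel_size,
                "frac_naive": self.frac_naive,
                "frac_dtp": self.frac_dtp,
                "frac_resistant": self.frac_resistant,
            }
        )

    def save_snapshots(self, path: str, states: list[PopulationState]) -> None:
        # optional HDF5 dump of full Q snapshots keyed by time
        import h5py

        with h5py.File(path, "w") as fh:
            for st in states:
                fh.create_dataset(f"Q/{st.t:.4f}", data=st.Q)


def bump_init(
    cp: CellularParams,
    grid: Grid,
    x0: float = 0.05,
    y0: float = 0.2,
    width: float = 0.05,
    mass_frac: float = 0.08,
) -> PopulationState:
    """Truncated Gaussian start-up state normalized to ``mass_frac * K``."""
    gx = np.exp(-0.5 * ((grid.x - x0) / width) ** 2)
    gy = np.exp(-0.5 * ((grid.y - y0) / width) ** 2)
    Q = gx[:, None] * gy[None, :]
    Q *= mass_frac * cp.K / (Q.sum() * grid.dx * grid.dy)
    return PopulationState(Q, 0.0, grid)


def stationary_init(
    ep: EpigeneticParams,
    cp: CellularParams,
    grid: Grid,
    mass_frac: float = 0.08,
) -> PopulationState:
    """Drug-free quasi-stationary state with total size ``mass_frac * K``.

    The trait marginal solves the drug-free selection/inheritance balance;
    the phenotype profile at each trait node is the zero-flux stationary
    density of the adaptation drift plus diffusion,
    ``h(y; x) ∝ exp(-v0*x*(y - y0_off)^2 / (2*sigma))``.
    Feeding this state to :func:`preheat` converges almost immediately.
    """
    from .singlecell import stationary_g

    g = stationary_g(ep, cp, dose=0.0, grid=grid)
    if cp.sigma > 0.0:
        w = np.exp(
            -cp.v0
            * grid.x[:, None]
            * (grid.y[None, :] - cp.y0_off) ** 2
            / (2.0 * cp.sigma)
        )
    else:
        w = np.exp(-0.5 * ((grid.y[None, :] - cp.y0_off) / 0.02) ** 2)
        w = np.broadcast_to(w, (grid.nx, grid.ny)).copy()
    w /= w.sum(axis=1, keepdims=True) * grid.dy
    Q = g[:, None] * w * mass_frac * cp.K
    return PopulationState(Q, 0.0, grid)


class PopulationSolver:
    """Explicit operator-splitting integrator with dose-keyed caches."""

    def __init__(
        self,
        ep: EpigeneticParams,
        cp: CellularParams,
        grid: Grid,
        schedule: DoseSchedule,
        dt: float = 0.01,
    ):
        self.ep = ep
        self.cp = cp
        self.grid = grid
        self.schedule = schedule
        self.dt = dt
        self._beta1_x = np.asarray(kernels.beta1(grid.x, cp))
        self._cache: dict[float, tuple] = {}
        self._check_cfl(schedule.max_dose)

    # -- per-dose precomputation -------------------------------------------
    def _ops(self, c: float):
        key = round(c, 12)
        ops = self._cache.get(key)
        if ops is None:
            g = self.grid
            alpha = kernels.alpha_of_dose(self.ep, c)
            P = kernels.inheritance_matrix(g.x, alpha, self.ep, dx=g.dx)
            G = 2.0 * P * (self._beta1_x * g.dx)[None, :]
            v_if = np.zeros((g.nx, g.ny + 1))
            v_if[:, 1:-1] = kernels.adaptation_velocity(
                g.x[:, None], g.y_edges[None, 1:-1], c, self.cp
            )
            gamma_y = np.asarray(kernels.death_rate(g.y, c, self.cp))
            death_factor = np.exp(-gamma_y * self.dt)
            ops = (G, v_if, gamma_y, death_factor)
            self._cache[key] = ops
        return ops

    def _check_cfl(self, c: float) -> None:
        g = self.grid
        # worst case over both the dosed and the drug-free branch of v
        vmax = self.cp.v0 * max(
            c * max(self.cp.y0_on, 1.0 - self.cp.y0_on),
            max(self.cp.y0_off, 1.0 - self.cp.y0_off),
        )
        if vmax > 0.0 and self.dt > g.dy / vmax:
            raise CFLError(
                f"dt={self.dt} violates advection CFL: need dt <= "
                f"{g.dy / vmax:.4g} (max |v| = {vmax:.4g}, dy = {g.dy:.4g})"
            )
        if self.cp.sigma > 0.0 and self.dt > g.dy**2 / (2.0 * self.cp.sigma):
            raise CFLError(
                f"dt={self.dt} violates diffusion CFL: need dt <= "
                f"{g.dy**2 / (2.0 * self.cp.sigma):.4g}"
            )

    # -- one step ----------------------------------------------------------
    def step(self, state: PopulationState) -> PopulationState:
        g = self.grid
        dt = self.dt
        c = kernels.dose_at(self.schedule, state.t)
        G, v_if, _, death_factor = self._ops(c)
        Q = state.Q
        Q_hat = Q.sum() * g.dx * g.dy

        # phenotype advection (first-order upwind, zero boundary flux)
        vp = np.maximum(v_if[:, 1:-1], 0.0)
        vm = np.minimum(v_if[:, 1:-1], 0.0)
        F = vp * Q[:, :-1] + vm * Q[:, 1:]
        Q = Q.copy()
        Q[:, :-1] -= dt / g.dy * F
        Q[:, 1:] += dt / g.dy * F

        # phenotype diffusion (central, reflecting walls)
        if self.cp.sigma > 0.0:
            lap = np.empty_like(Q)
            lap[:, 1:-1] = Q[:, 2:] - 2.0 * Q[:, 1:-1] + Q[:, :-2]
            lap[:, 0] = Q[:, 1] - Q[:, 0]
            lap[:, -1] = Q[:, -2] - Q[:, -1]
            Q += dt * self.cp.sigma / g.dy**2 * lap

        # death (exact exponential factor per phenotype column)
        Q *= death_factor[None, :]

        # mitosis: gain of two redistributed daughters minus entry loss
        lf = max(0.0, 1.0 - Q_hat / self.cp.K)
        if lf > 0.0:
            Q += dt * lf * (G @ Q - self._beta1_x[:, None] * Q)

        if not np.isfinite(Q).all():
            raise FloatingPointError(f"non-finite population at t={state.t}")
        if Q.min() < -1e-12 * max(Q.max(), 1.0):
            raise FloatingPointError(f"negative population at t={state.t}")
        np.clip(Q, 0.0, None, out=Q)
        return PopulationState(Q, state.t + dt, g)

    def derivative_total(self, state: PopulationState) -> float:
        """dQ_hat/dt from the birth/death balance (cross-checks the stepper)."""
        g = self.grid
        c = kernels.dose_at(self.schedule, state.t)
        _, _, gamma_y, _ = self._ops(c)
        lf = max(0.0, 1.0 - state.Q_hat / self.cp.K)
        integrand = (
            lf * self._beta1_x[:, None] - gamma_y[None, :]
        ) * state.Q
        return float(integrand.sum() * g.dx * g.dy)


def step_population(
    state: PopulationState,
    ep: EpigeneticParams,
    cp: CellularParams,
    schedule: DoseSchedule,
    dt: float,
) -> PopulationState:
    """One-shot step (builds a throwaway solver; use the class in loops)."""
    return PopulationSolver(ep, cp, state.grid, schedule, dt).step(state)


def total_population_derivative(
    state: PopulationState,
    ep: EpigeneticParams,
    cp: CellularParams,
    schedule: DoseSchedule,
) -> float:
    return PopulationSolver(ep, cp, state.grid, schedule, 0.01).derivative_total(
        state
    )


def classify_fractions(
    state: PopulationState,
    x_threshold: float = X_THRESHOLD,
    y_threshold: float = Y_THRESHOLD,
) -> CellTypeFractions:
    """Mass fractions of naive (y < y_c), persister (y > y_c, x > x_c) and
    resistant (y > y_c, x < x_c) cells."""
    Q_hat = state.Q_hat
    if Q_hat <= 0.0:
        raise ValueError("cell-type fractions undefined for empty population")
    g = state.grid
    naive_mask = g.y < y_threshold
    high_x = g.x > x_threshold
    w = g.dx * g.dy / Q_hat
    naive = state.Q[:, naive_mask].sum() * w
    surv = state.Q[:, ~naive_mask]
    dtp = surv[high_x, :].sum() * w
    resistant = surv[~high_x, :].sum() * w
    return CellTypeFractions(float(naive), float(dtp), float(resistant))


def preheat(
    ep: EpigeneticParams,
    cp: CellularParams,
    init: PopulationState,
    tol: float = 1e-3,
    dt: float = 0.01,
    check_every: float = 1.0,
    max_days: float = 400.0,
) -> tuple[PopulationState, float]:
    """Drug-free burn-in until the trait marginal is stationary.

    Integrates with zero dose until the L1 change of the normalized trait
    marginal per day drops below ``tol``; returns the settled state and the
    elapsed time.  An already-stationary input returns immediately with
    elapsed time 0.
    """
    solver = PopulationSolver(
        ep, cp, init.grid, DoseSchedule.constant(0.0), dt
    )
    state = init.copy()
    state.t = 0.0
    marg = state.trait_marginal()
    dx = state.grid.dx

    # fast path: drift over a single step, rescaled to one day
    probe = solver.step(state)
    drift = np.abs(probe.trait_marginal() - marg).sum() * dx / dt
    if drift < tol:
        return state, 0.0

    n_per_check = max(1, int(round(check_every / dt)))
    while state.t < max_days:
        for _ in range(n_per_check):
            state = solver.step(state)
        new_marg = state.trait_marginal()
        drift = np.abs(new_marg - marg).sum() * dx / (n_per_check * dt)
        if drift < tol:
            return state, state.t
        marg = new_marg
    raise RuntimeError(
        f"trait marginal not stationary within {max_days} days "
        f"(last drift {drift:.3g}/day, tol {tol:.3g})"
    )


def simulate(
    ep: EpigeneticParams,
    cp: CellularParams,
    schedule: DoseSchedule,
    t_end: float,
    dt: float = 0.01,
    record_every: float = 0.5,
    state: PopulationState | None = None,
    grid: Grid | None = None,
    record_marginals: bool = False,
    mass_frac: float = 0.08,
) -> Trajectory:
    """Integrate the population model and record relative size and fractions.

    ``state`` should be a preheated (drug-free stationary) state; if omitted
    one is built with :func:`stationary_init`.  Time restarts at zero, i.e.
    the treatment clock; relative sizes are normalized to the initial total.
    """
    if grid is None:
        grid = state.grid if state is not None else Grid()
    if state is None:
        state = stationary_init(ep, cp, grid, mass_frac=mass_frac)
    else:
        state = state.copy()
    state.t = 0.0
    solver = PopulationSolver(ep, cp, grid, schedule, dt)
    baseline = state.Q_hat

    n_steps = int(round(t_end / dt))
    rec_stride = max(1, int(round(record_every / dt)))
    ts, qs, fr = [], [], []
    margs = [] if record_marginals else None

    def record(st: PopulationState) -> None:
        ts.append(st.t)
        qs.append(st.Q_hat)
        fr.append(classify_fractions(st).as_tuple())
        if margs is not None:
            margs.append(st.trait_marginal())

    record(state)
    for i in range(1, n_steps + 1):
        state = solver.step(state)
        if i % rec_stride == 0 or i == n_steps:
            record(state)

    qs_arr = np.asarray(qs)
    fr_arr = np.asarray(fr)
    return Trajectory(
        t=np.asarray(ts),
        Q_hat=qs_arr,
        rel_size=qs_arr / baseline,
        frac_naive=fr_arr[:, 0],
        frac_dtp=fr_arr[:, 1],
        frac_resistant=fr_arr[:, 2],
        trait_marginals=np.asarray(margs) if margs is not None else None,
        final_state=state,
        baseline=baseline,
    )
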