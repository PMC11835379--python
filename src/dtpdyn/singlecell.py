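"""Single-cell probability-density model.

The joint density ``f(x, y, t)`` of a cell's heritable trait and phenotype
factorizes as ``f = h(y, t; x) * g(x, t)``: ``g`` is the trait marginal and
``h`` the conditional phenotype density at each trait node.  ``g`` evolves
by the crowding-free inheritance/selection balance, ``h`` by phenotype
advection-diffusion with a relative-death reweighting (death rate minus its
population average).  The two equations are coupled explicitly with lagged
coefficients, matching the splitting order of the population solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from . import kernels
from .grid import Grid
from .params import CellularParams, DoseSchedule, EpigeneticParams
from .population import (
    X_THRESHOLD,
    Y_THRESHOLD,
    PopulationState,
)

__all__ = [
    "DensityState",
    "SingleCellSolver",
    "density_from_population",
    "stationary_g",
    "evolve_g",
    "step_g",
    "step_h",
    "cell_type_probabilities",
    "survival_curve",
    "simulate_singlecell",
]

#: trait-marginal mass below which the conditional density is frozen
G_FLOOR = 1e-12


@dataclass
class DensityState:
    """Factorized single-cell density: trait marginal and conditionals."""

    g: NDArray          # (nx,) trait marginal, integrates to 1
    h: NDArray          # (nx, ny) conditional phenotype density per x-node
    t: float
    grid: Grid

    def copy(self) -> "DensityState":
        return DensityState(self.g.copy(), self.h.copy(), self.t, self.grid)

    @property
    def f(self) -> NDArray:
        """Joint density ``f = h * g``."""
        return self.h * self.g[:, None]


def density_from_population(state: PopulationState) -> DensityState:
    """Normalize a population state into the factorized density."""
    Q_hat = state.Q_hat
    if Q_hat <= 0.0:
        raise ValueError("cannot form a density from an empty population")
    grid = state.grid
    f = state.Q / Q_hat
    g = f.sum(axis=1) * grid.dy
    h = np.full_like(f, 1.0)  # uniform conditional where g vanishes
    ok = g > G_FLOOR
    h[ok] = f[ok] / g[ok, None]
    return DensityState(g, h, state.t, grid)


def _g_ops(ep: EpigeneticParams, cp: CellularParams, dose: float, grid: Grid):
    alpha = kernels.alpha_of_dose(ep, dose)
    P = kernels.inheritance_matrix(grid.x, alpha, ep, dx=grid.dx)
    b1 = np.asarray(kernels.beta1(grid.x, cp))
    return P, b1


def step_g(
    g: NDArray,
    ep: EpigeneticParams,
    cp: CellularParams,
    dose: float,
    dt: float,
    grid: Grid,
    _ops=None,
) -> NDArray:
    """One Euler step of the trait-marginal equation (crowding ignored).

    Gain of two redistributed daughters against the entry loss and the mean
    growth; the discrete right-hand side integrates to zero whenever ``g``
    does, so normalization is preserved to round-off.
    """
    P, b1 = _ops if _ops is not None else _g_ops(ep, cp, dose, grid)
    flux = b1 * g
    mean_b1 = flux.sum() * grid.dx
    rhs = 2.0 * (P @ flux) * grid.dx - g * (b1 + mean_b1)
    return g + dt * rhs


def _g_generator(ep: EpigeneticParams, cp: CellularParams, dose: float, grid: Grid) -> NDArray:
    """Linear generator A of the trait-marginal flow.

    The marginal equation is linear up to its normalization term: with
    ``A = 2*P*diag(beta1)*dx - diag(beta1)`` the normalized solution is
    ``g(t) = normalize(expm(A t) @ g0)``, and the stationary marginal is
    the Perron eigenvector of A.
    """
    P, b1 = _g_ops(ep, cp, dose, grid)
    return 2.0 * P * (b1 * grid.dx)[None, :] - np.diag(b1)


def stationary_g(
    ep: EpigeneticParams,
    cp: CellularParams,
    dose: float = 0.0,
    grid: Grid | None = None,
    dt: float = 0.1,
    tol: float = 1e-10,
    max_iter: int = 200_000,
    method: str = "eig",
) -> NDArray:
    """Stationary trait marginal at a constant dose.

    ``method="eig"`` extracts the Perron eigenvector of the linear
    generator (exact for the discretized equation and much faster);
    ``method="iterate"`` runs the explicit stepper to its fixed point and
    serves as an independent cross-check in the tests.
    """
    if grid is None:
        grid = Grid()
    if method == "eig":
        A = _g_generator(ep, cp, dose, grid)
        vals, vecs = np.linalg.eig(A)
        lead = np.argmax(vals.real)
        g = np.real(vecs[:, lead])
        if g.sum() < 0.0:
            g = -g
        np.clip(g, 0.0, None, out=g)
        total = g.sum() * grid.dx
        if total <= 0.0:
            raise RuntimeError("degenerate stationary trait marginal")
        return g / total
    ops = _g_ops(ep, cp, dose, grid)
    g = np.full(grid.nx, 1.0)
    for _ in range(max_iter):
        g_new = step_g(g, ep, cp, dose, dt, grid, _ops=ops)
        np.clip(g_new, 0.0, None, out=g_new)
        g_new /= g_new.sum() * grid.dx
        if np.abs(g_new - g).sum() * grid.dx < tol * dt:
            return g_new
        g = g_new
    raise RuntimeError(
        f"trait marginal did not reach a stationary point at dose {dose}"
    )


def evolve_g(
    g: NDArray,
    ep: EpigeneticParams,
    cp: CellularParams,
    dose: float,
    duration: float,
    dt: float = 0.01,
    grid: Grid | None = None,
    method: str = "step",
) -> NDArray:
    """Advance the trait marginal for ``duration`` days at a fixed dose.

    ``method="expm"`` propagates with the matrix exponential of the linear
    generator and renormalizes (exact in time); ``method="step"`` uses the
    explicit Euler stepper shared with the coupled solver.
    """
    if grid is None:
        grid = Grid()
    if method == "expm":
        from scipy.linalg import expm

        out = expm(_g_generator(ep, cp, dose, grid) * duration) @ g
        np.clip(out, 0.0, None, out=out)
        return out / (out.sum() * grid.dx)
    ops = _g_ops(ep, cp, dose, grid)
    out = g.copy()
    for _ in range(int(round(duration / dt))):
        out = step_g(out, ep, cp, dose, dt, grid, _ops=ops)
    return out


def step_h(
    h: NDArray,
    g: NDArray,
    ep: EpigeneticParams,
    cp: CellularParams,
    dose: float,
    dt: float,
    grid: Grid,
    renormalize: bool = True,
) -> NDArray:
    """One step of the conditional phenotype densities for every trait node.

    Advection plus diffusion plus the relative-death term
    ``-h * (gamma - <gamma>)`` with the population mean death rate evaluated
    from the lagged ``h`` and ``g``.  Rows are renormalized afterwards
    (conditionals are densities by construction); rows whose marginal mass
    is below :data:`G_FLOOR` are left frozen.
    """
    dy = grid.dy
    if cp.sigma > 0.0 and dt > dy**2 / (2.0 * cp.sigma):
        raise RuntimeError(
            f"dt={dt} violates the diffusion stability bound "
            f"{dy ** 2 / (2.0 * cp.sigma):.4g}"
        )
    gamma_y = np.asarray(kernels.death_rate(grid.y, dose, cp))
    mean_gamma = float(
        (g[:, None] * h * gamma_y[None, :]).sum() * grid.dx * dy
    )

    v_if = np.zeros((grid.nx, grid.ny + 1))
    v_if[:, 1:-1] = kernels.adaptation_velocity(
        grid.x[:, None], grid.y_edges[None, 1:-1], dose, cp
    )
    vp = np.maximum(v_if[:, 1:-1], 0.0)
    vm = np.minimum(v_if[:, 1:-1], 0.0)
    F = vp * h[:, :-1] + vm * h[:, 1:]
    out = h.copy()
    out[:, :-1] -= dt / dy * F
    out[:, 1:] += dt / dy * F

    if cp.sigma > 0.0:
        lap = np.empty_like(out)
        lap[:, 1:-1] = out[:, 2:] - 2.0 * out[:, 1:-1] + out[:, :-2]
        lap[:, 0] = out[:, 1] - out[:, 0]
        lap[:, -1] = out[:, -2] - out[:, -1]
        out += dt * cp.sigma / dy**2 * lap

    out -= dt * out * (gamma_y[None, :] - mean_gamma)

    np.clip(out, 0.0, None, out=out)
    if renormalize:
        mass = out.sum(axis=1) * dy
        ok = (g > G_FLOOR) & (mass > 0.0)
        out[ok] /= mass[ok, None] * 1.0
        out[~ok] = h[~ok]
    return out


class SingleCellSolver:
    """Coupled integrator for the (g, h) pair under a dose schedule."""

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
        if cp.sigma > 0.0 and dt > grid.dy**2 / (2.0 * cp.sigma):
            raise RuntimeError(
                f"dt={dt} violates the diffusion stability bound "
                f"{grid.dy ** 2 / (2.0 * cp.sigma):.4g}"
            )
        self._g_cache: dict[float, tuple] = {}
        self._h_cache: dict[float, tuple] = {}

    def _ops(self, c: float):
        key = round(c, 12)
        if key not in self._g_cache:
            self._g_cache[key] = _g_ops(self.ep, self.cp, c, self.grid)
            g = self.grid
            v_if = np.zeros((g.nx, g.ny + 1))
            v_if[:, 1:-1] = kernels.adaptation_velocity(
                g.x[:, None], g.y_edges[None, 1:-1], c, self.cp
            )
            gamma_y = np.asarray(kernels.death_rate(g.y, c, self.cp))
            self._h_cache[key] = (v_if, gamma_y)
        return self._g_cache[key], self._h_cache[key]

    def step(self, ds: DensityState) -> DensityState:
        g_grid = self.grid
        dt = self.dt
        c = kernels.dose_at(self.schedule, ds.t)
        (P, b1), (v_if, gamma_y) = self._ops(c)

        # conditional phenotype densities (lagged mean-death coupling)
        h = ds.h
        mean_gamma = float(
            (ds.g[:, None] * h * gamma_y[None, :]).sum() * g_grid.dx * g_grid.dy
        )
        vp = np.maximum(v_if[:, 1:-1], 0.0)
        vm = np.minimum(v_if[:, 1:-1], 0.0)
        F = vp * h[:, :-1] + vm * h[:, 1:]
        h_new = h.copy()
        h_new[:, :-1] -= dt / g_grid.dy * F
        h_new[:, 1:] += dt / g_grid.dy * F
        if self.cp.sigma > 0.0:
            lap = np.empty_like(h_new)
            lap[:, 1:-1] = h_new[:, 2:] - 2.0 * h_new[:, 1:-1] + h_new[:, :-2]
            lap[:, 0] = h_new[:, 1] - h_new[:, 0]
            lap[:, -1] = h_new[:, -2] - h_new[:, -1]
            h_new += dt * self.cp.sigma / g_grid.dy**2 * lap
        h_new -= dt * h_new * (gamma_y[None, :] - mean_gamma)
        np.clip(h_new, 0.0, None, out=h_new)
        mass = h_new.sum(axis=1) * g_grid.dy
        ok = (ds.g > G_FLOOR) & (mass > 0.0)
        h_new[ok] /= mass[ok, None]
        h_new[~ok] = h[~ok]

        # trait marginal
        flux = b1 * ds.g
        mean_b1 = flux.sum() * g_grid.dx
        g_new = ds.g + dt * (
            2.0 * (P @ flux) * g_grid.dx - ds.g * (b1 + mean_b1)
        )
        np.clip(g_new, 0.0, None, out=g_new)

        return DensityState(g_new, h_new, ds.t + dt, g_grid)


def cell_type_probabilities(
    ds: DensityState,
    x_threshold: float = X_THRESHOLD,
    y_threshold: float = Y_THRESHOLD,
) -> tuple[float, float, float]:
    """(naive, persister, resistant) probabilities of the joint density."""
    grid = ds.grid
    f = ds.f
    w = grid.dx * grid.dy
    naive_mask = grid.y < y_threshold
    high_x = grid.x > x_threshold
    p_naive = f[:, naive_mask].sum() * w
    surv = f[:, ~naive_mask]
    p_dtp = surv[high_x, :].sum() * w
    p_res = surv[~high_x, :].sum() * w
    return float(p_naive), float(p_dtp), float(p_res)


def equilibrium_h(cp: CellularParams, grid: Grid) -> NDArray:
    """Drug-free stationary conditional phenotype profile per trait node."""
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
    return w


def initial_density(
    ep: EpigeneticParams, cp: CellularParams, grid: Grid | None = None
) -> DensityState:
    """Drug-free stationary (g, h) pair used as the treatment-start state."""
    if grid is None:
        grid = Grid()
    g = stationary_g(ep, cp, dose=0.0, grid=grid)
    return DensityState(g, equilibrium_h(cp, grid), 0.0, grid)


def simulate_singlecell(
    ep: EpigeneticParams,
    cp: CellularParams,
    schedule: DoseSchedule,
    t_end: float,
    dt: float = 0.01,
    record_every: float = 0.5,
    grid: Grid | None = None,
    init: DensityState | None = None,
) -> pd.DataFrame:
    """Run the density model and record cell-type probabilities over time."""
    if init is None:
        init = initial_density(ep, cp, grid)
    grid = init.grid
    solver = SingleCellSolver(ep, cp, grid, schedule, dt)
    ds = init.copy()
    ds.t = 0.0

    n_steps = int(round(t_end / dt))
    stride = max(1, int(round(record_every / dt)))
    rows = []

    def record(d: DensityState) -> None:
        pn, pd_, pr = cell_type_probabilities(d)
        rows.append((d.t, pn, pd_, pr))

    record(ds)
    for i in range(1, n_steps + 1):
        ds = solver.step(ds)
        if i % stride == 0 or i == n_steps:
            record(ds)
    out = pd.DataFrame(
        rows, columns=["t", "P_naive", "P_dtp", "P_resistant"]
    )
    out.attrs["final_state"] = ds
    return out


def survival_curve(
    x_fixed: float,
    ep: EpigeneticParams,
    cp: CellularParams,
    dose: float,
    t_end: float,
    dt: float = 0.01,
    ny: int = 100,
) -> pd.DataFrame:
    """Survival probability of a cell with a frozen trait value.

    Evolves the phenotype density at ``x_fixed`` under the absolute death
    rate (no mean-death correction); the surviving mass is the survival
    probability ``S(t)``, monotone nonincreasing from 1.
    """
    if not 0.0 < x_fixed < 1.0:
        raise ValueError(f"x_fixed must lie in (0, 1), got {x_fixed}")
    grid = Grid(nx=2, ny=ny)
    y = grid.y
    dy = grid.dy
    gamma_y = np.asarray(kernels.death_rate(y, dose, cp))
    v_if = np.zeros(ny + 1)
    v_if[1:-1] = kernels.adaptation_velocity(
        x_fixed, grid.y_edges[1:-1], dose, cp
    )
    if cp.sigma > 0.0 and dt > dy**2 / (2.0 * cp.sigma):
        raise RuntimeError("dt violates the diffusion stability bound")

    rho = np.exp(-0.5 * ((y - cp.y0_off) / 0.05) ** 2)
    rho /= rho.sum() * dy
    death = np.exp(-gamma_y * dt)
    vp = np.maximum(v_if[1:-1], 0.0)
    vm = np.minimum(v_if[1:-1], 0.0)

    n_steps = int(round(t_end / dt))
    ts = np.empty(n_steps + 1)
    S = np.empty(n_steps + 1)
    ts[0], S[0] = 0.0, 1.0
    for i in range(1, n_steps + 1):
        F = vp * rho[:-1] + vm * rho[1:]
        rho = rho.copy()
        rho[:-1] -= dt / dy * F
        rho[1:] += dt / dy * F
        if cp.sigma > 0.0:
            lap = np.empty_like(rho)
            lap[1:-1] = rho[2:] - 2.0 * rho[1:-1] + rho[:-2]
            lap[0] = rho[1] - rho[0]
            lap[-1] = rho[-2] - rho[-1]
            rho += dt * cp.sigma / dy**2 * lap
        rho *= death
        ts[i] = i * dt
        S[i] = rho.sum() * dy
    return pd.DataFrame({"t": ts, "S": S})
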