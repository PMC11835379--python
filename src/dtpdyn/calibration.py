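"""Synthetic data generation and parameter recovery.

Emulates the two experimental inputs the model was originally fitted to:
clone-level trait ("chance to persist") measurements with and without drug,
and relative tumor-volume kinetics with multiplicative observation noise.
The fitting routines invert those synthetic datasets with bounded
multi-start least squares, enabling end-to-end parameter-recovery tests
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import optimize

from .grid import Grid
from .params import CellularParams, DoseSchedule, EpigeneticParams
from .population import simulate
from .singlecell import evolve_g, stationary_g

__all__ = [
    "SyntheticCtpDataset",
    "SyntheticKineticsDataset",
    "CalibrationResult",
    "generate_ctp_dataset",
    "generate_kinetics_dataset",
    "ctp_histogram_loss",
    "fit_epigenetic_params",
    "fit_cellular_params",
    "sensitivity_oat",
]

N_BINS = 20  # equal-width histogram bins on (0, 1) for trait fitting


@dataclass
class SyntheticCtpDataset:
    """Per-clone trait values for the control and drug-treated arms."""

    control_ctps: NDArray
    treated_ctps: NDArray
    seed: int
    dose: float = 0.9
    duration: float = 7.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": np.arange(
                    self.control_ctps.size + self.treated_ctps.size
                ),
                "ctp": np.concatenate([self.control_ctps, self.treated_ctps]),
                "arm": ["control"] * self.control_ctps.size
                + ["treated"] * self.treated_ctps.size,
            }
        )


@dataclass
class SyntheticKineticsDataset:
    """Relative tumor-volume time series for the vehicle and treated arms."""

    times: NDArray
    vehicle_rel_volume: NDArray
    treated_rel_volume: NDArray
    noise_sd: float
    seed: int
    dose: float = 0.3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.concatenate([self.times, self.times]),
                "arm": ["vehicle"] * self.times.size
                + ["treated"] * self.times.size,
                "rel_volume": np.concatenate(
                    [self.vehicle_rel_volume, self.treated_rel_volume]
                ),
            }
        )


@dataclass
class CalibrationResult:
    """Best fit of a bounded multi-start optimization."""

    params: dict[str, float]
    loss: float
    converged: bool
    extras: dict[str, float] = field(default_factory=dict)


def _sample_from_marginal(
    g: NDArray, grid: Grid, n: int, rng: np.random.Generator
) -> NDArray:
    """Draw trait values from a grid marginal, jittered within cells."""
    p = np.clip(g, 0.0, None)
    p = p / p.sum()
    idx = rng.choice(grid.nx, size=n, p=p)
    x = grid.x[idx] + (rng.random(n) - 0.5) * grid.dx
    return np.clip(x, 1e-9, 1.0 - 1e-9)


def generate_ctp_dataset(
    ep_true: EpigeneticParams,
    cp_true: CellularParams,
    n_control: int = 544,
    n_treated: int = 392,
    seed: int = 0,
    dose: float = 0.9,
    duration: float = 7.0,
    grid: Grid | None = None,
) -> SyntheticCtpDataset:
    """Clone traits from the stationary drug-free marginal (control) and
    from the marginal after ``duration`` days at ``dose`` (treated)."""
    if grid is None:
        grid = Grid()
    rng = np.random.default_rng(seed)
    g0 = stationary_g(ep_true, cp_true, dose=0.0, grid=grid)
    g1 = evolve_g(g0, ep_true, cp_true, dose, duration, grid=grid)
    control = _sample_from_marginal(g0, grid, n_control, rng)
    treated = _sample_from_marginal(g1, grid, n_treated, rng)
    return SyntheticCtpDataset(control, treated, seed, dose, duration)


def generate_kinetics_dataset(
    ep_true: EpigeneticParams,
    cp_true: CellularParams,
    dose: float,
    times,
    noise_sd: float = 0.1,
    seed: int = 0,
    grid: Grid | None = None,
    dt: float = 0.01,
    mass_frac: float = 0.08,
) -> SyntheticKineticsDataset:
    """Vehicle and treated relative-volume series with lognormal noise."""
    times = np.asarray(list(times), dtype=float)
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    t_end = float(times[-1])
    series = {}
    for arm, c in (("vehicle", 0.0), ("treated", dose)):
        traj = simulate(
            ep_true,
            cp_true,
            DoseSchedule.constant(c),
            t_end,
            dt=dt,
            record_every=dt,
            grid=grid,
            mass_frac=mass_frac,
        )
        rel = np.interp(times, traj.t, traj.rel_size)
        if noise_sd > 0.0:
            rel = rel * np.exp(rng.normal(0.0, noise_sd, size=rel.size))
        rel = rel / rel[0]
        series[arm] = rel
    return SyntheticKineticsDataset(
        times, series["vehicle"], series["treated"], noise_sd, seed, dose
    )


# ---------------------------------------------------------------------------
# epigenetic-scale fit: binned trait histograms against the model marginal
# ---------------------------------------------------------------------------

_EP_FIT_KEYS = ("phi0", "phi1", "alpha0", "k", "n", "eta0")
_EP_DEFAULT_BOUNDS = {
    "phi0": (0.01, 0.3),
    "phi1": (0.05, 0.8),
    "alpha0": (0.2, 5.0),
    "k": (1.0, 30.0),
    "n": (1.0, 6.0),
    "eta0": (5.0, 100.0),
}


def _hist_density(x: NDArray, n_bins: int = N_BINS) -> NDArray:
    hist, _ = np.histogram(x, bins=n_bins, range=(0.0, 1.0), density=True)
    return hist


def _marginal_to_hist(g: NDArray, grid: Grid, n_bins: int = N_BINS) -> NDArray:
    """Aggregate a grid marginal into equal-width bin densities."""
    if grid.nx % n_bins != 0:
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        idx = np.clip(np.digitize(grid.x, edges) - 1, 0, n_bins - 1)
        out = np.zeros(n_bins)
        np.add.at(out, idx, g * grid.dx)
        return out * n_bins
    per = grid.nx // n_bins
    return g.reshape(n_bins, per).mean(axis=1)


def ctp_histogram_loss(
    theta: dict[str, float],
    data: SyntheticCtpDataset,
    cp_fixed: CellularParams,
    grid: Grid,
) -> float:
    """Sum of squared histogram differences over both arms."""
    if theta["phi0"] + theta["phi1"] >= 0.99:
        return 1e6
    try:
        ep = EpigeneticParams(**theta)
    except ValueError:
        return 1e6
    g0 = stationary_g(ep, cp_fixed, dose=0.0, grid=grid)
    g1 = evolve_g(
        g0, ep, cp_fixed, data.dose, data.duration, grid=grid, method="expm"
    )
    loss = float(
        np.sum((_marginal_to_hist(g0, grid) - _hist_density(data.control_ctps)) ** 2)
        + np.sum((_marginal_to_hist(g1, grid) - _hist_density(data.treated_ctps)) ** 2)
    )
    return loss


def fit_epigenetic_params(
    data: SyntheticCtpDataset,
    cp_fixed: CellularParams,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_starts: int = 8,
    grid: Grid | None = None,
    maxiter: int = 120,
) -> CalibrationResult:
    """Recover the inheritance-kernel parameters from clone histograms.

    Bounded multi-start Nelder-Mead on the binned-histogram least-squares
    loss; the best of ``n_starts`` seeded starts is returned.
    """
    if data.control_ctps.size == 0 or data.treated_ctps.size == 0:
        raise ValueError("both arms must be nonempty")
    if grid is None:
        grid = Grid(nx=100, ny=2)
    bnds = dict(_EP_DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[k][0] for k in _EP_FIT_KEYS])
    hi = np.array([bnds[k][1] for k in _EP_FIT_KEYS])
    rng = np.random.default_rng(seed)

    def loss_vec(v: NDArray) -> float:
        theta = dict(zip(_EP_FIT_KEYS, v))
        return ctp_histogram_loss(theta, data, cp_fixed, grid)

    best = None
    for s in range(n_starts):
        x0 = lo + (hi - lo) * (
            0.5 * np.ones(lo.size) if s == 0 else rng.random(lo.size)
        )
        res = optimize.minimize(
            loss_vec,
            x0,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxiter": maxiter * lo.size, "xatol": 1e-4, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = dict(zip(_EP_FIT_KEYS, (float(v) for v in best.x)))
    return CalibrationResult(params, float(best.fun), bool(best.success))


# ---------------------------------------------------------------------------
# cellular-scale fit: relative-volume trajectories of both arms
# ---------------------------------------------------------------------------

_CP_FIT_KEYS = ("beta0", "gamma0", "beta10", "a1", "a2", "a3")
_CP_DEFAULT_BOUNDS = {
    "beta0": (0.01, 0.5),
    "gamma0": (0.005, 0.3),
    "beta10": (0.05, 1.5),
    "a1": (1.0, 30.0),
    "a2": (0.2, 5.0),
    "a3": (2.0, 30.0),
}


def _kinetics_residuals(
    v: NDArray,
    data: SyntheticKineticsDataset,
    ep_fixed: EpigeneticParams,
    base_cp: CellularParams,
    grid: Grid,
    dt: float,
    mass_frac: float,
) -> NDArray:
    theta = dict(zip(_CP_FIT_KEYS, v))
    try:
        cp = replace(base_cp, **theta)
    except ValueError:
        return np.full(2 * data.times.size, 1e3)
    t_end = float(data.times[-1])
    res = []
    try:
        for arm, c, obs in (
            ("vehicle", 0.0, data.vehicle_rel_volume),
            ("treated", data.dose, data.treated_rel_volume),
        ):
            traj = simulate(
                ep_fixed,
                cp,
                DoseSchedule.constant(c),
                t_end,
                dt=dt,
                record_every=max(dt, 1.0),
                grid=grid,
                mass_frac=mass_frac,
            )
            pred = np.interp(data.times, traj.t, traj.rel_size)
            res.append(np.log(np.clip(pred, 1e-9, None)) - np.log(obs))
    except (FloatingPointError, RuntimeError):
        return np.full(2 * data.times.size, 1e3)
    return np.concatenate(res)


def fit_cellular_params(
    data: SyntheticKineticsDataset,
    ep_fixed: EpigeneticParams,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_starts: int = 3,
    grid: Grid | None = None,
    dt: float = 0.04,
    base_cp: CellularParams | None = None,
    mass_frac: float = 0.08,
    max_nfev: int = 60,
) -> CalibrationResult:
    """Recover proliferation/death constants from volume kinetics.

    Bounded multi-start trust-region least squares on log relative volumes
    of both arms jointly.  The per-arm Pearson correlation between fit and
    data is reported as the goodness metric.
    """
    if grid is None:
        grid = Grid(nx=24, ny=24)
    if base_cp is None:
        base_cp = CellularParams()
    bnds = dict(_CP_DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[k][0] for k in _CP_FIT_KEYS])
    hi = np.array([bnds[k][1] for k in _CP_FIT_KEYS])
    rng = np.random.default_rng(seed)

    args = (data, ep_fixed, base_cp, grid, dt, mass_frac)
    best = None
    for s in range(n_starts):
        x0 = lo + (hi - lo) * (
            0.5 * np.ones(lo.size) if s == 0 else rng.random(lo.size)
        )
        try:
            res = optimize.least_squares(
                _kinetics_residuals,
                x0,
                bounds=(lo, hi),
                args=args,
                max_nfev=max_nfev,
                diff_step=1e-3,
            )
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return CalibrationResult({}, np.inf, False)

    params = dict(zip(_CP_FIT_KEYS, (float(v) for v in best.x)))
    resid = _kinetics_residuals(best.x, *args)
    n = data.times.size
    extras = {}
    for arm, obs, r in (
        ("vehicle", data.vehicle_rel_volume, resid[:n]),
        ("treated", data.treated_rel_volume, resid[n:]),
    ):
        pred = np.exp(r + np.log(obs))
        if np.std(pred) > 0 and np.std(obs) > 0:
            extras[f"R_{arm}"] = float(np.corrcoef(pred, obs)[0, 1])
        else:
            extras[f"R_{arm}"] = np.nan
    return CalibrationResult(
        params, float(best.cost), bool(best.status > 0), extras
    )


def sensitivity_oat(
    param_names,
    ep: EpigeneticParams,
    cp: CellularParams,
    dose: float = 0.9,
    perturbation: float = 0.2,
    t_end: float = 60.0,
    dt: float = 0.02,
    grid: Grid | None = None,
) -> pd.DataFrame:
    """One-at-a-time sensitivity of day-``t_end`` size and final resistant
    probability to a ±``perturbation`` relative change of each parameter.

    The baseline initial state is built once from the unperturbed parameters
    and shared by every run, so the table reflects the dynamics only.
    """
    from .population import stationary_init
    from .singlecell import initial_density, simulate_singlecell

    if grid is None:
        grid = Grid(nx=50, ny=50)
    schedule = DoseSchedule.constant(dose)
    state0 = stationary_init(ep, cp, grid)
    density0 = initial_density(ep, cp, grid)

    def outputs(ep_i: EpigeneticParams, cp_i: CellularParams):
        traj = simulate(
            ep_i, cp_i, schedule, t_end, dt=dt, grid=grid, state=state0
        )
        probs = simulate_singlecell(
            ep_i, cp_i, schedule, t_end, dt=dt, grid=grid, init=density0
        )
        return float(traj.rel_size[-1]), float(probs["P_resistant"].iloc[-1])

    base_q, base_p = outputs(ep, cp)
    rows = []
    for name in param_names:
        if hasattr(ep, name):
            target, other, is_ep = ep, cp, True
        elif hasattr(cp, name):
            target, other, is_ep = cp, ep, False
        else:
            raise KeyError(f"unknown parameter {name!r}")
        rel = {}
        for sign, tag in ((-1.0, "minus"), (1.0, "plus")):
            value = getattr(target, name) * (1.0 + sign * perturbation)
            try:
                perturbed = replace(target, **{name: value})
            except ValueError:
                rel[f"dQ_{tag}"] = np.nan
                rel[f"dPres_{tag}"] = np.nan
                continue
            ep_i = perturbed if is_ep else other
            cp_i = other if is_ep else perturbed
            q, p = outputs(ep_i, cp_i)
            rel[f"dQ_{tag}"] = (q - base_q) / base_q
            rel[f"dPres_{tag}"] = (p - base_p) / max(base_p, 1e-12)
        rows.append({"param": name, **rel})
    return pd.DataFrame(rows)
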