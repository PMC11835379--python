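"""Pure rate and kernel functions shared by every solver.

Everything here is a stateless function of parameters and scalar/array
inputs; the PDE, density, and agent solvers all call into this module so the
model is defined in exactly one place.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import stats

from .params import CellularParams, DoseSchedule, EpigeneticParams

__all__ = [
    "dose_at",
    "alpha_of_dose",
    "phi",
    "shape_params",
    "inheritance_density",
    "sample_daughter_ctp",
    "beta1",
    "beta_rate",
    "adaptation_velocity",
    "death_rate",
    "inheritance_matrix",
]

#: doses at or below this are treated as exactly drug free (the adaptation
#: drift is defined piecewise and discontinuous at c = 0)
ZERO_DOSE = 1e-12


def dose_at(schedule: DoseSchedule, t: float) -> float:
    """Dose c(t) of a schedule at time ``t`` (days).

    Constant mode returns ``c_const`` for ``t >= t0`` and 0 before.
    Intermittent mode returns ``c_on`` during the first ``tau_on`` days of
    each cycle after ``t0`` and ``c_off`` otherwise, on half-open intervals.
    """
    if t < 0.0:
        raise ValueError(f"time must be nonnegative, got {t}")
    if t < schedule.t0:
        return 0.0
    if schedule.mode == "constant":
        return schedule.c_const
    period = schedule.period
    if schedule.tau_off == 0.0:
        return schedule.c_on
    s = (t - schedule.t0) % period
    return schedule.c_on if s < schedule.tau_on else schedule.c_off


def alpha_of_dose(ep: EpigeneticParams, c: float) -> float:
    """Selection strength ``alpha = alpha0 + k*c``; increasing in the dose."""
    return ep.alpha0 + ep.k * c


def phi(z: ArrayLike, alpha: float, ep: EpigeneticParams) -> NDArray | float:
    """Expected daughter trait given mother trait ``z``.

    A Hill function ``phi0 + phi1*(alpha*z)^n / (1 + (alpha*z)^n)`` with
    values strictly inside ``(phi0, phi0 + phi1)``, nondecreasing in both
    ``z`` and ``alpha``.
    """
    az = np.asarray(alpha * np.asarray(z, dtype=float)) ** ep.n
    out = ep.phi0 + ep.phi1 * az / (1.0 + az)
    return out if out.ndim else float(out)


def shape_params(
    z: ArrayLike, alpha: float, ep: EpigeneticParams
) -> tuple[NDArray | float, NDArray | float]:
    """Beta shape parameters ``(a, b) = (eta0*phi, eta0*(1 - phi))``.

    Both are positive and sum to ``eta0``, so the Beta mean is ``phi(z)``
    and the variance is ``phi*(1 - phi)/(1 + eta0)``.
    """
    m = np.asarray(phi(z, alpha, ep))
    a = ep.eta0 * m
    b = ep.eta0 * (1.0 - m)
    if a.ndim == 0:
        return float(a), float(b)
    return a, b


def inheritance_density(
    x: ArrayLike, z: ArrayLike, alpha: float, ep: EpigeneticParams
) -> NDArray | float:
    """Beta density of the daughter trait ``x`` given the mother trait ``z``.

    Zero outside the open interval (0, 1) by convention; solvers only ever
    evaluate it on interior cell-centered nodes.
    """
    a, b = shape_params(z, alpha, ep)
    x = np.asarray(x, dtype=float)
    out = np.where(
        (x > 0.0) & (x < 1.0), stats.beta.pdf(np.clip(x, 1e-300, 1.0), a, b), 0.0
    )
    return out if out.ndim else float(out)


def sample_daughter_ctp(
    z: ArrayLike,
    alpha: float,
    ep: EpigeneticParams,
    rng: np.random.Generator,
) -> NDArray | float:
    """Draw daughter traits from the inheritance Beta distribution."""
    a, b = shape_params(z, alpha, ep)
    out = rng.beta(a, b)
    return out


def beta1(x: ArrayLike, cp: CellularParams) -> NDArray | float:
    """Trait-dependent proliferation-entry rate (per day)."""
    x = np.asarray(x, dtype=float)
    out = cp.beta0 + cp.beta10 * (cp.a1 * x + (cp.a2 * x) ** 6) / (
        1.0 + (cp.a3 * x) ** 6
    )
    return out if out.ndim else float(out)


def beta_rate(
    x: ArrayLike, Q_hat: float, cp: CellularParams
) -> NDArray | float:
    """Effective proliferation-entry rate with logistic crowding.

    ``beta1(x) * (1 - Q_hat/K)``, clamped at zero when the population
    transiently overshoots the carrying capacity (entry into proliferation
    is a nonnegative rate).
    """
    factor = max(0.0, 1.0 - Q_hat / cp.K)
    out = np.asarray(beta1(x, cp)) * factor
    return out if out.ndim else float(out)


def adaptation_velocity(
    x: ArrayLike, y: ArrayLike, c: float, cp: CellularParams
) -> NDArray | float:
    """Stress-adaptation drift of the phenotype ``y`` (per day).

    With drug present the phenotype relaxes toward ``y0_on`` at speed
    ``v0*x*c``; drug free it relaxes toward ``y0_off`` at speed ``v0*x``.
    The drift vanishes at the equilibrium and at ``x = 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if c > ZERO_DOSE:
        out = cp.v0 * x * c * (cp.y0_on - y)
    else:
        out = cp.v0 * x * (cp.y0_off - y)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def death_rate(y: ArrayLike, c: float, cp: CellularParams) -> NDArray | float:
    """Apoptosis rate ``gamma0 + gamma1*c*H(y_star - y)`` (per day).

    The drug-induced term only applies below the phenotype threshold; the
    Heaviside step uses H(0) = 0, so cells sitting exactly at the threshold
    join the surviving side.
    """
    y = np.asarray(y, dtype=float)
    out = cp.gamma0 + cp.gamma1 * c * (y < cp.y_star)
    return out if out.ndim else float(out)


def inheritance_matrix(
    x_nodes: NDArray,
    alpha: float,
    ep: EpigeneticParams,
    dx: float | None = None,
    renormalize: bool = True,
) -> NDArray:
    """Discretized inheritance kernel ``P[i, l] = p(x_i, z_l)``.

    Columns (fixed mother trait ``z_l``) are renormalized so that
    ``sum_i P[i, l] * dx == 1`` exactly, which makes the discrete mitosis
    operator conserve cell number to machine precision.
    """
    x = np.asarray(x_nodes, dtype=float)
    if dx is None:
        dx = float(x[1] - x[0])
    m = np.asarray(phi(x, alpha, ep))
    a = ep.eta0 * m
    b = ep.eta0 * (1.0 - m)
    P = stats.beta.pdf(x[:, None], a[None, :], b[None, :])
    if renormalize:
        col = P.sum(axis=0) * dx
        if np.any(col <= 0.0):
            raise FloatingPointError("inheritance kernel column underflow")
        P = P / col[None, :]
    return P
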