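"""Parameter containers, dose schedules, and flat key-value configuration I/O.

All quantities are dimensionless or expressed per day.  The default values
shipped here are *calibrated stand-ins*: they were obtained by fitting the
model to the qualitative and quantitative behavior it is expected to
reproduce (low-trait control distribution, treatment nadir/recovery/plateau
kinetics, intermittent-schedule response) and are exposed through a flat
YAML config so they can be overridden per run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "EpigeneticParams",
    "CellularParams",
    "DoseSchedule",
    "DEFAULT_CONFIG",
    "load_config",
    "epigenetic_from_config",
    "cellular_from_config",
    "schedule_from_config",
]


@dataclass(frozen=True)
class EpigeneticParams:
    """Parameters of the Beta-distributed trait-inheritance kernel.

    The heritable trait ``x`` of each daughter cell is drawn from a Beta
    distribution whose mean ``phi(z)`` is a Hill function of the mother's
    trait ``z`` scaled by the selection strength ``alpha = alpha0 + k*c``.
    ``eta0`` is the inverse noise: both Beta shape parameters sum to
    ``eta0``, so large ``eta0`` means faithful inheritance.
    """

    phi0: float = 0.11
    phi1: float = 0.45
    alpha0: float = 1.0
    k: float = 3.5
    n: float = 2.0
    eta0: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 < self.phi0:
            raise ValueError(f"phi0 must be positive, got {self.phi0}")
        if not self.phi0 + self.phi1 < 1.0:
            raise ValueError(
                f"phi0 + phi1 must be < 1, got {self.phi0 + self.phi1}"
            )
        if self.phi1 < 0.0:
            raise ValueError(f"phi1 must be nonnegative, got {self.phi1}")
        if self.alpha0 <= 0.0:
            raise ValueError(f"alpha0 must be > 0, got {self.alpha0}")
        if self.k <= 0.0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.eta0 <= 0.0:
            raise ValueError(f"eta0 must be > 0, got {self.eta0}")

    def with_(self, **kwargs: float) -> "EpigeneticParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CellularParams:
    """Rate and flux constants of the population model.

    ``beta0 + beta10*(a1*x + (a2*x)**6)/(1 + (a3*x)**6)`` is the trait-
    dependent rate of re-entry into proliferation; the logistic factor
    ``1 - Q_hat/K`` throttles it near the carrying capacity.  ``gamma0`` and
    ``gamma1`` are the natural and drug-induced death rates; the drug only
    kills cells with phenotype ``y < y_star``.  ``v0`` sets the speed of
    stress-driven phenotype adaptation toward ``y0_on`` (drug present) or
    ``y0_off`` (drug free); ``sigma`` is the phenotype diffusion magnitude.
    """

    beta0: float = 0.06
    beta10: float = 0.45
    a1: float = 11.0
    a2: float = 1.0
    a3: float = 8.0
    K: float = 1.0
    gamma0: float = 0.065
    gamma1: float = 1.20
    y_star: float = 0.5
    v0: float = 1.0
    sigma: float = 0.0008
    y0_on: float = 0.8
    y0_off: float = 0.2

    def __post_init__(self) -> None:
        for name in ("beta0", "beta10", "gamma0", "gamma1", "v0", "sigma"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be nonnegative")
        if self.K <= 0.0:
            raise ValueError(f"K must be > 0, got {self.K}")
        for name in ("y_star", "y0_on", "y0_off"):
            val = getattr(self, name)
            if not 0.0 < val < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {val}")

    def with_(self, **kwargs: float) -> "CellularParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DoseSchedule:
    """Dose profile c(t): constant after ``t0``, or periodic on/off cycles.

    In intermittent mode each cycle of length ``tau_on + tau_off`` starts
    with ``tau_on`` days at ``c_on`` followed by ``tau_off`` days at
    ``c_off``; intervals are half-open ``[on_start, off_start)``.
    """

    mode: str = "constant"
    c_const: float = 0.0
    tau_on: float = 7.0
    tau_off: float = 7.0
    c_on: float = 0.9
    c_off: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "intermittent"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        for name in ("c_const", "c_on", "c_off"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.mode == "intermittent":
            if self.tau_on <= 0.0:
                raise ValueError(f"tau_on must be > 0, got {self.tau_on}")
            if self.tau_off < 0.0:
                raise ValueError(f"tau_off must be >= 0, got {self.tau_off}")

    @classmethod
    def constant(cls, c: float, t0: float = 0.0) -> "DoseSchedule":
        return cls(mode="constant", c_const=c, t0=t0)

    @classmethod
    def intermittent(
        cls,
        tau_on: float,
        tau_off: float,
        c_on: float = 0.9,
        c_off: float = 0.0,
        t0: float = 0.0,
    ) -> "DoseSchedule":
        return cls(
            mode="intermittent",
            tau_on=tau_on,
            tau_off=tau_off,
            c_on=c_on,
            c_off=c_off,
            t0=t0,
        )

    @property
    def period(self) -> float:
        return self.tau_on + self.tau_off

    @property
    def max_dose(self) -> float:
        if self.mode == "constant":
            return self.c_const
        return max(self.c_on, self.c_off)


# Flat key-value defaults (symbol names match the dataclass fields).  The
# extra keys configure numerics and the initial condition of the solvers.
DEFAULT_CONFIG: dict[str, Any] = {
    # epigenetic scale
    **asdict(EpigeneticParams()),
    # cellular scale
    **asdict(CellularParams()),
    # schedule
    "mode": "constant",
    "c_const": 0.3,
    "tau_on": 7.0,
    "tau_off": 7.0,
    "c_on": 0.9,
    "c_off": 0.0,
    "t0": 0.0,
    # numerics / initial condition
    "nx": 100,
    "ny": 100,
    "dt": 0.01,
    "q0_frac": 0.08,       # initial total size as a fraction of K
    "init_x": 0.05,        # center of the start-up trait bump
    "init_y": 0.2,         # center of the start-up phenotype bump
    "init_width": 0.05,    # bump standard deviation
    "preheat_tol": 1e-3,   # L1 drift of the trait marginal per day
}

_EP_KEYS = tuple(asdict(EpigeneticParams()))
_CP_KEYS = tuple(asdict(CellularParams()))
_SCHED_KEYS = ("mode", "c_const", "tau_on", "tau_off", "c_on", "c_off", "t0")


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Read a flat YAML/JSON config, filling unspecified keys with defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ValueError(f"config {path} must be a flat mapping")
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def epigenetic_from_config(cfg: Mapping[str, Any]) -> EpigeneticParams:
    return EpigeneticParams(**{k: float(cfg[k]) for k in _EP_KEYS})


def cellular_from_config(cfg: Mapping[str, Any]) -> CellularParams:
    return CellularParams(**{k: float(cfg[k]) for k in _CP_KEYS})


def schedule_from_config(cfg: Mapping[str, Any]) -> DoseSchedule:
    kwargs = {k: cfg[k] for k in _SCHED_KEYS}
    mode = kwargs.pop("mode")
    return DoseSchedule(
        mode=str(mode), **{k: float(v) for k, v in kwargs.items()}
    )
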