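"""Cell-centered unit-square grid shared by the density solvers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

__all__ = ["Grid"]


@dataclass(frozen=True)
class Grid:
    """Cell-centered discretization of the (trait, phenotype) unit square.

    Nodes sit at ``x_i = (i + 0.5)/nx`` and ``y_j = (j + 0.5)/ny`` so they
    are strictly interior; with even ``nx``/``ny`` no node coincides with a
    classification threshold (0.15 or 0.5).
    """

    nx: int = 100
    ny: int = 100
    x: NDArray = field(init=False, repr=False, compare=False)
    y: NDArray = field(init=False, repr=False, compare=False)
    y_edges: NDArray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs at least 2 nodes per axis")
        object.__setattr__(
            self, "x", (np.arange(self.nx) + 0.5) / self.nx
        )
        object.__setattr__(
            self, "y", (np.arange(self.ny) + 0.5) / self.ny
        )
        object.__setattr__(
            self, "y_edges", np.arange(self.ny + 1) / self.ny
        )

    @property
    def dx(self) -> float:
        return 1.0 / self.nx

    @property
    def dy(self) -> float:
        return 1.0 / self.ny
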