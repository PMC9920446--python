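"""Shared in-memory containers for the planar-MIT inversion chain.

Conventions
-----------
All quantities are SI.  The conducting sheet lives in the plane ``z = 0`` of
the body frame; the undulator excitation plane sits at ``z = -z_exciter`` and
the receiver plane at ``z = +z_receiver``.  The body travels in ``x``; at scan
position ``x_s`` a body-frame point ``x`` is at laboratory position
``x + x_s``.

Grid indexing: a ``ConductivityGrid`` with ``nx x ny`` pixels stores
``values[ix, iy]`` where ``ix`` counts cells in ``x`` and ``iy`` in ``y``.
Pixel centers are at ``origin + (i + 0.5) * cell_size``.  Lattice nodes sit at
pixel corners.  Edge currents are stored on the two directed edge families:

* x-edges ``ix_currents[i, j]`` — from node ``(i, j)`` to ``(i+1, j)``;
  shape ``(nx, ny+1)``; the edge borders pixels ``(i, j-1)`` and ``(i, j)``.
* y-edges ``iy_currents[i, j]`` — from node ``(i, j)`` to ``(i, j+1)``;
  shape ``(nx+1, ny)``; the edge borders pixels ``(i-1, j)`` and ``(i, j)``.

Positive current flows in the +x / +y edge direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ConductivityGrid",
    "CurrentField",
    "MomentField",
    "ScanSignal",
    "FieldMap",
]


@dataclass
class ConductivityGrid:
    """2D conductivity map of a thin sheet.

    Parameters
    ----------
    values : ndarray, shape (nx, ny)
        Pixel conductivities in S/m, all >= 0.
    cell_size : float
        Square pixel edge length in m.
    origin : tuple of float
        Body-frame (x, y) of the grid's lower-left corner in m.
    thickness : float
        Effective sheet thickness in m; enters only as a global conductance
        scale in 2D.
    """

    values: np.ndarray
    cell_size: float = 0.02
    origin: tuple[float, float] = (-0.2, -0.2)
    thickness: float = 0.01

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("conductivity values must be a 2D array")
        if np.any(self.values < 0):
            raise ValueError("conductivities must be non-negative")
        if self.cell_size <= 0 or self.thickness <= 0:
            raise ValueError("cell_size and thickness must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Body-frame x and y coordinates of pixel centers (1D arrays)."""
        nx, ny = self.shape
        h = self.cell_size
        x = self.origin[0] + (np.arange(nx) + 0.5) * h
        y = self.origin[1] + (np.arange(ny) + 0.5) * h
        return x, y

    def copy(self) -> "ConductivityGrid":
        return replace(self, values=self.values.copy())


@dataclass
class CurrentField:
    """Edge currents of the discretized eddy-current field.

    ``ix`` holds currents of x-directed edges, ``iy`` of y-directed edges
    (see module docstring for the layout).  ``basis`` labels the excitation
    phase: "phi" (body centered on a stripe), "psi" (quarter period off), or
    e.g. "scan" for a general position.
    """

    ix: np.ndarray
    iy: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (-0.2, -0.2)
    basis: str = ""

    def __post_init__(self) -> None:
        self.ix = np.asarray(self.ix, dtype=float)
        self.iy = np.asarray(self.iy, dtype=float)
        nx, nyp = self.ix.shape
        nxp, ny = self.iy.shape
        if nyp != ny + 1 or nxp != nx + 1:
            raise ValueError(
                f"inconsistent edge array shapes {self.ix.shape} / {self.iy.shape}"
            )

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.ix.shape[0], self.iy.shape[1]

    def node_divergence(self) -> np.ndarray:
        """Signed current outflow at every lattice node, shape (nx+1, ny+1).

        Zero (to solver tolerance) for a physical eddy field — the Kirchhoff
        node rule.
        """
        nx, ny = self.grid_shape
        div = np.zeros((nx + 1, ny + 1))
        # x-edges: out of node (i, j), into node (i+1, j)
        div[:-1, :] += self.ix
        div[1:, :] -= self.ix
        # y-edges: out of node (i, j), into node (i, j+1)
        div[:, :-1] += self.iy
        div[:, 1:] -= self.iy
        return div

    def max_abs(self) -> float:
        return max(np.max(np.abs(self.ix), initial=0.0),
                   np.max(np.abs(self.iy), initial=0.0))

    def __add__(self, other: "CurrentField") -> "CurrentField":
        if self.grid_shape != other.grid_shape:
            raise ValueError("cannot add current fields on different grids")
        return CurrentField(self.ix + other.ix, self.iy + other.iy,
                            self.cell_size, self.origin, self.basis)

    def __mul__(self, a: float) -> "CurrentField":
        return CurrentField(self.ix * a, self.iy * a, self.cell_size,
                            self.origin, self.basis)

    __rmul__ = __mul__


@dataclass
class MomentField:
    """Per-pixel z-directed magnetic dipole moments (A m^2), zero outside."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (-0.2, -0.2)
    basis: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("moment values must be a 2D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.shape
        h = self.cell_size
        x = self.origin[0] + (np.arange(nx) + 0.5) * h
        y = self.origin[1] + (np.arange(ny) + 0.5) * h
        return x, y


@dataclass
class ScanSignal:
    """Per-receiver signal traces over the scan positions.

    ``total`` is the measurable signal S; ``phi`` / ``psi`` are its carrier
    components when known (forward simulation or after splitting), each of
    shape ``(n_receivers, n_scan)``.
    """

    x_s: np.ndarray
    total: np.ndarray
    phi: Optional[np.ndarray] = None
    psi: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x_s = np.asarray(self.x_s, dtype=float)
        self.total = np.atleast_2d(np.asarray(self.total, dtype=float))
        for name in ("phi", "psi"):
            v = getattr(self, name)
            if v is not None:
                v = np.atleast_2d(np.asarray(v, dtype=float))
                if v.shape != self.total.shape:
                    raise ValueError(f"{name} component shape mismatch")
                setattr(self, name, v)

    @property
    def n_receivers(self) -> int:
        return self.total.shape[0]

    @property
    def n_scan(self) -> int:
        return self.total.shape[1]

    def stacked(self, component: str = "total") -> np.ndarray:
        """Receiver-major 1D stacking of a component (length R * n_scan)."""
        arr = getattr(self, component)
        if arr is None:
            raise ValueError(f"component {component!r} not available")
        return arr.reshape(-1)

    def __sub__(self, other: "ScanSignal") -> "ScanSignal":
        if self.total.shape != other.total.shape:
            raise ValueError("signal shape mismatch")

        def diff(a, b):
            return a - b if (a is not None and b is not None) else None

        return ScanSignal(self.x_s, self.total - other.total,
                          diff(self.phi, other.phi), diff(self.psi, other.psi))


@dataclass
class FieldMap:
    """Vector field samples on a set of points.

    ``points`` has shape (N, 3); ``values`` has shape (N, 3) or
    (n_receivers, N, 3) for per-receiver fields.
    """

    points: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (N, 3)")
        if self.values.shape[-2:] != self.points.shape:
            raise ValueError("values must end with shape (N, 3)")
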