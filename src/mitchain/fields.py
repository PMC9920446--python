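"""Scanner geometry and the fixed excitation / receiver adjoint fields.

The planar scanner projects a spatially periodic excitation field from an
undulator plane below the sheet; simple straight-segment receivers above the
sheet pick up the secondary field of the eddy currents.  Under weak coupling
both field maps are fixed: the excitation vector potential A_E drives the
edge EMFs of the resistor network, and the receiver adjoint fields A_R / B_R
weight the eddy currents into signals via the reciprocity theorem.

In ideal mode the undulator field at height z above the plane is

    A_E,y(x, z) = cos(2*pi*x / D) * exp(-2*pi*z / D)

with D the undulator period (the sheet spans 2.5 periods by default).  The
"stripes" mode superposes the 2D fields of N parallel wires with alternating
current at spacing D/2, which converges to the ideal mode away from the
array edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
from typing import Sequence

import numpy as np
from scipy.constants import mu_0

from .containers import FieldMap

__all__ = [
    "ReceiverSegment",
    "ScanGeometry",
    "UndulatorField",
    "undulator_vector_potential",
    "receiver_adjoint_fields",
    "segment_vector_potential",
    "segment_flux_density",
    "receiver_bz_discrete",
    "cos_carrier",
    "sin_carrier",
]

#: minimum perpendicular distance (m) to a receiver segment before the
#: closed forms are considered singular
_SINGULAR_RHO = 1e-9


@dataclass(frozen=True)
class ReceiverSegment:
    """A straight receiver conductor of length L along y, unit current.

    ``center_y`` is the lab-frame y coordinate of the segment midpoint; the
    segment sits at lab x = 0 in the receiver plane.
    """

    center_y: float
    length: float = 0.10
    orientation: str = "y"

    def __post_init__(self) -> None:
        if self.orientation != "y":
            raise ValueError("only y-oriented receiver segments are supported")
        if self.length <= 0:
            raise ValueError("segment length must be positive")


def _default_receivers(y_extent: float = 0.4, n: int = 6,
                       length: float = 0.10) -> tuple[ReceiverSegment, ...]:
    """n segments with centers evenly spaced across the sheet's y extent."""
    pitch = y_extent / n
    centers = -y_extent / 2 + (np.arange(n) + 0.5) * pitch
    return tuple(ReceiverSegment(center_y=float(c), length=length) for c in centers)


@dataclass(frozen=True)
class ScanGeometry:
    """Full scanner geometry: undulator, sheet discretization, receivers, scan.

    Parameters
    ----------
    period : float
        Undulator field period D (m).  Stripe spacing is D/2.
    sheet_size : (float, float)
        Sheet extent in x and y (m).
    cell_size : float
        Pixel edge length (m); must divide the sheet size exactly.
    z_exciter : float
        Distance from undulator plane to the sheet (m), > 0.
    z_receiver : float
        Distance from sheet to the receiver plane (m); 0 is the
        "contacting measurement" diagnostic mode.
    receivers : tuple of ReceiverSegment
    scan_min, scan_max : float
        Scan range of x_s (m).
    n_scan : int
        Number of uniform scan samples.
    gamma : float
        Phase shift for the splitting basis, in [0, D/4) (m).
    y0, z0 : float
        Fixed offsets of the receiver plane relative to the body frame;
        z0 defaults to ``z_receiver``.
    """

    period: float = 0.16
    sheet_size: tuple[float, float] = (0.40, 0.40)
    cell_size: float = 0.02
    z_exciter: float = 0.10
    z_receiver: float = 0.10
    receivers: tuple[ReceiverSegment, ...] = field(default_factory=_default_receivers)
    scan_min: float = -0.40
    scan_max: float = 0.40
    n_scan: int = 200
    gamma: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("undulator period must be positive")
        for extent in self.sheet_size:
            n = extent / self.cell_size
            if abs(n - round(n)) > 1e-9:
                raise ValueError("cell_size must divide sheet_size exactly")
        if self.z_exciter <= 0:
            raise ValueError("z_exciter must be positive (contactless excitation)")
        if self.z_receiver < 0:
            raise ValueError("z_receiver must be >= 0")
        if not (self.scan_max > self.scan_min and self.n_scan >= 2):
            raise ValueError("invalid scan range")
        if not (0 <= self.gamma < self.period / 4):
            raise ValueError("gamma must lie in [0, D/4)")

    @property
    def n_cells(self) -> tuple[int, int]:
        return (round(self.sheet_size[0] / self.cell_size),
                round(self.sheet_size[1] / self.cell_size))

    @property
    def origin(self) -> tuple[float, float]:
        return (-self.sheet_size[0] / 2, -self.sheet_size[1] / 2)

    @property
    def z0(self) -> float:
        return self.z_receiver

    @property
    def scan_positions(self) -> np.ndarray:
        return np.linspace(self.scan_min, self.scan_max, self.n_scan)

    @property
    def n_receivers(self) -> int:
        return len(self.receivers)

    def with_(self, **kw) -> "ScanGeometry":
        from dataclasses import replace
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, cfg: dict) -> "ScanGeometry":
        """Build from a plain config mapping (the YAML/JSON file format).

        Recognized keys: D, cell_size, sheet_size [sx, sy], z_exciter,
        z_receiver, receivers (list of {center_y, length}), scan
        {min, max, n}, gamma, y0.
        """
        kw = {}
        if "D" in cfg:
            kw["period"] = float(cfg["D"])
        if "cell_size" in cfg:
            kw["cell_size"] = float(cfg["cell_size"])
        if "sheet_size" in cfg:
            sx, sy = cfg["sheet_size"]
            kw["sheet_size"] = (float(sx), float(sy))
        for k in ("z_exciter", "z_receiver", "gamma", "y0"):
            if k in cfg:
                kw[k] = float(cfg[k])
        if "receivers" in cfg:
            kw["receivers"] = tuple(
                ReceiverSegment(center_y=float(r["center_y"]),
                                length=float(r.get("length", 0.10)))
                for r in cfg["receivers"])
        if "scan" in cfg:
            s = cfg["scan"]
            kw["scan_min"] = float(s["min"])
            kw["scan_max"] = float(s["max"])
            kw["n_scan"] = int(s["n"])
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "D": self.period,
            "cell_size": self.cell_size,
            "sheet_size": list(self.sheet_size),
            "z_exciter": self.z_exciter,
            "z_receiver": self.z_receiver,
            "receivers": [{"center_y": r.center_y, "length": r.length}
                          for r in self.receivers],
            "scan": {"min": self.scan_min, "max": self.scan_max,
                     "n": self.n_scan},
            "gamma": self.gamma,
            "y0": self.y0,
        }


def cos_carrier(geometry: ScanGeometry, x_s: np.ndarray,
                gamma: float = 0.0) -> np.ndarray:
    """cos(2*pi*(x_s - gamma)/D) — weight of the phi component at x_s."""
    return np.cos(2 * np.pi * (np.asarray(x_s) - gamma) / geometry.period)


def sin_carrier(geometry: ScanGeometry, x_s: np.ndarray,
                gamma: float = 0.0) -> np.ndarray:
    """sin(2*pi*(x_s - gamma)/D) — weight of the psi component at x_s."""
    return np.sin(2 * np.pi * (np.asarray(x_s) - gamma) / geometry.period)


class UndulatorField:
    """Evaluator for the excitation vector potential A_E (y component only).

    mode "ideal": analytic periodic current-sheet limit, amplitude normalized
    to 1 at z = 0.  mode "stripes": Biot-Savart superposition of ``n_stripes``
    parallel wires along y with alternating current at spacing D/2, scaled to
    the same normalization.
    """

    def __init__(self, period: float, mode: str = "ideal", n_stripes: int = 41,
                 taper: int | None = None):
        if mode not in ("ideal", "stripes"):
            raise ValueError("mode must be 'ideal' or 'stripes'")
        if mode == "stripes" and (n_stripes < 3 or n_stripes % 2 == 0):
            raise ValueError("n_stripes must be odd and >= 3")
        self.period = period
        self.mode = mode
        self.n_stripes = n_stripes
        # current apodization width (stripes per side); a raw +/-1 truncation
        # leaves a slowly decaying edge term that buries the exponentially
        # small periodic field at sheet distance
        self.taper = round(0.3 * n_stripes) if taper is None else taper

    def a_y(self, x: np.ndarray, z: float) -> np.ndarray:
        """A_E,y at body-plane coordinates x (array) and height z > 0."""
        x = np.asarray(x, dtype=float)
        D = self.period
        if self.mode == "ideal":
            if z <= 0:
                raise ValueError("ideal undulator field requires z > 0")
            return np.cos(2 * np.pi * x / D) * math.exp(-2 * np.pi * z / D)
        # stripes: wires at x = k*D/2 carrying current (-1)^k (wire k=0
        # positive, matching the cosine phase).  2D wire potential
        # A_y = -(mu0 I / 2 pi) ln r; the alternating sum is normalized by
        # mu0 I / pi so that the far field matches the ideal mode.  Currents
        # of the outer ``taper`` stripes per side follow a raised-cosine
        # ramp (apodized array ends).
        half = self.n_stripes // 2
        k = np.arange(-half, half + 1)
        xk = k * D / 2
        sgn = np.where(k % 2 == 0, 1.0, -1.0)
        if self.taper > 0:
            t = (np.arange(self.taper) + 0.5) / self.taper
            ramp = 0.5 * (1 - np.cos(np.pi * t))
            sgn[:self.taper] *= ramp
            sgn[-self.taper:] *= ramp[::-1]
        r2 = (x[..., None] - xk) ** 2 + z ** 2
        if np.any(r2 <= 0):
            raise ValueError("field point coincides with a stripe")
        return -0.25 * np.sum(sgn * np.log(r2), axis=-1)


def undulator_vector_potential(geometry: ScanGeometry, points: np.ndarray,
                               mode: str = "ideal",
                               n_stripes: int = 41) -> FieldMap:
    """Sample A_E on ``points`` (N, 3) at the sheet plane.

    Points must lie at z = z_exciter above the undulator plane (the third
    column is ignored and taken as the sheet plane).
    """
    points = np.asarray(points, dtype=float)
    und = UndulatorField(geometry.period, mode=mode, n_stripes=n_stripes)
    values = np.zeros_like(points)
    values[:, 1] = und.a_y(points[:, 0], geometry.z_exciter)
    return FieldMap(points=points, values=values, name=f"A_E[{mode}]")


# ---------------------------------------------------------------------------
# receiver segment closed forms


def _segment_geometry(seg: ReceiverSegment, dx, dy, dz):
    """Common factors for the finite-segment closed forms.

    dx, dy, dz are field-point coordinates relative to the segment center,
    broadcastable arrays.
    """
    rho2 = dx ** 2 + dz ** 2
    t1 = -seg.length / 2 - dy
    t2 = seg.length / 2 - dy
    r1 = np.sqrt(rho2 + t1 ** 2)
    r2 = np.sqrt(rho2 + t2 ** 2)
    return rho2, t1, t2, r1, r2


def segment_vector_potential(seg: ReceiverSegment, dx, dy, dz,
                             check_singular: bool = True) -> np.ndarray:
    """A_y of a unit-current finite straight segment (closed form).

    ``(dx, dy, dz)`` is the field point relative to the segment center.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    rho2, t1, t2, _, _ = _segment_geometry(seg, dx, dy, dz)
    if check_singular and np.any(rho2 < _SINGULAR_RHO ** 2):
        raise ValueError("field point lies on the segment axis (singular)")
    rho = np.sqrt(rho2)
    return mu_0 / (4 * np.pi) * (np.arcsinh(t2 / rho) - np.arcsinh(t1 / rho))


def segment_flux_density(seg: ReceiverSegment, dx, dy, dz,
                         check_singular: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """(B_x, B_z) of a unit-current finite segment, closed-form Biot-Savart.

    B has no y component for a y-directed segment.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    rho2, t1, t2, r1, r2 = _segment_geometry(seg, dx, dy, dz)
    if check_singular and np.any(rho2 < _SINGULAR_RHO ** 2):
        raise ValueError("field point lies on the segment axis (singular)")
    f = mu_0 / (4 * np.pi) * (t2 / r2 - t1 / r1) / rho2
    return f * dz, -f * dx


def receiver_adjoint_fields(geometry: ScanGeometry,
                            points: np.ndarray) -> tuple[FieldMap, FieldMap]:
    """Sample A_R and B_R of every receiver on ``points`` (N, 3).

    Points are lab-frame coordinates in the sheet plane (their z column is
    the sheet plane; the receiver plane sits ``z_receiver`` above it).
    Returns two FieldMaps with values of shape (n_receivers, N, 3).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    R = geometry.n_receivers
    a_vals = np.zeros((R, n, 3))
    b_vals = np.zeros((R, n, 3))
    dz = geometry.z_receiver
    for r, seg in enumerate(geometry.receivers):
        dx = points[:, 0]
        dy = points[:, 1] - seg.center_y + geometry.y0
        a_vals[r, :, 1] = segment_vector_potential(seg, dx, dy, dz)
        bx, bz = segment_flux_density(seg, dx, dy, dz)
        b_vals[r, :, 0] = bx
        b_vals[r, :, 2] = bz
    return (FieldMap(points, a_vals, name="A_R"),
            FieldMap(points, b_vals, name="B_R"))


def receiver_bz_discrete(seg: ReceiverSegment, dx, dy, dz,
                         cell_size: float) -> np.ndarray:
    """z flux density of a segment as the one-cell discrete curl of A_R.

    Central difference of A_R,y over one pixel in x.  This is the B that
    makes the moment-path signal identical to the current-path signal on the
    lattice (summation by parts); it approaches the closed-form B_z to
    O(cell_size^2).
    """
    h = cell_size
    ap = segment_vector_potential(seg, np.asarray(dx) + h / 2, dy, dz)
    am = segment_vector_potential(seg, np.asarray(dx) - h / 2, dy, dz)
    return (ap - am) / h
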