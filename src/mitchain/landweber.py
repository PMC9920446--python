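"""Stage 2 — moments from split signals by regularized Landweber iteration.

The linear forward map from per-pixel z moments to stacked receiver traces
is a dense transfer matrix T whose column j holds the scan-shifted z flux
density traces of all receivers for a unit moment at pixel j.  One matrix
serves both basis components; the sinusoidal carriers enter as diagonal row
scalings.  Because the receiver fields are spatially low-passed, T is
heavily rank deficient: far fewer singular values are significant than
there are moment unknowns, and the inversion is regularized by early
stopping of the Landweber iteration

    m_(k+1) = m_k + tau * T^T (s - T m_k),   m_0 = 0,

which converges to the minimum-norm least-squares solution for
0 < tau < 2 / sigma_max^2 and exhibits semi-convergence on noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MomentField
from .fields import (ScanGeometry, cos_carrier, receiver_bz_discrete,
                     sin_carrier)
from .splitting import SplitResult

__all__ = [
    "TransferMatrix",
    "build_transfer_matrix",
    "effective_rank",
    "landweber_invert",
    "invert_components",
]

#: rows whose |carrier| falls below this weight carry no information for
#: the component and are zeroed during the inversion
CARRIER_CUTOFF = 0.05


@dataclass
class TransferMatrix:
    """Dense moment-to-signal map for one scanner geometry.

    ``matrix`` has shape (n_receivers * n_scan, nx * ny): receiver-major
    stacked signal rows, C-ordered pixel columns.  Rows hold the raw
    (carrier-free) B_R,z traces; carriers are applied per component at
    inversion time.
    """

    matrix: np.ndarray
    geometry: ScanGeometry
    grid_shape: tuple[int, int]
    carrier_applied: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def carrier_weights(self, component: str) -> np.ndarray:
        """Per-row carrier values for a component, stacked receiver-major."""
        xs = self.geometry.scan_positions
        if component == "phi":
            w = cos_carrier(self.geometry, xs)
        elif component == "psi":
            w = sin_carrier(self.geometry, xs)
        else:
            raise ValueError("component must be 'phi' or 'psi'")
        return np.tile(w, self.geometry.n_receivers)


def build_transfer_matrix(geometry: ScanGeometry) -> TransferMatrix:
    """Transfer matrix entry ((rho, s), j) = B_R,z of receiver rho at pixel
    j's center shifted by scan position x_s.

    B_R,z is the one-cell discrete curl of the segment vector potential, so
    a matrix column reproduces the carrier-free moment-path signal of a unit
    moment at that pixel to round-off.
    """
    nx, ny = geometry.n_cells
    h = geometry.cell_size
    x0, y0 = geometry.origin
    xc = x0 + (np.arange(nx) + 0.5) * h
    yc = y0 + (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    px, py = X.reshape(-1), Y.reshape(-1)

    xs = geometry.scan_positions
    n_pix = px.size
    T = np.empty((geometry.n_receivers * xs.size, n_pix))
    dx = px[None, :] + xs[:, None]  # (n_scan, n_pix)
    for r, seg in enumerate(geometry.receivers):
        dy = (py - seg.center_y + geometry.y0)[None, :]
        bz = receiver_bz_discrete(seg, dx, dy, geometry.z_receiver, h)
        T[r * xs.size:(r + 1) * xs.size] = bz
    return TransferMatrix(T, geometry, (nx, ny))


def effective_rank(T: TransferMatrix | np.ndarray,
                   rel_threshold: float = 1e-3) -> int:
    """Number of singular values >= rel_threshold times the largest.

    With the threshold at 1e-3 (a 60 dB dynamic range) this counts the
    signal-space directions a realistic measurement can actually resolve.
    """
    if not (0 < rel_threshold < 1):
        raise ValueError("rel_threshold must lie in (0, 1)")
    A = T.matrix if isinstance(T, TransferMatrix) else np.asarray(T)
    sv = np.linalg.svd(A, compute_uv=False)
    if sv.size == 0 or sv[0] == 0:
        return 0
    return int(np.sum(sv >= rel_threshold * sv[0]))


def _sigma_max(A: np.ndarray, n_iter: int = 200, tol: float = 1e-10) -> float:
    """Largest singular value by power iteration on A^T A (deterministic)."""
    v = np.ones(A.shape[1])
    v /= np.linalg.norm(v)
    prev = 0.0
    for _ in range(n_iter):
        w = A.T @ (A @ v)
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return 0.0
        v = w / nrm
        if abs(nrm - prev) <= tol * nrm:
            break
        prev = nrm
    return float(np.sqrt(nrm))


def landweber_invert(T: TransferMatrix | np.ndarray, s: np.ndarray,
                     n_iter: int = 1000, relaxation: float | None = None,
                     x0: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Landweber iteration on T m = s from a zero initial guess.

    Parameters
    ----------
    relaxation : float, optional
        Step tau; must satisfy 0 < tau < 2 / sigma_max^2.  Default
        1 / sigma_max^2 (sigma_max by power iteration).

    Returns
    -------
    m : ndarray
        Iterate after ``n_iter`` steps (flat pixel ordering).
    residuals : ndarray
        ||s - T m_k|| per iteration (diagnostics; non-increasing for a
        valid tau).
    """
    A = T.matrix if isinstance(T, TransferMatrix) else np.asarray(T)
    s = np.asarray(s, dtype=float).reshape(-1)
    if s.size != A.shape[0]:
        raise ValueError("signal length does not match the matrix rows")
    smax = _sigma_max(A)
    if relaxation is None:
        if smax == 0:
            raise ValueError("zero matrix has no default relaxation")
        tau = 1.0 / smax ** 2
    else:
        tau = float(relaxation)
        if not (0 < tau < 2 / smax ** 2 if smax > 0 else tau > 0):
            raise ValueError(
                f"relaxation {tau:g} outside the convergence interval "
                f"(0, {2 / smax ** 2:g})")
    m = np.zeros(A.shape[1]) if x0 is None else np.asarray(x0, float).copy()
    residuals = np.empty(n_iter)
    for k in range(n_iter):
        r = s - A @ m
        residuals[k] = np.linalg.norm(r)
        m += tau * (A.T @ r)
    return m, residuals


def _component_matrix(T: TransferMatrix, component: str
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Carrier-scaled matrix and row mask for one component."""
    w = T.carrier_weights(component)
    mask = np.abs(w) >= CARRIER_CUTOFF
    return (w * mask)[:, None] * T.matrix, mask


def invert_components(split: SplitResult, T: TransferMatrix,
                      n_iter: int = 1000, relaxation: float | None = None
                      ) -> tuple[MomentField, MomentField]:
    """Landweber-invert both split components against the shared matrix.

    Each component is solved against diag(carrier) T with rows near the
    carrier nulls removed (they carry no information for that component and
    only amplify noise).
    """
    geom = T.geometry
    out = []
    for comp in ("phi", "psi"):
        A, mask = _component_matrix(T, comp)
        s = split.signal.stacked(comp) * mask
        m, _ = landweber_invert(A, s, n_iter=n_iter, relaxation=relaxation)
        out.append(MomentField(m.reshape(T.grid_shape), geom.cell_size,
                               geom.origin, basis=comp))
    return out[0], out[1]
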