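"""Weak-coupling eddy-current forward model on a resistor lattice.

The conductivity sheet is lumped into a rectangular network of resistors on
pixel edges.  The periodic excitation field induces an EMF in every edge
(inner product of A_E with the directed edge length); nodal analysis yields
the unique eddy-current distribution; the reciprocity theorem turns currents
into receiver signals:

    S = sum_i I_i (A_R,i . dl_i)            (current path)
    S = sum_j m_j B_R,z,j                   (moment path)

Because the excitation is sinusoidally periodic in x, the eddy field at any
scan position is a two-term superposition of the basis fields J_phi (body
centered on a stripe) and J_psi (a quarter period off):

    J(x_s) = cos(2 pi x_s / D) J_phi + sin(2 pi x_s / D) J_psi

so only two network solves are needed per conductivity map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .containers import ConductivityGrid, CurrentField, MomentField, ScanSignal
from .fields import (ScanGeometry, UndulatorField, cos_carrier,
                     segment_vector_potential, receiver_bz_discrete,
                     sin_carrier)

__all__ = [
    "ResistorNetwork",
    "build_network",
    "induced_emfs",
    "solve_eddy_currents",
    "basis_currents",
    "current_at_position",
    "signal_from_currents",
    "signal_from_moments",
    "currents_to_moments",
]

#: node-rule tolerance (relative to max |I|) accepted by currents_to_moments
NODE_RULE_RTOL = 1e-8


@dataclass
class ResistorNetwork:
    """Resistor lattice on the pixel edges of a conductivity grid.

    Edge conductances: ``gx[i, j]`` for the x-edge from node (i, j) to
    (i+1, j), ``gy[i, j]`` for the y-edge from node (i, j) to (i, j+1).
    The flat edge ordering used for vectors is all x-edges in C order
    followed by all y-edges in C order.
    """

    gx: np.ndarray
    gy: np.ndarray
    cell_size: float
    origin: tuple[float, float]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.gx.shape[0], self.gy.shape[1]

    @property
    def n_nodes(self) -> int:
        nx, ny = self.grid_shape
        return (nx + 1) * (ny + 1)

    @property
    def n_edges(self) -> int:
        return self.gx.size + self.gy.size

    @property
    def n_loops(self) -> int:
        """Cycle-space dimension k - n + 1 of the (connected) full lattice.

        Equals the pixel count — the number of independent loop currents,
        and hence of describing magnetic moments.
        """
        return self.n_edges - self.n_nodes + 1

    # --- geometry helpers ------------------------------------------------

    def node_index(self, i, j):
        ny = self.grid_shape[1]
        return i * (ny + 1) + j

    def edge_midpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) midpoints of all edges in flat order, and unit directions.

        Returns (mid, direction) with shapes (k, 2) each.
        """
        nx, ny = self.grid_shape
        h = self.cell_size
        x0, y0 = self.origin
        ix, jx = np.meshgrid(np.arange(nx), np.arange(ny + 1), indexing="ij")
        mx = np.stack([x0 + (ix + 0.5) * h, y0 + jx * h], axis=-1).reshape(-1, 2)
        iy, jy = np.meshgrid(np.arange(nx + 1), np.arange(ny), indexing="ij")
        my = np.stack([x0 + iy * h, y0 + (jy + 0.5) * h], axis=-1).reshape(-1, 2)
        mid = np.concatenate([mx, my], axis=0)
        direction = np.zeros_like(mid)
        direction[:mx.shape[0], 0] = 1.0
        direction[mx.shape[0]:, 1] = 1.0
        return mid, direction

    def incidence(self) -> sp.csr_matrix:
        """Signed edge-node incidence matrix M (k x n): +1 tail, -1 head.

        Edge current obeys I = g (M V + U) with V node potentials and U the
        edge EMF oriented along the edge direction.
        """
        nx, ny = self.grid_shape
        rows, cols, vals = [], [], []
        e = 0
        for i in range(nx):
            for j in range(ny + 1):
                rows += [e, e]
                cols += [self.node_index(i, j), self.node_index(i + 1, j)]
                vals += [1.0, -1.0]
                e += 1
        for i in range(nx + 1):
            for j in range(ny):
                rows += [e, e]
                cols += [self.node_index(i, j), self.node_index(i, j + 1)]
                vals += [1.0, -1.0]
                e += 1
        return sp.csr_matrix((vals, (rows, cols)),
                             shape=(self.n_edges, self.n_nodes))

    def conductance_vector(self) -> np.ndarray:
        return np.concatenate([self.gx.reshape(-1), self.gy.reshape(-1)])

    def split_edge_vector(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        kx = self.gx.size
        return (v[:kx].reshape(self.gx.shape), v[kx:].reshape(self.gy.shape))


def build_network(grid: ConductivityGrid) -> ResistorNetwork:
    """Lump a conductivity grid into edge conductances.

    Each edge conductance is the arithmetic mean of the conductivities of
    the (one or two) adjacent pixels times the sheet thickness; for square
    cells the edge length cancels against the current-tube width, so g is
    simply sigma * t.
    """
    sig = grid.values
    nx, ny = sig.shape
    t = grid.thickness
    # x-edge (i, j) borders pixels (i, j-1) and (i, j)
    gx = np.empty((nx, ny + 1))
    gx[:, 0] = sig[:, 0] * t
    gx[:, -1] = sig[:, -1] * t
    gx[:, 1:-1] = 0.5 * (sig[:, :-1] + sig[:, 1:]) * t
    # y-edge (i, j) borders pixels (i-1, j) and (i, j)
    gy = np.empty((nx + 1, ny))
    gy[0, :] = sig[0, :] * t
    gy[-1, :] = sig[-1, :] * t
    gy[1:-1, :] = 0.5 * (sig[:-1, :] + sig[1:, :]) * t
    return ResistorNetwork(gx=gx, gy=gy, cell_size=grid.cell_size,
                           origin=grid.origin)


def induced_emfs(network: ResistorNetwork, undulator: UndulatorField,
                 z_exciter: float, x_s: float, scale: float = 1.0) -> np.ndarray:
    """Per-edge EMF U = scale * (A_E . direction) * dl at edge midpoints.

    The 90-degree eddy phase and the j*omega factor are absorbed into the
    real ``scale`` (default 1), so all signals are real amplitudes.  Only
    edges parallel to the stripes (y-edges for the default undulator) pick
    up an EMF.
    """
    mid, direction = network.edge_midpoints()
    a_y = undulator.a_y(mid[:, 0] + x_s, z_exciter)
    return scale * a_y * direction[:, 1] * network.cell_size


def solve_eddy_currents(network: ResistorNetwork, emfs: np.ndarray,
                        basis: str = "") -> CurrentField:
    """Nodal analysis of the resistor lattice with per-edge EMF sources.

    Edge current I = g (V_a - V_b + U).  One node per connected conducting
    component is grounded (lowest index) to fix the potential gauge; a fully
    non-conducting network returns zero currents.
    """
    g = network.conductance_vector()
    emfs = np.asarray(emfs, dtype=float)
    if emfs.shape != (network.n_edges,):
        raise ValueError("EMF vector length must equal the edge count")
    if not np.any(g > 0):
        ix, iy = network.split_edge_vector(np.zeros(network.n_edges))
        return CurrentField(ix, iy, network.cell_size, network.origin, basis)

    M = network.incidence()
    G = sp.diags(g)
    lap = (M.T @ G @ M).tocsr()
    rhs = -M.T @ (g * emfs)

    # connected components of the conducting subgraph
    conducting = g > 0
    Mc = M[conducting]
    adj = (Mc.T @ Mc).tocsr()
    n_comp, labels = connected_components(abs(adj) > 0, directed=False)
    touched = np.asarray(abs(Mc).sum(axis=0)).ravel() > 0

    V = np.zeros(network.n_nodes)
    free = np.ones(network.n_nodes, dtype=bool)
    free[~touched] = False  # isolated nodes stay at 0 V
    for c in range(n_comp):
        members = np.where((labels == c) & touched)[0]
        if members.size:
            free[members[0]] = False  # ground the lowest-index node
    idx = np.where(free)[0]
    if idx.size:
        V[idx] = spsolve(lap[np.ix_(idx, idx)].tocsc(), rhs[idx])

    currents = g * (M @ V + emfs)
    ix, iy = network.split_edge_vector(currents)
    return CurrentField(ix, iy, network.cell_size, network.origin, basis)


def basis_currents(grid: ConductivityGrid, geometry: ScanGeometry,
                   undulator: UndulatorField | None = None
                   ) -> tuple[CurrentField, CurrentField]:
    """Solve the two basis eddy fields J_phi (x_s = 0) and J_psi (x_s = D/4)."""
    und = undulator or UndulatorField(geometry.period)
    net = build_network(grid)
    u_phi = induced_emfs(net, und, geometry.z_exciter, 0.0)
    u_psi = induced_emfs(net, und, geometry.z_exciter, geometry.period / 4)
    return (solve_eddy_currents(net, u_phi, basis="phi"),
            solve_eddy_currents(net, u_psi, basis="psi"))


def current_at_position(j_phi: CurrentField, j_psi: CurrentField,
                        geometry: ScanGeometry, x_s: float) -> CurrentField:
    """Superpose the basis fields at scan position x_s (two-term expansion)."""
    c = float(cos_carrier(geometry, x_s))
    s = float(sin_carrier(geometry, x_s))
    out = c * j_phi + s * j_psi
    out.basis = f"scan({x_s:g})"
    return out


def _receiver_weighted_sums(xm: np.ndarray, ym: np.ndarray,
                            weights: np.ndarray, geometry: ScanGeometry,
                            field: str) -> np.ndarray:
    """sum_e w_e * F_R(x_e + x_s, y_e - y_c, z_rec) per receiver and x_s.

    ``field`` selects A_R,y ('a') or the cell-stencil B_R,z ('bz').
    Returns shape (n_receivers, n_scan).
    """
    xs = geometry.scan_positions
    out = np.empty((geometry.n_receivers, xs.size))
    dzr = geometry.z_receiver
    dx = xm[:, None] + xs[None, :]
    for r, seg in enumerate(geometry.receivers):
        dy = (ym - seg.center_y + geometry.y0)[:, None]
        if field == "a":
            vals = segment_vector_potential(seg, dx, dy, dzr)
        else:
            vals = receiver_bz_discrete(seg, dx, dy, dzr, geometry.cell_size)
        out[r] = weights @ vals
    return out


def signal_from_currents(j_phi: CurrentField, j_psi: CurrentField,
                         geometry: ScanGeometry) -> ScanSignal:
    """Receiver signals by reciprocity from the basis current fields.

    S_phi(x_s) = cos(2 pi x_s / D) * sum_i I_phi,i dl (A_R,y at the shifted
    edge midpoint), and analogously for S_psi with the sine carrier; the
    total is their sum.  Only y-edges contribute (A_R has only a y
    component for y-oriented segments).
    """
    net_like = j_phi
    nx, ny = net_like.grid_shape
    h = net_like.cell_size
    x0, y0 = net_like.origin
    iy_idx, jy_idx = np.meshgrid(np.arange(nx + 1), np.arange(ny), indexing="ij")
    xm = (x0 + iy_idx * h).reshape(-1)
    ym = (y0 + (jy_idx + 0.5) * h).reshape(-1)

    xs = geometry.scan_positions
    env_phi = _receiver_weighted_sums(xm, ym, j_phi.iy.reshape(-1) * h,
                                      geometry, "a")
    env_psi = _receiver_weighted_sums(xm, ym, j_psi.iy.reshape(-1) * h,
                                      geometry, "a")
    s_phi = cos_carrier(geometry, xs)[None, :] * env_phi
    s_psi = sin_carrier(geometry, xs)[None, :] * env_psi
    return ScanSignal(xs, s_phi + s_psi, phi=s_phi, psi=s_psi)


def signal_from_moments(m_phi: MomentField, m_psi: MomentField,
                        geometry: ScanGeometry) -> ScanSignal:
    """Receiver signals from per-pixel moments: S = sum_j m_j B_R,z,j.

    Uses the one-cell discrete curl of A_R as B_R,z so that the moment path
    agrees with the current path to round-off on the lattice.
    """
    xc, yc = m_phi.pixel_centers()
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    xm, ym = X.reshape(-1), Y.reshape(-1)
    env_phi = _receiver_weighted_sums(xm, ym, m_phi.values.reshape(-1),
                                      geometry, "bz")
    env_psi = _receiver_weighted_sums(xm, ym, m_psi.values.reshape(-1),
                                      geometry, "bz")
    xs = geometry.scan_positions
    s_phi = cos_carrier(geometry, xs)[None, :] * env_phi
    s_psi = sin_carrier(geometry, xs)[None, :] * env_psi
    return ScanSignal(xs, s_phi + s_psi, phi=s_phi, psi=s_psi)


def currents_to_moments(J: CurrentField) -> MomentField:
    """Integrate a node-rule-satisfying edge current field to pixel moments.

    The discrete line integral sweeps from the body boundary inward (moments
    are anchored at zero outside the sheet); it is the exact inverse of the
    discrete curl.  Inputs violating the node rule are rejected — no
    consistent moment field exists for them.
    """
    scale = J.max_abs()
    if scale > 0:
        resid = np.max(np.abs(J.node_divergence()))
        if resid > NODE_RULE_RTOL * scale:
            raise ValueError(
                f"current field violates the node rule (residual {resid:.3e})")
    h2 = J.cell_size ** 2
    # I_y(i, j) = -(m(i, j) - m(i-1, j)) / h^2  with m(-1, j) = 0
    m = -h2 * np.cumsum(J.iy[:-1, :], axis=0)
    return MomentField(m, J.cell_size, J.origin, J.basis)
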