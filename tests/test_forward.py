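"""Resistor-network forward model: graph structure, solver, reciprocity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mitchain import (ConductivityGrid, CurrentField, MomentField,
                      ScanGeometry, UndulatorField, basis_currents,
                      build_network, current_at_position, currents_to_moments,
                      induced_emfs, moments_to_currents, signal_from_currents,
                      signal_from_moments, solve_eddy_currents)


def mesh_current_oracle(network, emfs):
    """Independent loop (mesh) solver: B R B^T lam = B U, I = B^T lam.

    Valid for fully conducting grids; the signed loop-edge matrix B walks
    each pixel loop counterclockwise.
    """
    nx, ny = network.grid_shape
    k = network.n_edges
    kx = network.gx.size
    B = np.zeros((nx * ny, k))

    def xe(i, j):
        return i * (ny + 1) + j

    def ye(i, j):
        return kx + i * ny + j

    for i in range(nx):
        for j in range(ny):
            p = i * ny + j
            B[p, xe(i, j)] = 1.0        # bottom, +x
            B[p, ye(i + 1, j)] = 1.0    # right, +y
            B[p, xe(i, j + 1)] = -1.0   # top, -x
            B[p, ye(i, j)] = -1.0       # left, -y
    r = 1.0 / network.conductance_vector()
    lam = np.linalg.solve(B @ np.diag(r) @ B.T, B @ emfs)
    return B.T @ lam


class TestNetworkStructure:
    def test_three_by_three_counts(self, small_grid):
        net = build_network(small_grid)
        assert (net.n_nodes, net.n_edges, net.n_loops) == (16, 24, 9)

    @pytest.mark.parametrize("c", [2, 5, 11, 20, 30])
    def test_loop_count_equals_pixel_count(self, c):
        grid = ConductivityGrid(np.full((c, c), 0.5), 0.02, (0, 0))
        net = build_network(grid)
        assert net.n_edges == 2 * c * (c + 1)
        assert net.n_nodes == (c + 1) ** 2
        assert net.n_loops == c * c

    def test_loop_count_is_cycle_space_rank(self, small_grid):
        """k - n + 1 equals the corank of the incidence matrix."""
        net = build_network(small_grid)
        M = net.incidence().toarray()
        rank = np.linalg.matrix_rank(M)
        assert net.n_edges - rank == net.n_loops

    def test_homogeneous_interior_conductances_equal(self):
        grid = ConductivityGrid(np.full((4, 4), 0.7), 0.02, (0, 0))
        net = build_network(grid)
        assert np.allclose(net.gx, 0.7 * grid.thickness)
        assert np.allclose(net.gy, 0.7 * grid.thickness)

    def test_default_grid_counts(self, homogeneous):
        net = build_network(homogeneous)
        assert (net.n_nodes, net.n_edges, net.n_loops) == (441, 840, 400)


class TestInducedEmfs:
    def test_only_stripe_parallel_edges_driven(self, small_grid):
        net = build_network(small_grid)
        u = induced_emfs(net, UndulatorField(0.16), 0.1, 0.0)
        kx = net.gx.size
        assert np.all(u[:kx] == 0)          # x-edges see no EMF
        assert np.any(u[kx:] != 0)

    def test_half_period_shift_flips_all_emfs(self, small_grid):
        net = build_network(small_grid)
        und = UndulatorField(0.16)
        u0 = induced_emfs(net, und, 0.1, 0.03)
        u1 = induced_emfs(net, und, 0.1, 0.03 + 0.08)
        assert np.allclose(u1, -u0, atol=1e-18)


class TestEddySolver:
    def test_zero_emf_zero_currents(self, small_grid):
        net = build_network(small_grid)
        J = solve_eddy_currents(net, np.zeros(net.n_edges))
        assert J.max_abs() == 0

    def test_nonconducting_sheet_returns_zero(self):
        grid = ConductivityGrid(np.zeros((4, 4)), 0.02, (0, 0))
        net = build_network(grid)
        u = induced_emfs(net, UndulatorField(0.16), 0.1, 0.0)
        assert solve_eddy_currents(net, u).max_abs() == 0

    def test_matches_mesh_current_oracle(self, small_grid):
        """Nodal solve equals an independent loop-current brute force on the
        9-loop network, for arbitrary EMFs."""
        net = build_network(small_grid)
        rng = np.random.default_rng(3)
        emfs = rng.standard_normal(net.n_edges)
        J = solve_eddy_currents(net, emfs)
        flat = np.concatenate([J.ix.reshape(-1), J.iy.reshape(-1)])
        oracle = mesh_current_oracle(net, emfs)
        assert np.linalg.norm(flat - oracle) / np.linalg.norm(oracle) < 1e-8

    def test_node_rule_residual(self, basis_fields):
        for J in basis_fields:
            resid = np.max(np.abs(J.node_divergence()))
            assert resid <= 1e-10 * J.max_abs()

    def test_phi_pattern_mirror_symmetric(self, homogeneous, geometry):
        """Centered on a stripe, the eddy pattern is mirror-symmetric about
        the stripe axis: y-currents even in x, x-currents odd."""
        j_phi, _ = basis_currents(homogeneous, geometry)
        scale = j_phi.max_abs()
        assert np.max(np.abs(j_phi.iy - j_phi.iy[::-1, :])) < 1e-8 * scale
        assert np.max(np.abs(j_phi.ix + j_phi.ix[::-1, :])) < 1e-8 * scale

    def test_disconnected_islands_solved_independently(self):
        sig = np.zeros((6, 6))
        sig[:2, :2] = 1.0
        sig[4:, 4:] = 0.5
        grid = ConductivityGrid(sig, 0.02, (0, 0))
        net = build_network(grid)
        u = induced_emfs(net, UndulatorField(0.16), 0.1, 0.02)
        J = solve_eddy_currents(net, u)
        assert np.max(np.abs(J.node_divergence())) <= 1e-10 * J.max_abs()


class TestBasisSuperposition:
    def test_two_field_expansion_matches_direct_solve(self, three_level,
                                                      geometry):
        """J(x_s) = cos(2 pi x_s/D) J_phi + sin(2 pi x_s/D) J_psi equals a
        direct solve at x_s, at random scan positions."""
        j_phi, j_psi = basis_currents(three_level, geometry)
        net = build_network(three_level)
        und = UndulatorField(geometry.period)
        rng = np.random.default_rng(11)
        for x_s in rng.uniform(-0.4, 0.4, 8):
            direct = solve_eddy_currents(
                net, induced_emfs(net, und, geometry.z_exciter, x_s))
            sup = current_at_position(j_phi, j_psi, geometry, x_s)
            err = max(np.max(np.abs(direct.ix - sup.ix)),
                      np.max(np.abs(direct.iy - sup.iy)))
            assert err < 1e-8 * direct.max_abs()

    def test_phi_position_is_pure_phi(self, basis_fields, geometry):
        j_phi, j_psi = basis_fields
        sup = current_at_position(j_phi, j_psi, geometry, 0.0)
        assert np.allclose(sup.ix, j_phi.ix) and np.allclose(sup.iy, j_phi.iy)

    def test_eighth_period_weights_are_equal(self, geometry):
        from mitchain import cos_carrier, sin_carrier
        x = geometry.period / 8
        assert cos_carrier(geometry, x) == pytest.approx(np.cos(np.pi / 4))
        assert sin_carrier(geometry, x) == pytest.approx(np.sin(np.pi / 4))


class TestReciprocitySignals:
    def test_zero_currents_zero_signal(self, geometry):
        zero = CurrentField(np.zeros((20, 21)), np.zeros((21, 20)), 0.02)
        sig = signal_from_currents(zero, zero, geometry)
        assert np.all(sig.total == 0)

    def test_linearity_in_currents(self, basis_fields, geometry):
        j_phi, j_psi = basis_fields
        s1 = signal_from_currents(j_phi, j_psi, geometry)
        s2 = signal_from_currents(2.0 * j_phi, 2.0 * j_psi, geometry)
        assert np.allclose(s2.total, 2.0 * s1.total, rtol=1e-12)

    def test_dual_path_identity(self, basis_fields, geometry):
        """Currents dotted with A_R and moments dotted with B_R give the
        same signal to <1e-6 relative — the triple-product identity."""
        j_phi, j_psi = basis_fields
        s_cur = signal_from_currents(j_phi, j_psi, geometry)
        m_phi = currents_to_moments(j_phi)
        m_psi = currents_to_moments(j_psi)
        s_mom = signal_from_moments(m_phi, m_psi, geometry)
        rel = (np.max(np.abs(s_cur.total - s_mom.total))
               / np.max(np.abs(s_cur.total)))
        assert rel < 1e-6

    def test_dual_path_identity_random_moments(self, geometry):
        """Same identity for arbitrary moment arrays (through the curl)."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            m1 = MomentField(rng.standard_normal((20, 20)), 0.02)
            m2 = MomentField(rng.standard_normal((20, 20)), 0.02)
            s_mom = signal_from_moments(m1, m2, geometry)
            s_cur = signal_from_currents(moments_to_currents(m1),
                                         moments_to_currents(m2), geometry)
            rel = (np.max(np.abs(s_cur.total - s_mom.total))
                   / np.max(np.abs(s_mom.total)))
            assert rel < 1e-6

    def test_single_moment_signal_is_field_trace(self, geometry):
        """One unit moment at the sheet center: the psi-carrier-free trace
        equals B_R,z along the scan."""
        from mitchain import cos_carrier
        from mitchain.fields import receiver_bz_discrete
        m = np.zeros((20, 20))
        m[10, 10] = 1.0
        mf = MomentField(m, 0.02, geometry.origin)
        zero = MomentField(np.zeros((20, 20)), 0.02, geometry.origin)
        sig = signal_from_moments(mf, zero, geometry)
        xc = geometry.origin[0] + 10.5 * 0.02
        yc = geometry.origin[1] + 10.5 * 0.02
        seg = geometry.receivers[2]
        trace = receiver_bz_discrete(seg, xc + geometry.scan_positions,
                                     yc - seg.center_y, geometry.z_receiver,
                                     geometry.cell_size)
        carrier = cos_carrier(geometry, geometry.scan_positions)
        assert np.allclose(sig.phi[2], carrier * trace, rtol=0, atol=1e-25)


class TestCurrentsToMoments:
    def test_elementary_vortex_moment(self):
        """A unit circulation around one pixel maps to a single moment."""
        m = np.zeros((4, 4))
        m[1, 2] = 1.0
        J = moments_to_currents(MomentField(m, 0.02))
        back = currents_to_moments(J)
        assert np.allclose(back.values, m, atol=1e-15)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.standard_normal((7, 5))
        back = currents_to_moments(moments_to_currents(MomentField(m, 0.02)))
        assert np.max(np.abs(back.values - m)) < 1e-12

    def test_path_independence_of_summation(self, basis_fields):
        """Sweeping from the left boundary (y-edges) or from the bottom
        boundary (x-edges) gives identical moments for node-rule fields."""
        J = basis_fields[0]
        m_left = currents_to_moments(J).values
        h2 = J.cell_size ** 2
        m_bottom = h2 * np.cumsum(J.ix[:, :-1], axis=1)
        assert np.max(np.abs(m_left - m_bottom)) < 1e-12 * np.max(
            np.abs(m_left))

    def test_node_rule_violation_rejected(self):
        ix = np.zeros((3, 4))
        iy = np.zeros((4, 3))
        ix[1, 1] = 1.0  # a lone edge current is not divergence free
        with pytest.raises(ValueError, match="node rule"):
            currents_to_moments(CurrentField(ix, iy, 0.02))
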