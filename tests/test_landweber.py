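"""Transfer matrix and Landweber moment inversion."""

import numpy as np
import pytest

from mitchain import (MomentField, ScanSignal, build_transfer_matrix,
                      effective_rank, invert_components, landweber_invert,
                      signal_from_moments)
from mitchain.splitting import SplitResult


@pytest.fixture(scope="module")
def transfer(geometry):
    return build_transfer_matrix(geometry)


@pytest.fixture(scope="module")
def reduced_transfer(reduced_geometry):
    return build_transfer_matrix(reduced_geometry)


class TestTransferMatrix:
    def test_default_shape(self, transfer):
        assert transfer.shape == (1200, 400)

    def test_column_equals_carrier_free_moment_signal(self, transfer,
                                                      geometry):
        """A unit moment's column reproduces the carrier-free moment-path
        signal trace to round-off."""
        j = 123
        m = np.zeros(transfer.grid_shape)
        m[np.unravel_index(j, transfer.grid_shape)] = 1.0
        mf = MomentField(m, geometry.cell_size, geometry.origin)
        zero = MomentField(np.zeros_like(m), geometry.cell_size,
                           geometry.origin)
        sig = signal_from_moments(mf, zero, geometry)
        from mitchain import cos_carrier
        env = sig.phi / cos_carrier(geometry, geometry.scan_positions)[None, :]
        assert np.max(np.abs(env.reshape(-1) - transfer.matrix[:, j])) < 1e-12

    def test_pixel_shift_shifts_column_pattern(self, transfer, geometry):
        """Moving the moment one pixel (2 cm) in x shifts each receiver's
        column trace by 2 cm worth of scan samples (cross-correlation lag)."""
        ny = transfer.grid_shape[1]
        j = 9 * ny + 10
        j_shift = 10 * ny + 10  # one pixel further in x
        n_s = geometry.n_scan
        xs = geometry.scan_positions
        a = transfer.matrix[:n_s, j]
        b = transfer.matrix[:n_s, j_shift]
        interior = slice(10, -10)
        shifted = np.interp(xs + geometry.cell_size, xs, a)
        assert np.allclose(b[interior], shifted[interior],
                           atol=1e-3 * np.max(np.abs(a)))

    def test_effective_rank_identity_matrix(self):
        assert effective_rank(np.eye(17), 0.5) == 17

    def test_effective_rank_below_200(self, transfer):
        """Despite 1200 signal entries, fewer than 200 directions survive a
        60 dB dynamic range."""
        assert effective_rank(transfer, 1e-3) < 200

    def test_rank_decreases_with_receiver_distance(self, geometry):
        ranks = [effective_rank(build_transfer_matrix(
            geometry.with_(z_receiver=z)), 1e-3) for z in (0.05, 0.10, 0.15)]
        assert ranks[0] >= ranks[1] >= ranks[2]
        assert ranks[0] > ranks[2]

    def test_underdetermination_quantified(self, transfer):
        assert effective_rank(transfer, 1e-3) < transfer.shape[1]


class TestLandweber:
    def test_zero_signal_fixed_point(self, reduced_transfer):
        m, res = landweber_invert(reduced_transfer,
                                  np.zeros(reduced_transfer.shape[0]),
                                  n_iter=50)
        assert np.all(m == 0) and np.all(res == 0)

    def test_invalid_relaxation_rejected(self, reduced_transfer):
        s = np.zeros(reduced_transfer.shape[0])
        smax = np.linalg.norm(reduced_transfer.matrix, 2)
        with pytest.raises(ValueError, match="relaxation"):
            landweber_invert(reduced_transfer, s, n_iter=5,
                             relaxation=3.0 / smax ** 2)

    def test_residual_monotone_for_valid_relaxation(self, reduced_transfer):
        rng = np.random.default_rng(2)
        s = rng.standard_normal(reduced_transfer.shape[0])
        _, res = landweber_invert(reduced_transfer, s, n_iter=300)
        assert np.all(np.diff(res) <= 1e-12 * res[0])

    def test_matches_pseudoinverse_on_resolved_subspace(self,
                                                        reduced_transfer):
        """Noiseless data from moments in the well-resolved singular
        subspace: 1e4 Landweber steps agree with the SVD pseudoinverse to
        <1e-3.  (Modes below ~3% of sigma_max converge too slowly to be
        testable at this iteration count.)"""
        A = reduced_transfer.matrix
        U, sv, Vt = np.linalg.svd(A, full_matrices=False)
        keep = sv >= 0.05 * sv[0]
        rng = np.random.default_rng(4)
        m_true = Vt[keep].T @ rng.standard_normal(int(np.sum(keep)))
        s = A @ m_true
        m_pinv = np.linalg.pinv(A) @ s
        m, _ = landweber_invert(A, s, n_iter=10_000)
        assert (np.linalg.norm(m - m_pinv) / np.linalg.norm(m_pinv)) < 1e-3

    def test_iterate_equals_svd_filter_expansion(self):
        """m_k = V diag((1-(1-tau s^2)^k)/s) U^T b — the spectral filter
        form of the Landweber iterate."""
        rng = np.random.default_rng(9)
        A = rng.standard_normal((12, 7))
        b = rng.standard_normal(12)
        U, sv, Vt = np.linalg.svd(A, full_matrices=False)
        smax = sv[0]
        tau = 1.0 / smax ** 2
        for k in (1, 5, 40):
            m, _ = landweber_invert(A, b, n_iter=k, relaxation=tau)
            filt = (1 - (1 - tau * sv ** 2) ** k) / sv
            expect = Vt.T @ (filt * (U.T @ b))
            assert np.allclose(m, expect, atol=1e-10)

    def test_semi_convergence_under_noise(self, reduced_transfer):
        """With 40 dB noise the error to the true moments falls, reaches a
        minimum, and grows again at high iteration counts."""
        A = reduced_transfer.matrix
        U, sv, Vt = np.linalg.svd(A, full_matrices=False)
        rng = np.random.default_rng(6)
        keep = sv >= 0.05 * sv[0]
        m_true = Vt[keep].T @ rng.standard_normal(int(np.sum(keep)))
        s = A @ m_true
        noise = rng.standard_normal(s.size)
        noise *= np.sqrt(np.mean(s ** 2) / 1e4) / np.std(noise)
        s_noisy = s + noise
        tau = 1.0 / sv[0] ** 2
        m = np.zeros(A.shape[1])
        checkpoints = {}
        for k in range(10_000):
            m += tau * (A.T @ (s_noisy - A @ m))
            if k + 1 in (10, 100, 500, 1000, 10_000):
                checkpoints[k + 1] = np.linalg.norm(m - m_true)
        errs = [checkpoints[k] for k in sorted(checkpoints)]
        k_min = int(np.argmin(errs))
        assert 0 < k_min < len(errs) - 1          # interior minimum
        assert errs[k_min] < checkpoints[10_000]  # grows again
        assert errs[k_min] < errs[0]              # fell first


class TestInvertComponents:
    def test_zero_differential_gives_zero_moments(self, transfer, geometry):
        x = geometry.scan_positions
        zeros = np.zeros((6, x.size))
        split = SplitResult(ScanSignal(x, zeros, zeros, zeros),
                            zeros, zeros, 0.0, 0.0)
        m_phi, m_psi = invert_components(split, transfer, n_iter=20)
        assert np.all(m_phi.values == 0) and np.all(m_psi.values == 0)

    def test_differential_current_intensity_localizes_perturbation(
            self, close_geometry, homogeneous):
        """Single perturbation at 5 cm receivers: the per-pixel intensity of
        the reconstructed differential currents peaks inside the
        perturbation support."""
        from mitchain import (basis_currents, moments_to_currents,
                              pixel_intensity, signal_from_currents,
                              split_signal)
        truth = homogeneous.copy()
        truth.values[12:14, 9:11] = 1.0
        T = build_transfer_matrix(close_geometry)
        s = signal_from_currents(*basis_currents(truth, close_geometry),
                                 close_geometry)
        s_ref = signal_from_currents(
            *basis_currents(homogeneous, close_geometry), close_geometry)
        ds = ScanSignal(s.x_s, s.total - s_ref.total)
        split = split_signal(ds, close_geometry)
        m_phi, m_psi = invert_components(split, T)
        inten = pixel_intensity(moments_to_currents(m_phi),
                                moments_to_currents(m_psi))
        peak = np.unravel_index(np.argmax(inten), inten.shape)
        assert 11 <= peak[0] <= 14 and 8 <= peak[1] <= 11
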