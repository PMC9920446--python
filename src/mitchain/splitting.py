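"""Stage 1 — split a measured scan signal into its phi and psi components.

Any signal trace has the carrier structure

    S(x_s) = cos(2 pi x_s / D) E_phi(x_s) + sin(2 pi x_s / D) E_psi(x_s)

with slowly varying envelopes E_c (low-passed by the distant receiver
fields).  At the carrier zeros of one component the other is fully active,
so sparse exact samples of each envelope are available every D/2 (the two
families interleaved at D/4).  Interpolating the sparse envelopes and
re-modulating gives first estimates; the leftover residual
e = S - S_phi,E1 - S_psi,E1 is distributed between the components with
energy-proportional weights so that the final split sums to S exactly.

A basis shift gamma in [0, D/4) rotates the component pair; it is chosen to
make the two first-estimate energies as different as possible, because the
residual correction is exact when one component dominates completely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .containers import ScanSignal
from .fields import ScanGeometry, cos_carrier, sin_carrier

__all__ = ["SplitResult", "sample_at_carrier_zeros", "split_signal"]


@dataclass
class SplitResult:
    """Outcome of the signal splitting stage.

    ``signal`` carries the final components (phi/psi of the embedded
    ScanSignal are the second estimates, which sum to the input exactly);
    first estimates and the chosen shift are kept for diagnostics.
    """

    signal: ScanSignal
    phi_e1: np.ndarray
    psi_e1: np.ndarray
    gamma_star: float
    energy_ratio: float

    @property
    def phi(self) -> np.ndarray:
        return self.signal.phi

    @property
    def psi(self) -> np.ndarray:
        return self.signal.psi


def _zero_positions(geometry: ScanGeometry, gamma: float,
                    component: str) -> np.ndarray:
    """Scan positions where the *other* carrier vanishes (every D/2)."""
    D = geometry.period
    offset = gamma if component == "phi" else gamma + D / 4
    lo, hi = geometry.scan_min, geometry.scan_max
    k_min = int(np.ceil((lo - offset) / (D / 2) - 1e-12))
    k_max = int(np.floor((hi - offset) / (D / 2) + 1e-12))
    return offset + np.arange(k_min, k_max + 1) * (D / 2)


def sample_at_carrier_zeros(S: ScanSignal, geometry: ScanGeometry,
                            gamma: float, component: str = "phi"
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Sparse envelope samples of one component in the gamma-shifted basis.

    At each position where the other component's carrier is zero, the signal
    equals +/- the envelope of the requested component; the sign is removed
    by dividing by its own carrier (+/-1 there).  Signal values between scan
    samples are obtained by cubic interpolation of S.

    Returns (positions, samples) with samples of shape (n_receivers, n_pos).
    """
    if component not in ("phi", "psi"):
        raise ValueError("component must be 'phi' or 'psi'")
    if geometry.scan_max - geometry.scan_min < geometry.period:
        raise ValueError("scan range must cover at least one undulator period")
    pos = _zero_positions(geometry, gamma, component)
    interp = CubicSpline(S.x_s, S.total, axis=1)
    vals = interp(pos)
    if component == "phi":
        carrier = cos_carrier(geometry, pos, gamma)
    else:
        carrier = sin_carrier(geometry, pos, gamma)
    return pos, vals / carrier[None, :]


def _envelope_estimate(pos: np.ndarray, samples: np.ndarray, x: np.ndarray,
                       interpolation: str) -> np.ndarray:
    """Interpolate sparse envelope samples onto the full scan grid."""
    if interpolation == "spline":
        if pos.size < 2:
            return np.repeat(samples, x.size, axis=1) if pos.size == 1 \
                else np.zeros((samples.shape[0], x.size))
        return CubicSpline(pos, samples, axis=1, bc_type="natural")(x)
    if interpolation == "sinc":
        dx = pos[1] - pos[0]
        kernel = np.sinc((x[None, :] - pos[:, None]) / dx)
        return samples @ kernel
    raise ValueError("interpolation must be 'spline' or 'sinc'")


def _first_estimates(S: ScanSignal, geometry: ScanGeometry, gamma: float,
                     interpolation: str) -> tuple[np.ndarray, np.ndarray,
                                                  np.ndarray, np.ndarray]:
    """Envelope estimates (phi, psi) in the gamma basis and their signals."""
    x = S.x_s
    pos_p, samp_p = sample_at_carrier_zeros(S, geometry, gamma, "phi")
    pos_q, samp_q = sample_at_carrier_zeros(S, geometry, gamma, "psi")
    env_p = _envelope_estimate(pos_p, samp_p, x, interpolation)
    env_q = _envelope_estimate(pos_q, samp_q, x, interpolation)
    sig_p = cos_carrier(geometry, x, gamma)[None, :] * env_p
    sig_q = sin_carrier(geometry, x, gamma)[None, :] * env_q
    return env_p, env_q, sig_p, sig_q


def split_signal(S: ScanSignal, geometry: ScanGeometry,
                 gamma: float | None = None, n_gamma: int = 16,
                 interpolation: str = "spline",
                 weighting: str = "energy") -> SplitResult:
    """Decompose a scan signal into its phi and psi components.

    Parameters
    ----------
    S : ScanSignal
        Measured (or differential) signal; only ``total`` is used.
    gamma : float, optional
        Basis shift in [0, D/4).  By default a grid of ``n_gamma`` shifts is
        searched for the one making the first-estimate energies most
        different (summed over all receivers).
    interpolation : {"spline", "sinc"}
        Envelope interpolation between the sparse carrier-zero samples:
        natural cubic spline (default) or band-limited sinc.
    weighting : {"energy", "carrier"}
        Residual distribution: global energy-proportional per-receiver
        weights (default) or per-sample squared-carrier weights (linear in
        the signal).
    """
    x = S.x_s
    D = geometry.period

    if gamma is None:
        gammas = np.linspace(0.0, D / 4, n_gamma, endpoint=False)
        best = (-1.0, 0.0)
        for g in gammas:
            _, _, sig_p, sig_q = _first_estimates(S, geometry, g, interpolation)
            ep, eq = np.sum(sig_p ** 2), np.sum(sig_q ** 2)
            ratio = abs(ep - eq) / (ep + eq) if ep + eq > 0 else 0.0
            if ratio > best[0]:
                best = (ratio, g)
        energy_ratio, gamma_star = best
    else:
        if not (0 <= gamma < D / 4):
            raise ValueError("gamma must lie in [0, D/4)")
        gamma_star = float(gamma)
        energy_ratio = np.nan

    env_p, env_q, sig_p, sig_q = _first_estimates(S, geometry, gamma_star,
                                                  interpolation)
    if gamma is not None:
        ep, eq = np.sum(sig_p ** 2), np.sum(sig_q ** 2)
        energy_ratio = abs(ep - eq) / (ep + eq) if ep + eq > 0 else 0.0

    # rotate the shifted-basis envelopes back to the phi/psi basis
    alpha = 2 * np.pi * gamma_star / D
    env_phi = np.cos(alpha) * env_p - np.sin(alpha) * env_q
    env_psi = np.sin(alpha) * env_p + np.cos(alpha) * env_q
    c = cos_carrier(geometry, x)[None, :]
    s = sin_carrier(geometry, x)[None, :]
    phi_e1 = c * env_phi
    psi_e1 = s * env_psi

    residual = S.total - phi_e1 - psi_e1
    if weighting == "energy":
        e_phi = np.sum(phi_e1 ** 2, axis=1, keepdims=True)
        e_psi = np.sum(psi_e1 ** 2, axis=1, keepdims=True)
        tot = e_phi + e_psi
        w_phi = np.divide(e_phi, tot, out=np.full_like(e_phi, 0.5),
                          where=tot > 0)
    elif weighting == "carrier":
        w_phi = np.broadcast_to(c ** 2, S.total.shape)
    else:
        raise ValueError("weighting must be 'energy' or 'carrier'")
    phi_e2 = phi_e1 + w_phi * residual
    psi_e2 = psi_e1 + (1.0 - w_phi) * residual

    out = ScanSignal(x, S.total.copy(), phi=phi_e2, psi=psi_e2)
    return SplitResult(signal=out, phi_e1=phi_e1, psi_e1=psi_e1,
                       gamma_star=gamma_star, energy_ratio=float(energy_ratio))
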