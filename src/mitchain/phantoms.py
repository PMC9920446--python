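"""Synthetic conductivity phantoms and signal noise injection.

The default test object is a 40 cm x 40 cm sheet discretized into
2 cm x 2 cm pixels with a 0.5 S/m background — conductivities span the
biomedical range [0, 1] S/m.  The "three-level" phantom adds one higher
(1 S/m) and one lower (0.25 S/m) rectangular region; the "homogeneous"
phantom is the reference body for differential operation.  Additive white
Gaussian noise at a prescribed SNR (40 dB is the practically observed
level) emulates measurement noise on the differential signal traces.
"""

from __future__ import annotations

import numpy as np

from .containers import ConductivityGrid, ScanSignal

__all__ = [
    "make_phantom",
    "random_phantom",
    "add_noise",
    "BACKGROUND_SIGMA",
    "HIGH_SIGMA",
    "LOW_SIGMA",
]

BACKGROUND_SIGMA = 0.5  # S/m
HIGH_SIGMA = 1.0        # S/m
LOW_SIGMA = 0.25        # S/m

#: documented default rectangles of the three-level phantom, in pixel
#: index ranges (x_lo, x_hi, y_lo, y_hi), half-open
THREE_LEVEL_HIGH = (4, 8, 11, 15)
THREE_LEVEL_LOW = (12, 16, 4, 8)


def _base_grid(shape=(20, 20), cell_size=0.02) -> ConductivityGrid:
    origin = (-shape[0] * cell_size / 2, -shape[1] * cell_size / 2)
    return ConductivityGrid(np.full(shape, BACKGROUND_SIGMA),
                            cell_size=cell_size, origin=origin)


def make_phantom(which: str = "three-level") -> ConductivityGrid:
    """Standard test phantoms on the default 20 x 20 grid.

    * ``"homogeneous"`` — uniform 0.5 S/m reference sheet.
    * ``"three-level"`` — 0.5 S/m background with one 1 S/m and one
      0.25 S/m rectangular region (exactly three distinct values).
    * ``"prior-structured"`` — a 23 x 23 (46 cm) sheet with pronounced
      inhomogeneities on the right side, for prior-knowledge experiments.
    """
    if which == "homogeneous":
        return _base_grid()
    if which == "three-level":
        g = _base_grid()
        x0, x1, y0, y1 = THREE_LEVEL_HIGH
        g.values[x0:x1, y0:y1] = HIGH_SIGMA
        x0, x1, y0, y1 = THREE_LEVEL_LOW
        g.values[x0:x1, y0:y1] = LOW_SIGMA
        return g
    if which == "prior-structured":
        g = _base_grid(shape=(23, 23))
        g.values[16:21, 4:9] = HIGH_SIGMA
        g.values[16:21, 14:19] = LOW_SIGMA
        g.values[3:6, 9:14] = LOW_SIGMA
        return g
    raise ValueError(
        "which must be 'homogeneous', 'three-level' or 'prior-structured'")


def random_phantom(seed: int, n_perturbations: int = 2,
                   size_range: tuple[int, int] = (2, 5),
                   value_range: tuple[float, float] = (0.1, 1.0),
                   shape: tuple[int, int] = (20, 20),
                   cell_size: float = 0.02,
                   max_tries: int = 200) -> ConductivityGrid:
    """Seed-deterministic phantom with non-overlapping rectangular regions.

    Perturbation side lengths are drawn uniformly from ``size_range``
    (pixels, inclusive) and conductivities uniformly from ``value_range``
    (S/m) on a 0.5 S/m background.  Regions keep at least one background
    pixel between them so each perturbation stays a distinct object.
    """
    rng = np.random.default_rng(seed)
    g = _base_grid(shape=shape, cell_size=cell_size)
    occupied = np.zeros(shape, dtype=bool)
    placed = 0
    for _ in range(max_tries):
        if placed == n_perturbations:
            break
        w = rng.integers(size_range[0], size_range[1] + 1)
        hgt = rng.integers(size_range[0], size_range[1] + 1)
        x0 = rng.integers(0, shape[0] - w + 1)
        y0 = rng.integers(0, shape[1] - hgt + 1)
        lo_x, hi_x = max(x0 - 1, 0), min(x0 + w + 1, shape[0])
        lo_y, hi_y = max(y0 - 1, 0), min(y0 + hgt + 1, shape[1])
        if occupied[lo_x:hi_x, lo_y:hi_y].any():
            continue
        value = rng.uniform(*value_range)
        g.values[x0:x0 + w, y0:y0 + hgt] = value
        occupied[x0:x0 + w, y0:y0 + hgt] = True
        placed += 1
    if placed < n_perturbations:
        raise RuntimeError(
            f"could not place {n_perturbations} non-overlapping regions")
    return g


def add_noise(S: ScanSignal, snr_db: float, seed: int) -> ScanSignal:
    """Additive white Gaussian noise at a prescribed SNR on the total trace.

    The noise variance is set from the mean power of the stacked trace so
    that 10 log10(P_signal / P_noise) = ``snr_db``.  ``snr_db = inf``
    returns an unchanged copy.  Component labels are dropped — a noisy
    signal is a measurement whose split is unknown.
    """
    if np.isinf(snr_db):
        return ScanSignal(S.x_s.copy(), S.total.copy(),
                          None if S.phi is None else S.phi.copy(),
                          None if S.psi is None else S.psi.copy())
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite or +inf")
    power = float(np.mean(S.total ** 2))
    if power == 0:
        raise ValueError("cannot set a finite SNR on a zero-power signal")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(power / 10 ** (snr_db / 10))
    noisy = S.total + rng.normal(0.0, sigma, size=S.total.shape)
    return ScanSignal(S.x_s.copy(), noisy)
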