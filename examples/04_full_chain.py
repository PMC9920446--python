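"""Full differential reconstruction: signals -> conductivity map.

Simulates a measurement of the three-level phantom, runs all four inverse
stages against the homogeneous reference body, and summarizes how well the
two perturbations are recovered — noiselessly and at the practically
observed 40 dB SNR.
"""

import numpy as np

from mitchain import (ScanGeometry, make_phantom, run_differential_chain,
                      simulate_measurement)
from mitchain.phantoms import THREE_LEVEL_HIGH, THREE_LEVEL_LOW

geometry = ScanGeometry(z_receiver=0.05)   # sharpest contactless preset
truth = make_phantom("three-level")
reference = make_phantom("homogeneous")
s_meas = simulate_measurement(truth, geometry)


def summarize(label, sigma):
    hx0, hx1, hy0, hy1 = THREE_LEVEL_HIGH
    lx0, lx1, ly0, ly1 = THREE_LEVEL_LOW
    mask = np.ones(sigma.shape, bool)
    mask[hx0:hx1, hy0:hy1] = False
    mask[lx0:lx1, ly0:ly1] = False
    print(f"{label}: mean sigma  high region {sigma[hx0:hx1, hy0:hy1].mean():.3f}"
          f"  background {sigma[mask].mean():.3f}"
          f"  low region {sigma[lx0:lx1, ly0:ly1].mean():.3f}  (S/m)")


summarize("true map      ", truth.values)
res = run_differential_chain(s_meas, reference, geometry)
summarize("reconstruction", res.sigma.values)
print(f"conductivity stage: {res.history.n_iterations} iterations, "
      f"final max|K-1| = {res.history.max_k_deviation[-1]:.3f}")

noisy = run_differential_chain(s_meas, reference, geometry,
                               noise_snr_db=40.0, seed=7)
summarize("40 dB SNR run ", noisy.sigma.values)
print("-> both perturbations keep the correct contrast sign; noise at the")
print("   practical level only moderately blurs the reconstruction.")
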