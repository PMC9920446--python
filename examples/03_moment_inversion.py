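"""Stage 2: transfer matrix, its information content, and Landweber.

Builds the 1200 x 400 moment-to-signal matrix for the default geometry,
counts how many of its singular directions survive a 60 dB dynamic range,
and shows how that number shrinks as the receivers move away — the
mechanism that limits depth resolution in induction imaging.
"""

import numpy as np

from mitchain import (ScanGeometry, build_transfer_matrix, effective_rank,
                      landweber_invert)

geometry = ScanGeometry()
T = build_transfer_matrix(geometry)
print(f"transfer matrix shape: {T.shape} "
      f"(6 receivers x 200 scan positions -> 20x20 moments)")
for z in (0.05, 0.10, 0.15):
    Tz = build_transfer_matrix(geometry.with_(z_receiver=z))
    r = effective_rank(Tz, rel_threshold=1e-3)
    print(f"receivers at {z * 100:2.0f} cm: effective rank @1e-3 = {r:3d} "
          f"of {Tz.shape[1]} moment unknowns")

rng = np.random.default_rng(0)
U, sv, Vt = np.linalg.svd(T.matrix, full_matrices=False)
m_true = Vt[sv >= 0.05 * sv[0]].T @ rng.standard_normal(
    int(np.sum(sv >= 0.05 * sv[0])))
s = T.matrix @ m_true
m, residuals = landweber_invert(T, s, n_iter=1000)
rel = np.linalg.norm(m - m_true) / np.linalg.norm(m_true)
print(f"Landweber, 1000 iterations on noiseless resolvable moments: "
      f"relative error {rel:.2e}")
print(f"residual decreased monotonically: "
      f"{bool(np.all(np.diff(residuals) <= 0))}")
print("-> far fewer independent data than unknowns: the inversion is")
print("   regularized by early stopping and recovers only smooth features.")
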