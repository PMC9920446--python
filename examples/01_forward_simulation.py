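"""Forward problem: eddy currents of a phantom and its receiver signals.

Builds the standard three-level phantom (0.5 S/m background, one 1 S/m and
one 0.25 S/m region), solves the two basis eddy-current fields on the
resistor lattice, and synthesizes the six receiver traces by reciprocity —
once from edge currents dotted with A_R and once from pixel moments dotted
with B_R, which must agree.
"""

import numpy as np

from mitchain import (ScanGeometry, basis_currents, build_network,
                      currents_to_moments, make_phantom, signal_from_currents,
                      signal_from_moments)

geometry = ScanGeometry()  # D = 16 cm, 20x20 sheet, receivers at 10 cm
phantom = make_phantom("three-level")

network = build_network(phantom)
print(f"resistor lattice: {network.n_nodes} nodes, {network.n_edges} edges, "
      f"{network.n_loops} independent loops (= pixels)")

j_phi, j_psi = basis_currents(phantom, geometry)
resid = np.max(np.abs(j_phi.node_divergence())) / j_phi.max_abs()
print(f"Kirchhoff node-rule residual of J_phi: {resid:.2e} (relative)")

s_cur = signal_from_currents(j_phi, j_psi, geometry)
s_mom = signal_from_moments(currents_to_moments(j_phi),
                            currents_to_moments(j_psi), geometry)
rel = np.max(np.abs(s_cur.total - s_mom.total)) / np.max(np.abs(s_cur.total))
print(f"signal traces: {s_cur.n_receivers} receivers x {s_cur.n_scan} "
      f"scan positions")
print(f"current-path vs moment-path signal deviation: {rel:.2e} (relative)")
print("-> the two reciprocity formulations are numerically identical, so")
print("   moments are a faithful, node-rule-safe basis for the eddy field.")
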