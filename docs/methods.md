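# Methods

This note documents the physical model, the numerical choices and the known
limitations of the package, in the order of the processing chain.

## Forward model

**Weak coupling.** The sheet conductivities are low (biomedical range,
≤ 1 S/m) and the operating frequency is low enough that eddy currents
neither deform the excitation field nor their own secondary field.  Both
field maps are therefore fixed and precomputable: the excitation vector
potential A_E drives the eddies, and the receiver adjoint fields A_R / B_R
convert them to signals via the reciprocity theorem.  Capacitive and
inductive reactance of the lattice are neglected; the eddy phase sits 90°
from the exciting current, and that phase together with the jω factor of
the induction law is absorbed into one real scale (set to 1), so all
signals are real amplitudes.

**Excitation.** Ideal mode uses the periodic current-sheet limit
A_E,y(x, z) = cos(2πx/D) e^(−2πz/D), normalized to unit amplitude at the
source plane.  The default period is D = 16 cm (stripe spacing 8 cm), so
the 40 cm sheet spans 2.5 periods; the value is configurable and only sets
the spatial frequency that probes the body.  The "stripes" mode superposes
2D wire fields at spacing D/2 with alternating current.  A truncated ±1
array does not converge to the periodic limit at sheet distance: its net
current and the slowly decaying edge terms swamp the exponentially small
(≈ 0.02) useful field.  The finite array is therefore apodized — a
raised-cosine current ramp over the outer ~30 % of stripes per side — after
which 41 stripes agree with the ideal mode to 1.5 % over the central 40 cm
window at z = 10 cm.

**Receivers.** Six straight segments of length 10 cm along y, centers
evenly spaced across the sheet's y extent, at z_receiver = 10 cm by default
(5 cm and 15 cm as presets; z_receiver = 0 is the diagnostic "contacting
measurement").  A_R and B_R follow the closed forms for a finite
unit-current segment.  Gradiometric/butterfly structure is not modeled: it
exists to cancel the primary field in hardware, and the simulator computes
only eddy-sourced signals.

**Lattice.** A c × c pixel grid becomes a resistor network on the pixel
edges: (c+1)² nodes, 2c(c+1) edges, and k − n + 1 = c² independent loops —
exactly one loop (one z-moment) per pixel.  Edge conductance is the
arithmetic mean of the adjacent pixel conductivities times the sheet
thickness (boundary edges use their single neighbor); for square cells the
edge length cancels.  Thickness (default 1 cm) is a pure signal scale in
2D.  Nodal analysis with one grounded reference node per connected
conducting component gives the unique currents I = g(V_a − V_b + U);
σ = 0 pixels simply carry no current.  Only two solves (the φ and ψ basis
positions, a quarter period apart) are needed per conductivity map.

**Dual reciprocity paths.** S = Σ I Δl · A_R and S = Σ m · B_R must agree.
On the lattice this identity is exact (summation by parts) only when B_R,z
is the *discrete* curl of A_R over one cell — a central difference at the
pixel pitch — rather than the analytic curl.  The package therefore uses
the cell-stencil B_R in the moment-path signal and in the transfer matrix
(it equals the analytic field to O(h²), h = 2 cm), and keeps the
closed-form Biot–Savart B_R for field inspection.  The measured agreement
of the two signal paths is ~1e-14 relative.

## Stage 1 — signal splitting

Model: S(x) = cos(2πx/D) E_φ(x) + sin(2πx/D) E_ψ(x) with slowly varying
envelopes.  At the zeros of one carrier the other component is fully
active, giving exact envelope samples every D/2 per component.  Procedure:

1. Search a shift γ over [0, D/4) (16-point grid; envelope energies vary
   slowly in γ) maximizing the energy contrast |E_φ − E_ψ|/(E_φ + E_ψ) of
   the first estimates, summed over all receivers.
2. Interpolate the sparse envelope samples — natural cubic spline by
   default; band-limited sinc interpolation behind a flag (exact for
   envelopes band-limited below half the component sampling rate).
3. Rotate the shifted-basis envelope estimates back to the φ/ψ basis by
   the 2 × 2 rotation with angle 2πγ/D.  (The rotation acts on envelopes,
   not on modulated signals, which would be undefined at carrier nulls.)
4. Re-modulate, form the residual e = S − S_φ,E1 − S_ψ,E1, and distribute
   it with per-receiver energy weights w_c = E_c/(E_φ + E_ψ), so
   S_φ,E2 + S_ψ,E2 = S holds to round-off.  A per-sample squared-carrier
   weighting is available; it makes the splitting exactly linear in S.

When one true component vanishes the recovered split is exact (the energy
weight of the spurious component is ~0).  Splitting is applied per
receiver; γ is chosen jointly.

## Stage 2 — moment inversion

The transfer matrix (1200 × 400 for the default geometry: 6 receivers ×
200 scan samples over ±40 cm, 400 pixel moments) holds the carrier-free
B_R,z traces of a unit moment per pixel; one matrix serves both components,
with the carriers applied as diagonal row scalings.  Rows where
|carrier| < 0.05 are zeroed during inversion — they carry no information
for that component and only amplify noise.

Landweber iteration m ← m + τ Tᵀ(s − T m) from zero initial moments,
fixed 1000 iterations by default, τ = 1/σ_max² (power iteration); τ is
validated against the convergence interval (0, 2/σ_max²).  No Tikhonov
term: regularization is purely by early stopping.  The iterate equals the
spectral filter V diag((1−(1−τσ²)^k)/σ) Uᵀ s, so modes with σ ≪ σ_max
converge at rate τσ² per step: after 10⁴ iterations only modes above a few
percent of σ_max are resolved, and with noisy data the error
semi-converges (falls, reaches a minimum, rises).  The effective rank at a
1e-3 relative singular-value threshold (a 60 dB dynamic range) is 64 for
the default geometry — far below the 400 unknowns — and shrinks further as
the receivers move away (114 at 5 cm, 43 at 15 cm): the receiver fields
low-pass the spatial information over distance.

## Stage 3 — discrete curl

For z-only moments on a square lattice, I_x = Δm_z/Δy and I_y = −Δm_z/Δx
over cell-size differences, with m ≡ 0 outside the sheet (boundary edges
difference against zero).  The output satisfies the node rule exactly for
arbitrary moment arrays, and the operation is the exact inverse of the
boundary-anchored moment summation (round trip < 1e-12).  The in-plane
moment components vanish identically in 2D; 3D lattices are out of scope.
Edge indexing (x-edges by (column, row-boundary), y-edges by
(column-boundary, row)) is fixed so CSV outputs are bit-comparable.

In differential operation the curl output is added edgewise to the
reference body's basis currents to obtain the "measured" fields.

## Stage 4 — conductivity correction

Per pixel the four bordering edge |currents| are condensed to one amount
(arithmetic mean by default, RMS behind a flag — the lumping rule is a
package choice), separately for φ and ψ, combined as
I = sqrt(I_φ² + I_ψ²).  The correction K = I_M/I_E multiplies the estimate
elementwise; σ is clipped to [0, σ_cap] with σ_cap = 1 S/m by default
(biomedical bound, exposed as a parameter).  Pixels with I_E below
1e-3 × max(I_E) keep K = 1: a vanishing estimated current carries no
correction information.  The loop stops at max_iter (default 10) or when
max|K − 1| < 0.01.  With exact currents the true map is a fixed point;
from a homogeneous start on the standard three-level phantom the map
becomes stationary (< 1 % relative change) after 8 iterations and the
perturbation locations and contrast signs settle by iteration 5.  The
strict max|K − 1| < 0.01 criterion is reached later (~15 iterations): the
multiplicative fixed-point iteration has a slow linear tail, while the
map itself has long stopped changing visibly.  No damping is applied to K.

## Synthetic data

The generator reproduces the study conditions: a 40 cm × 40 cm sheet at
2 cm pixels, 0.5 S/m background, a three-level phantom with 1 S/m and
0.25 S/m rectangles (their positions are package defaults — documented
rectangles, not ground truth from any measurement), seeded random phantoms
with non-overlapping rectangular perturbations in [0.1, 1] S/m, and
additive white Gaussian noise at a prescribed SNR (default experiments use
40 dB on the differential signal, the practically observed level; the
noise spectrum is assumed white and the SNR is global over the stacked
trace).  What the generator does *not* emulate: real coil imperfections,
primary-field leakage, drift, non-white noise, 3D bodies, and contour
mismatch between reference and measured body.  Passing tests therefore
demonstrate the correctness and conditioning of the inversion chain, not
end-to-end hardware performance.

## Numerical conventions and degenerate inputs

- All quantities SI; excitation amplitude normalized to 1.
- Node-rule tolerance for accepting a current field as curl-consistent:
  1e-8 × max|I|; solver residuals are ~1e-14 relative.
- Fully non-conducting sheets yield zero currents (not an error);
  disconnected conducting islands are solved per component with one
  grounded node each (removes the potential gauge deterministically).
- An all-zero signal splits into all-zero components with equal weights.
- Landweber rejects τ outside (0, 2/σ_max²); a zero matrix has no default τ.
- Random phantom placement retries up to 200 times before failing.

## Known limitations

- 2D sheets only; the 3D moment basis (x/y components plus a single
  y-moment layer) is future work and not stubbed in.
- The splitting assumes the ideal cos/sin carrier; finite-stripe carrier
  distortion is not compensated.
- The conductivity stage recovers compressed contrast whenever the moment
  stage has discarded high-spatial-frequency information — more iterations
  do not help, as the loss happens upstream.
- Reconstruction quality degrades monotonically with receiver distance;
  at the contacting-measurement limit the nonlinear stage is the only
  error source.
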