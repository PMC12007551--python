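# Methods

This note documents the models, numerical choices and limitations of
`tmsresponse`.  It is the package's own account; every number quoted here is
either a default the code uses or a quantity the test suite computes.

## Geometry and conventions

Morphologies are rooted trees of sections (polylines with per-point
diameters, µm).  The soma sits at the origin, the main axon extends toward
−z, dendrites toward +z, so the local z-axis is the somato-dendritic axis
and coincides with the cortical-normal direction when a cell is placed in a
patch element.  All coordinates are stored in µm; z is converted to mm only
inside the field-profile evaluation, whose decay parameter Δ|Ẽ| is in %/mm.

SWC I/O uses the standard 7-column format.  SWC has no myelin vocabulary,
so three custom type codes are added:

| code | meaning            |
|------|--------------------|
| 1    | soma               |
| 2    | unmyelinated axon  |
| 3, 4 | dendrite           |
| 7    | myelin internode   |
| 8    | node of Ranvier    |
| 9    | myelinated terminal|

Every section point is written as its own record (the junction point of a
child section duplicates its parent's last record), which makes save∘load
bit-exact on generator output.  Files without duplicated junction points are
also read correctly (the parent point is prepended to the child section).

## Myelination

Axonal cables are partitioned, proximal to distal, into: node of Ranvier
(width 1 µm), then alternating internode/node, with internode length
L = 100·D and a distal terminal section of length 70·D (truncated when the
cable is shorter).  Boundary remainders extend the last internode rather
than creating sub-node-width stubs; branch-point sections end in a node so
branch points stay excitable.  Arc length is conserved to < 0.1%.  A
consequence of the truncation rule worth knowing: the 760 µm × 15 µm
ball-and-stick axon is shorter than one full terminal (70·15 = 1050 µm), so
it reduces to node(1 µm) + terminal(759 µm).

The length of unmyelinated initial segment is exposed
(`initial_segment`, default 0 µm): there is no consensus default for the
stand-in archetypes, and 0 keeps the partition rule exactly enumerable.

## Synthetic populations

`generate_synthetic_population` produces seeded stand-ins for reconstructed
cortical cells: a descending main axon with lateral jitter, 4–11 myelinated
collaterals branching at random heights and directions, and a passive
apical-like dendrite.  Two archetypes differ only in geometry ranges:
pyramidal-like cells are tall (main axon 800–1000 µm, dendrite 400 µm,
collaterals within 55–125° of the downward axis), basket-like cells are
compact and closer to isotropic (axon 250–350 µm, longer and more
uniformly oriented collaterals).  The generator emulates what matters for
field coupling — terminals distributed over directions and depths — and
does **not** emulate realistic branching statistics, tortuosity, synaptic
boutons, or the morphological diversity of curated reconstructions.  A
green test on these populations establishes correctness of the pipeline's
mechanics, not biological threshold values.

## Membrane model

The channel tables of detailed cortical neuron models live in external
databases and are not redistributable, so the membrane model is
package-owned and deliberately generic:

| role                 | c_m (µF/cm²) | g_pas (S/cm²) | g_Na (S/cm²) | g_K (S/cm²) |
|----------------------|--------------|---------------|--------------|-------------|
| soma/dendrite        | 1.0          | 1e-3          | —            | —           |
| myelin internode     | 0.02         | 2e-5          | —            | —           |
| node/terminal/axon   | 1.0          | 5e-3          | 3.0          | 0.08        |

Axial resistivity 100 Ω·cm; E_Na = +50 mV, E_K = −90 mV.  Active
compartments carry classic squid-type m³h/n⁴ kinetics with Q10 = 2.3
acceleration to 37 °C; the nodal sodium density (3.0 S/cm²) is in the range
used for nodal membrane and keeps spiking robust at body temperature, where
the original squid parameters would heat-block.  The leak reversal of every
compartment is balanced so the resting state sits exactly at v_init
(−70 mV); a 20 ms unstimulated settling run (computed once per cell and
cached) precedes every stimulus regardless.

Consequently absolute thresholds are model-specific — O(10–100) V/m for the
default cells, the right order of magnitude for TMS but not calibrated —
and only structural behaviour (direction/decay sensitivity, monotone
recruitment, the 1/cosθ straight-axon limit) is asserted anywhere.

## Numerics

- **Integrator.**  Backward Euler on the branched cable, solved per step by
  Thomas-style elimination in Hines order (unconditionally stable at 5 µs).
  Gating variables use exact exponential updates with rates evaluated in a
  predictor–corrector pass (predictor at the old voltage, corrector at the
  midpoint), which brings the threshold discretization error at dt = 5 µs
  vs 2.5 µs to ≈ 0.5% on the ball-and-stick cell (tested bound: < 2%).
- **Quasipotential quadrature.**  Trapezoid rule on E·dl between
  compartment centers: exact for uniform fields (path independence to 1e−9
  relative on random trees) and for the linear decay profile along straight
  edges.  The reference potential is fixed to 0 at the root compartment;
  cable dynamics only see differences.
- **Discretization.**  Sections split into ceil(L/20 µm) equal-arc
  compartments; the sealed-end passive cable matches the analytic
  E·λ·tanh(L/λ) terminal polarization within 2% at 5 µm resolution
  (converging under refinement; at 20 µm the centered sampling of the last
  compartment dominates the error at ≈ 2.6%).
- **Threshold search.**  Amplitude 0 never fires (the drive is linear in
  amplitude), so the bracket starts at [0, 50 V/m], doubles until firing
  (cap 1e5 V/m → "not excitable" sentinel, distinct from an error), then
  bisects to 0.05 V/m.  AP criterion: upward crossing of 0 mV in ≥ 3
  compartments anywhere on the cell (the conventional crossing voltage; the
  source convention for "three compartments" does not specify branch
  locality).
- **Averaging.**  φ is sampled on [0°, 360°) half-open so 0 ≡ 360 is not
  double-weighted.  Non-excitable sentinels are excluded from bin means and
  their fraction reported; CI rule: 1.96·SE (normal approximation), stated
  in the map metadata because percentile-based alternatives exist.
- **Recruitment fit.**  The "integration of thresholds along the field
  magnitude" is implemented as the empirical CDF of the pooled
  (cells × φ) thresholds; the sigmoid fit is nonlinear least squares with
  r > 0, initialized at E0 = median, r = 1.1/IQR.  Degenerate bins (all
  thresholds equal) get an explicit step-like representation instead of an
  ill-posed fit.  Recovery bounds verified: r within 10% and E0 within 2%
  (n = 50, noise σ = 0.01) across 100 seeded replicates.
- **gPC.**  Basis orthonormal under the input measure: Legendre for
  uniform, Jacobi for beta with α = q−1, β = p−1 on the standardized
  support (both beta conventions circulate; this mapping is verified by a
  Monte-Carlo Gram-matrix test).  Coefficients by seeded least-squares
  collocation with ≥ 2× (default 2.5×) oversampling; the condition number
  is checked and reported.  Sobol indices are ratios of squared coefficient
  groups and sum to 1 by construction.
- **Verification metrics.**  NRMSE = ‖y_ref − y‖/‖y_ref‖,
  MAPE = mean|Δ/y_ref|.  The primary R² normalizes the residual by the
  variance of the *reduced* model about its own mean — an unconventional
  form kept verbatim for comparability — and a conventional R² (reference
  variance) is reported alongside, clearly labeled.
- **Cosine baseline.**  y(θ) = ŷ/|cosθ| with ŷ = 233.66 V/m by default;
  the θ = 90° singularity returns an unbounded sentinel (optionally capped
  for plotting).  The contrast that motivates the full model is reproduced
  at desk scale: branched synthetic cells keep finite thresholds at
  tangential incidence where the cosine model diverges.

## Synthetic patch verification

`generate_synthetic_patch` draws per-element normals uniformly on the
sphere, θ from beta(1.51, 1.56) on [0, 180]°, Δ|Ẽ| from beta(13.86, 13.78)
on [−30, 30] %/mm, and lognormal field magnitudes; the marginals are
KS-tested against the generating distributions.  Element fields lie exactly
in the parameterized-field family, so verifying a map against a patch is a
closure experiment: the reference (direct per-element threshold searches
over cells × the same azimuth set used in the map build) differs from the
map lookup only through bilinear interpolation between grid nodes.
Measured at the reduced grid (θ step 15°, φ step 30°, Δ step 20 %/mm,
5 cells, 500 elements): MAPE ≈ 0.7%, 1st/99th percentiles of relative
differences ≈ ±1.7% (tested bounds: 1% and ±2%).  Patches do not emulate
spatially correlated field structure (gyral crowns, sulcal walls), so
systematic distortions across a neuron — the dominant residual in realistic
settings — are absent here by construction.

## Known limitations

- No FEM field computation, head models, conductivity tensors or coil
  models; fields are always the two-parameter family.
- Membrane model is generic (see above); species scaling of morphologies is
  exposed (`apply_scaling`) but defaults to identity rather than inventing
  calibration factors.
- Recorded stimulator waveforms are replaced by analytic stand-ins (damped
  half-sine/cosine, period 280 µs; trapezoid 60/30/43.2 µs); all are
  normalized to unit peak, so thresholds scale accordingly.
- Repetitive protocols, synaptic activity and network effects are out of
  scope; simulations cover a single 1 ms pulse from rest.
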