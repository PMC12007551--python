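# tmsresponse

Average response models of cortical neurons under transcranial magnetic
stimulation (TMS).

Direct biophysical modeling of TMS couples the induced electric field into
multicompartment neuron models and finds, per neuron and field
configuration, the minimum field magnitude that triggers action potentials.
That is accurate but far too slow for routine use (mapping, dosing), because
every cortical location and neuron needs its own cable simulation.  This
package implements the *reduced average-response* approach: the firing
threshold of a neuron population is precomputed as a function of just two
local field parameters — the polar angle θ between the field and the
somato-dendritic axis, and the relative field change Δ|Ẽ| (%/mm) along that
axis — and averaged over cells and azimuthal orientation φ.  Applying the
model afterwards is a table lookup, yet it closely tracks per-neuron
reference simulation.

It is aimed at researchers in computational neurostimulation who want a
transparent, self-contained re-implementation of that pipeline on synthetic
neuron populations (detailed reconstructed cortical cells and FEM head
models are external resources and are deliberately out of scope).

## Model summary

- **Field parameterization.**
  `E(z) = E_soma · u(θ, φ) · max(Δ|Ẽ|/100 · (z − z_soma) + 1, 0)` with
  `u = (sinθcosφ, sinθsinφ, cosθ)`, z in mm.  At threshold, `E_soma = E_thres`.
- **Coupling.**  The field enters the cable equation as an extracellular
  quasipotential `φ_e(z) = −∫ E·dl`, accumulated along the neurite tree
  (trapezoid rule, exact for the linear profile above) and scaled by the
  normalized pulse waveform and amplitude.
- **Cable dynamics.**  Branched cable equation with Hodgkin–Huxley-type
  membrane (active nodes of Ranvier/terminals, passive myelin and
  soma/dendrites), backward Euler with a Hines-ordered tree solve at
  dt = 5 µs, 1 ms window, 37 °C, v_init = −70 mV.  Threshold = minimum
  soma-level field magnitude eliciting action potentials in ≥ 3
  compartments, found by binary search to 0.05 V/m.
- **Reduction.**  Thresholds on the grid θ ∈ [0,180]° (3°), φ ∈ [0,360)°
  (6°), Δ|Ẽ| ∈ [−100,100] %/mm (10) are averaged over cells × φ into a
  (θ, Δ|Ẽ|) map with 95% CIs; the pooled threshold CDF per bin is smoothed
  by the recruitment sigmoid `f(E) = (1 + e^{−r(E−E0)})^{−1}`.
- **Surrogate & sensitivity.**  A generalized polynomial-chaos expansion
  (order 15 ⇒ 136 coefficients for 2 parameters; Legendre/Jacobi bases
  matched to uniform/beta inputs) gives a matrix-form threshold estimator
  `Ψc = y` and analytic first/second-order Sobol indices.
- **Verification.**  On synthetic cortical patches with beta-distributed
  θ (p=1.51, q=1.56 on [0,180]°) and Δ|Ẽ| (p=13.86, q=13.78 on
  [−30,30] %/mm), the map prediction is compared against direct per-element
  reference simulation via NRMSE, MAPE, R² and 1st/99th percentiles of the
  relative differences.  Baselines: the cortical-column cosine model
  `y(θ) = ŷ/|cosθ|` and a myelinated straight-axon ball-and-stick cell
  (l = 760 µm, d = 15 µm).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from tmsresponse import (MembraneModel, SimConfig, make_waveform,
                         generate_synthetic_population)
from tmsresponse.response_model import (build_threshold_grid, average_map,
                                        recruitment_surface, interpolate_threshold)

cfg, mm = SimConfig(), MembraneModel()
wave = make_waveform("monophasic", dt=cfg.dt)
cells = generate_synthetic_population(3, "pyramidal_like", seed=42)

grid = build_threshold_grid(
    cells, wave, cfg, mm,
    theta_axis=np.arange(0, 180.1, 45.0),
    phi_axis=np.arange(0, 360, 90.0),
    delta_axis=np.array([-20.0, 0.0, 20.0]),
)
amap = average_map(grid)
print(np.round(amap.mean, 1))          # V/m, rows = theta, cols = delta
print(round(interpolate_threshold(amap, 22.5, 0.0), 1))

surf = recruitment_surface(grid)
sig = surf.sigmoid_at(90.0, 0.0)
print(round(sig.E0, 1), round(sig.r, 3))
```

Output (V/m; exact values depend on the built-in membrane model):

```
[[ 77.   89.8 106.8]
 [ 69.7  79.1  91.2]
 [ 71.   77.2  84.5]
 [ 32.3  36.   40.6]
 [ 23.   25.6  28.9]]
84.5
59.2 0.102
```

Rows sweep θ (0…180°), columns Δ|Ẽ| (−20, 0, +20 %/mm).  Thresholds are
lowest at θ = 180°, where the field points from dendrites toward the axon
(orthodromic for an axon extending toward −z), and highest for tangential
incidence and positive field change.  The interpolated value 84.5 V/m sits
between the θ = 0° and 45° rows.  At θ = 90°, `E0 = 59.2 V/m` is the
half-recruitment field of the pooled population and `r = 0.102 (V/m)⁻¹` its
slope.

The same steps are available from the shell:

```bash
tmsresponse generate-cells --archetype pyramidal_like --n 3 --seed 42 --out cells/
tmsresponse build-map --cells cells/ --theta-step 45 --phi-step 90 \
    --delta-step 20 --delta-range 20 --out map.h5 --grid-out grid.h5
tmsresponse recruitment --grid grid.h5 --theta 90 --delta 0
tmsresponse gpc --map map.h5 --order 6 --out gpc.json && tmsresponse sobol --model gpc.json
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end pipeline from scratch at desk scale: a
seeded synthetic population, the threshold-grid sweep and averaged map,
recruitment-sigmoid fits, the polynomial-chaos surrogate with Sobol
indices, and the patch verification against direct reference simulation,
logging the summary metrics to stderr and writing the results JSON to
`--out`.  The quantitative guarantees (analytic cable limits, search
correctness, closure bounds) live in `tests/test_acceptance.py`.
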