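# cawave

Simulation of intercellular Ca²⁺ wave dynamics in coupled endothelial-cell
(EC) / smooth-muscle-cell (SMC) populations tiled over idealised arterial
tube and Y-bifurcation surfaces.

Preferential sites of atherosclerosis correlate with low wall shear stress,
reduced luminal ATP, and hence reduced IP₃/Ca²⁺ signalling in the arterial
wall. `cawave` is for researchers who want to study how a spatially varying
agonist (ATP → J_PLC) map and different gap-junction coupling regimes —
healthy or pathological connexin expression — shape macro-scale Ca²⁺ wave
propagation across hundreds of thousands of coupled cells, at desk scale
rather than on a supercomputer.

## The model

Each SMC carries five ODEs (cytosolic Ca²⁺ `c`, store Ca²⁺ `s`, membrane
potential `v`, K⁺-channel open fraction `w`, IP₃ `I`) and each EC four
(`c`, `s`, `v`, `I`).  The oscillation engine is IP₃-sensitised
calcium-induced calcium release:

```
SMC:  dc/dt = J_IP3(I) − J_SERCA(c) + J_CICR(c,s) − J_extr(c,v) + J_leak(s)
              − J_VOCC(v) + J_Na/Ca(c,v) + coupling
      ds/dt = J_SERCA − J_CICR − J_leak
      dv/dt = γ(−J_Na/K − J_Cl − 2 J_VOCC − J_Na/Ca − J_K) + coupling
      dw/dt = λ (K_act(c,v) − w)
      dI/dt = −k I + coupling

EC:   dI/dt = J_PLC − k I + coupling      (agonist enters here only)
      dv/dt = −(I_BKCa+SKCa + I_R)/C_m + coupling
```

with units μM, mV, s.  Gap-junction coupling is linear gradient exchange,
`g·Σ(x_k − x_self)`, homocellularly on each layer's 4-neighbour grid
(circumferentially periodic) and heterocellularly between each EC and the
13 SMCs of its fundamental unit.  Four coupling cases select which species
(V, Ca²⁺, IP₃) pass which junctions, modelling healthy tissue through
progressive atheroma (Cx43/IP₃-only communication).

Surfaces are generated by patchwise solves of the anisotropic biharmonic
equation `(∂²/∂u² + a²∂²/∂v²)² φ = 0` (the classic PDE surface-design
method), stitched into a pair-of-pants bifurcation, and tiled with
physiological cell footprints: 5 ECs (65×10 μm, axial) + 13 SMCs (50×5 μm,
circumferential) per fundamental unit, 4×4 units = 288 cells per
quadrilateral domain.  An 8.84 mm / Ø 2.55 mm symmetric bifurcation
resolves to Q = 4080 quads and 1,175,040 cells.

Agonist maps assign each EC a J_PLC value (μM/s): an axial sigmoid, a
reduced 2D channel ATP-transport solve with a reactive (Robin) wall, or a
user file.  Time integration uses adaptive Runge–Kutta/BDF, either
monolithically or with per-quad domains exchanging frozen ghost states at a
fixed communication interval (0.01 s), matching the communication pattern
of massively parallel implementations.

## Worked example

Locate the agonist window of a single coupled EC/SMC unit, then run a small
tube:

```python
from cawave import bifurcation_sweep
diag = bifurcation_sweep(1, j_plc_range=(2.0, 5.0))
print(diag.lower_threshold)    # 3.699
```

The value is the lower Hopf-type onset (in μM/s of J_PLC at the EC): below
it the SMC Ca²⁺ is steady, above it the unit oscillates.  Case 4 coupling
(IP₃-only heterocellular exchange, progressive atheroma) shifts the onset
to ≈ 2.97 — the pathological tissue starts oscillating at weaker agonist.

```console
$ cawave simulate --config cfg.yaml --case 1 --mesh tube --out out --vtu
cawave mesh: 8 quads, 640 EC, 1664 SMC (10880 ODEs)
cawave agonist: sigmoid, J_PLC range [2.73, 4.27] uM/s
cawave wrote 3 snapshots to out
```

`out/state.h5` holds per-second snapshots of all state variables;
`snap_*.vtu` are ParaView-ready surface files with per-cell Ca²⁺, IP₃,
membrane potential and layer tags.  `cawave analyze sweep|spacetime`
produce bifurcation diagrams and space–time (kymograph) maps; on a tube
with a sigmoid agonist map spanning the oscillatory window, SMC Ca²⁺ waves
propagate toward decreasing agonist and invade the formally steady region
below the lower threshold.

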