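# Methods

## Cell models

The SMC (5 ODEs) and EC (4 ODEs) follow the Koenigsberger-family lumped
pathway models of arterial coupled cells: IP₃-receptor store release,
SERCA uptake, calcium-induced calcium release (CICR), voltage-operated
Ca²⁺ channels (SMC), Na⁺/Ca²⁺ exchange, Ca²⁺-gated K⁺ channels, and a
non-selective Ca²⁺-activated cation channel plus BKCa/SKCa currents in the
EC.  All parameters live in `src/cawave/params/default_parameters.txt`,
one symbol per line with value, unit and description; that file is the
single transcription of the model and the test suite checks it against an
independent symbolic (sympy) transcription to 10⁻¹² relative.

Two points deserve emphasis:

* The EC K⁺ current needs **both** the BKCa term (jointly gated by voltage
  and Ca²⁺, opening only at several μM Ca²⁺) and the SKCa term (gated by
  Ca²⁺ alone, midpoint ≈ 0.5 μM).  The SKCa pathway is what hyperpolarises
  a stimulated EC to ≈ −70 mV; without it the heterocellular electrical
  coupling acts with the wrong sign on the SMC oscillation threshold and
  the healthy/pathological ordering of the agonist windows inverts.
* States are never clamped: a transcription error that drives a
  concentration negative should fail loudly (the `log₁₀(Ca)` terms use a
  10⁻¹² floor only to keep the RHS finite during root-finding excursions).

Units are μM, mV, s; J_PLC (the agonist input, IP₃ production at the EC)
is in μM/s and enters only the EC IP₃ equation.

**Initial conditions.** The literature rarely states them; `cawave` uses a
reproducible convention: the isolated-cell rest state at J_PLC = 0, found
by 500 s of relaxation integration followed by root polishing
(`rest_state`), replicated over the tissue.  An optional seeded Ca²⁺
perturbation (`TissueModel.initial_state(ca_noise=...)`) breaks the exact
symmetry of the meshes when symmetric locking is a concern; it defaults to
off, and none of the shipped results depend on it.

## Coupling

Gap-junction exchange is linear in the concentration/potential gradient;
the electro-diffusive drift contribution to V coupling is neglected
(documented as negligible for this model family).  Defaults:

| rate | value | origin |
| --- | --- | --- |
| `g_v_homo` | 1000 s⁻¹ | homocellular electrical coupling, both layers |
| `g_chem_homo` | 0.05 s⁻¹ | homocellular Ca²⁺ and IP₃ coupling |
| `g_v_hetero` | 50 s⁻¹ | heterocellular electrical coupling |
| `g_ca_hetero` | 0.05 s⁻¹ | heterocellular Ca²⁺ coupling (cases 2–3) |
| `g_ip3_hetero` | 0.0026 s⁻¹ | heterocellular IP₃ coupling, calibrated |

The heterocellular IP₃ rate is not published in rate units; it was
calibrated **once** so that the Case-1 single-unit sweep places the lower
oscillation onset at 3.70 μM/s, and never revisited.  Case 4 then lands at
2.97 μM/s independently, which is the strongest internal check of the
calibration: the shift is produced entirely by removing the electrical
heterocellular pathway, not by further tuning.  Its small magnitude
relative to `g_chem_homo` is consistent with the low homotypic connexin
permeability of IP₃.

**Heterocellular weights.** Within a fundamental unit every EC overlaps
every SMC in an identical 5×10 μm rectangle, so overlap weights are
uniform.  Fluxes are normalised per receiving cell: an EC averages its 13
SMC partners, an SMC its 5 EC partners.  Because the EC:SMC footprint area
ratio is 650:250 = 13:5, this is exactly equal-and-opposite **molar** flux
through each junction (concentration rates scale inversely with lumped
cell volume).  It also makes a homogeneous tissue behave identically to
the single coupled unit, so the unit bifurcation diagram transfers to the
tissue — without this property the tissue's oscillatory window sits at a
different agonist level than the unit diagram used to interpret it.

## Surface generation

Patches solve `(∂²/∂u² + a²∂²/∂v²)² φ = 0` per coordinate with a 13-point
stencil on the unit-spaced parameter grid; Dirichlet edge positions are
imposed exactly and Neumann cross-derivatives through one ghost layer.
Each tubular segment is two half-tube patches; the Y-junction stitches
three segments along three shared seam curves (two parent/branch seams on
the parent cylinder and the exact branch/branch intersection ellipse
through the crotch), sampled once and reused verbatim so the mesh is
watertight by construction.

**Anisotropy `a`.** The default is 0.1, not 1.  With `a ≈ 1` the interior
of a long patch relaxes toward a cubic blend of its edge data and a
half-tube cross-section flattens by ~20%; with a small `a` the
cross-sectional boundary data propagates stiffly along the axis and the
deviation from an exact cylinder scales as O((a·k·m)⁴), well below the 1%
acceptance bound for the shipped geometries (measured at ~10⁻⁶ of the
diameter on the 10-quad-long test tube).  The acceptance check (cylinder
within 1%) measures this directly.

Quads are 260 μm (axial) × 200 μm (circumferential), carrying 4×4
fundamental units of 5 ECs + 13 SMCs (288 cells, 80 EC + 208 SMC).  These
footprints, applied to a branch length of 8.84 mm and diameter 2.55 mm at
a 30° branch angle, give m = 34, n = 40 per segment and hence Q = 4080
quads / 1,175,040 cells; the larger published configuration (10.92 mm,
Ø 4.08 mm) gives Q = 8064.  Near the junction quads distort (the carina
seam stretches them); cell counts per quad stay fixed, an acknowledged
tessellation artefact of this construction.  Axial (centreline)
coordinates are negative in the parent, zero at the bifurcation point and
positive in the branches.

## Agonist maps

The sigmoid map is a logistic function of the axial coordinate only
(circumferentially uniform), defaulting to j_min = 2.0, j_max = 5.5 μM/s
— bracketing the Case-1 oscillatory window so the canonical demo contains
steady, oscillatory and steady bands — centred on the bifurcation point
with steepness 2 mm⁻¹.  ATP→J_PLC conversion is affine and floored at
zero; the default slope 10 (μM/s)/μM maps the 0.1 μM inlet concentration
of the transport module to 1 μM/s.

The reduced transport module solves steady advection–diffusion over a 2D
half-channel with prescribed Poiseuille flow (the full 3D Navier–Stokes
stage is out of scope; maps from external CFD can be loaded from file).
The wall is reactive: `D ∂φ/∂y = Kφ − S`, `S = S_max τ_w/τ_m`, i.e.
hydrolysis against shear-dependent production.  K, τ_m, S_max and the flow
parameters are user-calibration values (defaults: K = 2×10⁻³ mm/s,
τ_m = 1 Pa, S_max = 10⁻⁴ μM·mm/s, D = 2.36×10⁻⁴ mm²/s, U = 10 mm/s,
ν = 3.5 mm²/s, ρ = 1050 kg/m³).  Discretisation is finite-volume with
first-order upwind advection (robust at Péclet ~10⁵) and central
diffusion; the Robin condition is linearised through the near-wall cell
(unconditionally stable) and certified by a self-consistency loop to
10⁻⁸.  Face-wise assembly makes the discrete species balance close to
solver precision; the suite requires < 0.1%.

## Time integration

The reference mode integrates the whole tissue monolithically with scipy's
BDF using the model's sparse Jacobian pattern (dense 4×4/5×5 intra-cell
blocks plus coupled-species neighbour entries); the electrical coupling at
1000 s⁻¹ makes the system stiff enough that explicit methods need
~3×10⁻⁴ s steps.  The decomposed mode mirrors the parallel reference
implementation: one quad = one domain, each domain integrating its 1360
ODEs adaptively inside a 0.01 s communication interval while cross-domain
neighbours are frozen at start-of-interval values (zeroth-order ghost
hold — the exchange order is not interpolated because the reference
implementation exchanges raw edge states at a fixed cadence).  The
`parallel` backend runs the same per-domain solves in a process pool;
because the frozen-ghost contract fixes every solver input, serial and
parallel runs are bitwise identical, which the suite verifies.  Shrinking
the communication interval converges the decomposed solution to the
monolithic one (verified on a two-interval pair).

Snapshots go to HDF5 (one group per snapshot, per-variable datasets,
geometry and config echoed as attributes) every second of physiological
time by default, and optionally to ASCII VTU (one quad cell per biological
cell with Ca²⁺/IP₃/V/layer cell data) for ParaView.

## Analysis

The single-unit bifurcation sweep integrates one heterocellularly coupled
EC/SMC pair per J_PLC value for 200 s (settle) + 300 s (measurement) with
LSODA at rtol 10⁻⁸, classifies oscillation as peak-to-peak SMC Ca²⁺
exceeding 1% of the window mean — with a decay guard (second-half
amplitude must exceed half the first-half amplitude) so slowly decaying
transients near the Hopf points are not miscounted — and bisects the
onsets to 0.01 μM/s.  Thresholds are stable to ±0.02 μM/s under halved
tolerances and doubled windows.

Space–time maps sample one SMC per axial ring along a wall line (default a
quarter-turn from the top pole, continuing into the first branch on a
bifurcation).  Wave metrics report per-position amplitude and period
(peak spacing), a band-edge front trajectory from windowed amplitude
exceedance, and a crest propagation direction estimated from
cross-correlation lags between separated oscillatory positions — the
band-edge front is ill-defined while start-up transients ring, so the
phase direction is the robust indicator of propagation against the
agonist gradient.

## Scaling choices and what the tests show

Full-scale runs (Q = 4080, 10.6M ODEs, 1000 s) are cluster work.  The
shipped wave-dynamics checks run a 16-quad tube (4,608 cells, 21,760
ODEs) for 170 s with a steepened sigmoid spanning the oscillatory window;
because the agonist is circumferentially uniform, the tube's dynamics
reduce exactly to an axial chain, so the narrow circumference loses no
physics for this purpose.  On that tube, Case-1 waves ring up in the
high-agonist band, their crests travel upstream (toward decreasing
agonist), and the sustained oscillatory band extends upstream past the
axial position where the local J_PLC equals the single-unit lower
threshold — the same excitability-driven invasion seen at full scale —
while the low-agonist inlet stays quiet.  What these tests do **not**
show: spiral-wave formation, wave-packet phenomenology and the ~200 s
full-geometry upstream-crossing time, which need the large meshes.

The synthetic fixtures emulate idealised geometry (perfect symmetric
bifurcations, uniform cell sizes) and noiseless dynamics; real tissue has
irregular cell orientation near bifurcations, heterogeneous coupling and
stochastic channel gating, none of which are modelled (lumped deterministic
cells, single SMC layer, no NO/eNOS chemistry).

## Numerical odds and ends

* Seam/node merge tolerance 10⁻⁹ mm; quad (u,v) indexing 0-based, u
  increasing downstream, v counter-clockwise viewed from the inlet.
* `bifurcation_sweep` scans at 0.5 μM/s then bisects; degenerate ranges
  (no oscillatory point, or oscillation at the range edge) return `None`
  thresholds rather than extrapolating.
* The ODE count of a mesh is 4 per EC + 5 per SMC (10,575,360 for the
  Q = 4080 mesh).
* Integrator failures name the domain and time; the rest-state search
  refuses to return a point when the residual indicates an oscillatory
  regime.
* The CLI (`cawave simulate|analyze|fixtures`) is a thin wrapper; all
  functionality is importable.
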