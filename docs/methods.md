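# Methods

This note records the models implemented in `pulmoasl`, the defaults and
their provenance, the design choices that were genuinely open, and what the
synthetic geometry does and does not emulate.

## Coordinate frame and domain

Right-handed mm frame: x runs lateral(−) → medial(+), y dorsal(−) →
ventral(+), z caudal(−) → cranial(+). The lung is a half-ellipsoid
(semi-axes 75, 75, 110 mm; the flat medial face is the plane x = 0) so the
five default 15 mm sagittal slices tile x ∈ [−75, 0], slice 1 most lateral,
slice 5 against the hilum. The hilum — entry of the trunk and exit of the
veins — sits on the medial face at y = −22.5 mm, displaced dorsally as the
lung root is in the chest.

Two structural features of the generator are load-bearing for the analysis
and deliberate:

* **Medial conduit concentration.** Both trees root at the hilum, so the
  largest vessels (and hence the brightest, conduit-dominated voxels) lie
  in the medial slices, while lateral slices are perfusion-dominated.
* **Dorsal density gradient** (`dorsal_density_bias`, default 0.35).
  Terminal-unit density rises linearly toward the dorsal face (~1.9:1
  dorsal:ventral across the full extent). Real lungs have higher dorsal
  tissue and vascular density; this gravity-independent structural
  preference is why prone perfusion is flatter than supine rather than its
  mirror image, and it is required for the supine > prone heterogeneity
  direction to emerge. A dorsoventrally symmetric stand-in cannot show it.

## Network generation

Volume-filling branching: n terminal seed points are sampled in the domain
(rejection sampling with the dorsal weighting), then recursively bisected
by the plane through the sub-cloud's centre of mass perpendicular to its
principal axis; a branch extends from the parent tip toward each
sub-cloud's centroid, scaled by the length fraction (0.4) with a 2 mm
minimum and clamped inside the domain. A cloud of one point terminates the
branch exactly at the point. Branching is strictly binary, so an n-terminal
tree has exactly 2n − 1 elements. Ties in degenerate bisections are broken
by lowest point index; all randomness is fixed by the seed. The venous tree
is grown over the same seed points from a slightly ventrally offset root
(arteries and veins run broadly parallel in the lung), and each arterial
terminal couples to the nearest venous terminal through an
arteriole (1 mm) → capillary sheet (1 mm) → venule (1 mm) unit aimed toward
the hilum.

Radii: terminal arterioles and venules take the configured terminal radius;
conduit radii follow Murray's law r_p^k = Σ r_c^k (k = 3) propagated
root-ward; capillaries carry a nominal 0.05 mm table radius (their
hydraulics come from the sheet model, not from a tube). The trunk radius
(15 mm default) overrides the inlet element, and symmetrically the outlet
vein.

### Desk-scale parameter choices

The bundled study conditions (`pulmoasl.demo`) use 1000 terminal units,
each lumping roughly 30 real acini. Two parameters are set accordingly
rather than from the config defaults:

* terminal arteriole radius 0.6 → **0.5 mm in the demo**: a vessel feeding
  1/1000 of cardiac output at 0.1 mm radius would drop >100 mmHg and carry
  blood at >10 m/s; 0.5 mm reproduces small-artery mean velocities near
  100 mm/s and keeps the microcirculation, not the arterioles, as the
  dominant resistance.
* per-unit sheet area 15 000 mm²: at the operating thickness (~5 µm) this
  puts total capillary blood near the textbook ~75 mL and the mean
  capillary transit near 0.9 s at 5 L/min. Both matter for the ASL signal:
  the transit sets how much of the sheet's blood is replaced by fresh
  (fully magnetized) blood within one TI.

## Hemodynamics

Pressures in Pa, lengths mm, flows mm³/s (so Poiseuille resistance
8µL/(πr⁴) is in Pa·s/mm³ without conversion factors). Blood: density
1050 kg/m³, viscosity 3.36 mPa·s, apparent microvascular viscosity
1.92 mPa·s for arterioles/venules — standard pulmonary-modeling values,
configurable.

* **Conduits** (arteries, veins): Poiseuille resistance at the distended
  radius plus a hydrostatic source ρg(h_in − h_out) along the centerline;
  supine gravity points dorsal (−y), prone reverses it. Distension is
  linear, r = r0(1 + 0.02·Ptm[cmH₂O]) capped at 1.5 r0, with no collapse
  below zero transmural pressure — the simplest law with the right
  qualitative behavior, as the underlying pressure–area relation is not
  otherwise constrained.
* **Arterioles/venules**: rigid Poiseuille tubes; they are short enough
  that gravity within them is neglected.
* **Capillary sheets** (Fung–Sobin): thickness h = clamp(h0 + α·Ptm, 0,
  h_max) for Ptm > 0 (h0 = 3.5 µm, α = 0.127 µm/cmH₂O, h_max = 7 µm),
  collapsed to 0.01·h0 otherwise; flow = C_sheet·(h_a⁴ − h_v,eff⁴)·f with
  zone-2 sluicing (h_v,eff = h0 whenever the venular transmural pressure is
  non-positive, making the flow independent of downstream pressure) and a
  recruitment factor f = clip(Ptm_a/10 cmH₂O, 0.1, 1). C_sheet is
  calibrated per network by bisection so the trunk-to-atrium drop at
  5 L/min is ~10 mmHg; the calibration is logged and saturates with a
  warning if the conduit tree alone exceeds the target.

**Solver.** Each element is linearized to a conductance (conduits: 1/R at
current radius; capillaries: secant conductance of the sheet law, with a
small-signal fallback when the pressure difference vanishes) and the sparse
node-conservation system is solved with the inlet flow and outlet pressure
constraints; radii/thicknesses are then updated and the cycle repeats.
Three stabilizations matter in practice: pressure under-relaxation (0.5,
tightened automatically toward 0.95 when the residual stalls — the zone-2
switch otherwise produces a limit cycle at high sheet conductance),
geometric damping of the capillary secant conductance, and a final
undamped solve at the converged geometry so node conservation is
machine-exact (interior imbalance ~10⁻¹² of CO; tolerance 10⁻⁶ on the
relative pressure change, 200 iterations max, explicit failure with the
residual history otherwise). With distension off and a fixed capillary
conductance (`SheetParams.linear_conductance`) the problem is linear and
the solver reproduces a direct dense solve to 10⁻¹⁰ — the oracle used in
the tests.

Velocity conventions: conduits v = Q/(πr²) (V_B = πr²L); capillaries
V_B = sheet area × thickness and v = Q·L/V_B, the plug-flow speed whose
transit time is V_B/Q. The capillary transit (~0.9 s at defaults) is what
the backward tracing sees.

## ASL forward model

Only the bright image is simulated; with no static tissue in the model it
stands for the bright-minus-dark difference image.

1. **Parcels.** Every element intersecting the 15 mm slab contributes
   sub-segments (≤ 1 mm; capillaries are additionally split by volume into
   ≥ 8 parcels so the fresh fraction of the sheet transit is resolved);
   each in-slab sub-segment becomes a parcel with its share of the element
   blood volume.
2. **Back-tracing.** Each parcel walks upstream consuming TI at the local
   velocity. Venous confluences split the parcel by flow fraction
   (sub-parcels below 10⁻⁶ mm³ are frozen at the junction); the arterial
   side has a unique parent. Walking out of the network inlet marks the
   parcel as fresh (outside the band) at the inlet position; a
   zero-velocity element freezes the parcel in place.
3. **Labeling profile.** The inversion band is the slice plus a 15 mm gap
   on each face. The parametric profile is a −1 plateau across the slice
   with error-function shoulders through the gap (scale = gap/4), even
   and monotone in each transition; a measured profile can be supplied as
   a (z_mm, m0) table. The profile is evaluated at the origin's signed
   slice-normal distance.
4. **Signal.** The two inversion-recovery expressions above; they agree at
   m0 = +1, fully inverted blood nulls exactly at TI = T1·ln 2 ≈ 901 ms,
   and negative (over-nulled) values are kept, not clamped.
5. **Voxelization.** In-plane 3 × 1.5 mm grid over the domain's y–z
   bounding box, one 15 mm cell through-plane, components kept per vessel
   class. A parcel wider than a voxel (a large conduit, or a capillary
   unit's tissue-territory footprint — the radius of the sphere holding
   the domain volume / n units, ~6.8 mm at 1000 units) is spread uniformly
   over the voxels its cross-section covers. A physical occupancy clamp
   caps each voxel's delivered blood at the voxel volume; excess from
   overlapping synthetic vessels is discarded and logged (signal is
   conserved exactly whenever vessels do not overlap). Voxels outside the
   lung cross-section are masked.

The ASL value is (signal-volume / 67.5 mm³) × 60000/TI, in mL/min/cm³; a
fully filled fresh voxel reads ≈ e^(−TE/T2) × 60000/TI ≈ 65 at TI = 800 ms.

## Thresholding and the cost function

Removal acts on the voxel **total** (components are never thresholded
separately): voxels strictly above (x/100)·67.5 are removed entirely, so
retained sets are nested as x decreases and x = 100 is the identity.
C_removed is implemented as the *removed* conduit fraction
1 − after/prior — the variable's name and its appearance as (1 − C_removed)
in the cost require it, although the defining sentence literally describes
the remaining fraction; the literal reading is available behind
`literal_c_removed=True`. ΔCOV and Δgrad are unitless fractional absolute
differences against the **unfiltered capillary component** (the underlying
perfusion); a zero reference drops the term with a logged warning. COV is
the population SD/mean over retained voxels; the gradient is an OLS slope
of per-bin mean signal against gravitational height (10 bins over the
retained extent, abscissa = each bin's member-mean height so exactly
linear fields are recovered exactly; height increases toward the
non-dependent side, so dependent-dominated flow has a negative slope).
Zero-denominator conventions: no conduit → C_removed = 1, no capillary →
Q_remain = 1, empty filtered grid → Q_fraction = 0. The optimum is the
argmin over the descending grid with ties broken toward larger x; the full
table is always retained because the minimum is often flat.

## Study orchestration

Scenario rows follow CO = HR × SV with TI = round(0.8 × 60000/HR) ms
(48 → 1000, 60 → 800, 72 → 667, 80 → 600, 86 → 558, 90 → 533, 96 → 500).
SV acts through the inlet flow, HR through TI — the flow model is steady
state, so these are the only channels available. Posture comparisons use a
paired two-sided t-test on per-slice COV and gradient differences (the test
choice is ours; α = 0.05), skipped with a warning below two pairs. Both
median and mean ASL are reported; the median is used for directional
checks. Reruns with the same seed and config are byte-identical.

## What the synthetic lung does and does not show

The generator reproduces the *structural pattern* the analysis depends on —
conduit blood medial, capillary units peripheral, dorsal structural flow
preference, gravity-dependent perfusion — but it is not a morphometric
lung: no lobes or fissures, no airway tree, one breathing state, desk-scale
acinar lumping, and vessels may geometrically overlap near the hilum.
Passing tests therefore demonstrate the behavior of the measurement and
filtering chain under a lung-like flow distribution, not subject-specific
values: per-slice COVs, gradients and optimal thresholds depend on the
geometry and will differ from any imaged lung. Directional statements
(medial vs lateral, SV vs HR, supine vs prone, the ΔCOV minimum at an
interior threshold) are the reproducible content, and those are what the
acceptance suite asserts, at 1000 terminals with fixed seeds. The
mid-lung slice (3) is used for the sweep-shape check: the most lateral
slice has too few conduit hot spots for a robust interior ΔCOV minimum and
the most medial slice has the noisiest perfusion reference.

## Numerical and edge-case choices

* Parcel quantum 1 mm; clipping error bounded by one sub-segment.
* Volume floor 10⁻⁶ mm³ for venous splitting; bounds parcel blow-up.
* Slice with no intersecting blood → empty parcel list → zero grid (valid).
* Sweep grid restricted to [5, 100] and strictly descending by contract.
* COV/gradient on degenerate inputs (one voxel, zero mean, one height bin)
  raise explicit errors rather than returning NaN; the sweep records the
  term as unavailable.
* All user-facing pressures accept mmHg/cmH₂O and flows L/min, converted
  with exact constants (1 mmHg = 133.322387415 Pa, 1 cmH₂O = 98.0665 Pa).
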