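# Methods

This note documents the models, numerical methods and design choices behind
`atriamap`, in the spirit of a methods appendix: what is simulated, which
knobs matter, and what the synthetic setting does and does not establish.

## Synthetic atrial geometry

The chamber is a star-shaped, ellipsoid-like closed surface (default
semi-axes 18 × 16 × 15 mm, i.e. a 3–3.6 cm chamber) built by mapping an
icosphere through an analytic radial function, with

* a Gaussian appendage bulge (amplitude 22 % of the local radius, angular
  width 0.45 rad), labeled and excluded from epi–endo agreement statistics
  because the balloon is far from it and its anatomy is deliberately crude;
* a smooth, seeded radial jitter (0.1 mm), so no two seeds produce the same
  chamber and the mesh is free of exact symmetries;
* three circular holes (SVC, IVC, tricuspid valve; radii 5/5/8 mm) whose
  rims are labeled boundary loops, and angular anatomical regions: the
  sinus-node (SAN) region anterolateral below the SVC ostium, the
  ganglionated-plexus region (RAGP) at the SVC–atrial junction, the
  interatrial/Bachmann region (IA) anterosuperiorly, and a coronary-sinus
  (CS) patch inferoseptally. No attempt is made to model trabeculae,
  pectinate muscles or the terminal crest.

Two surfaces coexist: the **open** anatomical surface (holes cut) bounds the
myocardium, and its fan-filled **closed** counterpart is the domain of the
inverse problem — mirroring the fact that the clinical device reconstructs
potentials on a closed virtual surface even though the real wall has ostia.
For the inverse problem the closed surface is refined by one midpoint
subdivision (N ≈ 2300 nodes, matching the 2048 virtual channels of the
device; the unrefined N ≈ 580 surface noticeably quantizes reconstructed
activation maps).

The wall is voxelized on the cubic lattice `(i+1/2)h` by keeping voxel
centers within `[0, thickness]` of the surface along the outward normal
(defaults: thickness 1.75 mm; h = 0.25 mm at full fidelity, 0.5 mm in the
desk profile). Fibers follow the simplest rule consistent with rule-based
atrial fiber models: circumferential about the SVC–IVC axis, projected onto
the wall tangent plane.

## Membrane models

**Detailed model (`crn`, config alias `ramirez`).** The
Courtemanche–Ramirez–Nattel atrial formulation (21 states) plus the
acetylcholine-activated K⁺ current
`g(ACh) = 10/(1 + 9.14/[ACh]^0.478)` (µM), which shortens APD₉₀ from
≈ 259 ms to ≈ 55 ms at 0.03 µM, CL 600 ms. The canine-specific parameter
adjustments of the same model family are not reproduced — the human
parameter set is used — because the properties the pipeline depends on
(wave shape, graded ACh shortening, APD < 300 ms) are preserved and are
what the tests assert. Gates are integrated with Rush–Larsen exponential
steps (the m-gate time constant is ~8 µs at rest, below the 20 µs step;
forward Euler on the gates is unstable there), voltage and concentrations
with forward Euler at dt ≤ 20 µs. A 20 µs trace matches a 1 µs reference
within 2 mV RMS over a beat.

**Surrogate (`surrogate`).** A Mitchell–Schaeffer-type two-variable model
(τ_in = 0.3 ms, τ_out = 6 ms, τ_open = 120 ms, v_gate = 0.13; resting
−80 mV, peak ≈ +25 mV) whose APD₉₀ is a *direct parameter* (default
180 ms). The closed-form plateau duration `τ_close · ln(τ_out/4τ_in)`
under-predicts APD by the slow-passage and tail contributions (~35 ms), so
the APD→τ_close map is an affine calibration measured once per parameter
set from two single-cell runs; measured APD₉₀ then tracks the parameter to
< 1 %. ACh acts through a saturating dose–response
`APD_eff = APD · (1 − 0.45·[ACh]/([ACh]+0.01 µM))` — ≈ 34 % shortening at
0.03 µM, deliberately milder than the detailed model so that desk-scale
repolarization gradients stay in a physiological range.

## Monodomain solver

`beta (Cm dVm/dt + I_ion) = div(sigma grad Vm) + I_stim` with
`sigma = sigma_t I + (sigma_l − sigma_t) f fᵀ`, sigma_l = 12 mS/cm,
anisotropy 3:1, beta = 2000 cm⁻¹, Cm = 1 µF/cm² (diffusivities 0.6 /
0.2 mm²/ms). The spatial operator is a conservative face-flux stencil:
normal fluxes from face-averaged tensors, tangential derivatives from
averaged one-sided/central differences, each interior face visited once and
accumulated with opposite signs — so the total transmembrane current of an
unstimulated no-flux domain vanishes to rounding, and no-flux boundaries
are simply zero-flux faces. Explicit time stepping with
`dt ≤ 0.7 h²/(2(d_l + 2 d_t))`, snapped to an integer divisor of the 1 ms
output interval. Measured behavior on strip/slab fixtures: CV ≈ 0.82 mm/ms
longitudinally, CV ∝ √sigma, CV_L/CV_T = √3 ± 1 %, CV change < 5 % upon
halving h.

Pacing: 2 ms, 40 mV/ms injections at the SAN-region voxels at CL 600 ms.
After every beat APD₉₀ is evaluated at 20 seeded probe voxels; the run
stops at the first beat whose maximal relative APD change is below 1 %
(cap 10 beats) and that beat is the analyzed one. The surrogate converges
at the second beat on the default fixture.

Transmembrane current for electrograms is the discrete divergence of the
intracellular flux (same stencil, volume-weighted), which equals
`beta(Cm dVm/dt + I_ion) − I_stim` up to truncation error.

## Electrograms

Unipolar potentials use the infinite-volume-conductor current-source sum
with one source per voxel; sigma_o is arbitrary (default 1) because every
downstream statistic is amplitude-normalized. For sources within 3h of an
electrode the 1/r gain is replaced by a subdivided-voxel quadrature (4³
within h, 2³ beyond) that converges to the distributed-source volume
integral; without it, desk-resolution (h = 0.5 mm) reference electrograms
at the surface carry discretization graininess that contaminates
ATa statistics (control-run epi–endo ATa r rises from 0.72 to 0.96 with the
refinement). Bipolar electrograms are differences of unipolar pairs
< 5 mm apart; default probe pairs are oriented along the expected local
propagation direction (tangential component of the SAN→site vector), the
orientation a contact bipolar catheter is normally given.

## Boundary-element inverse

Green's second identity for the source-free blood pool gives the interior
and boundary collocation relations; per-triangle integrals are analytic
(van Oosterom–Strackee arctangent for the solid angle, the Wilton/Rao
line-integral formula for `∫ 1/r dS`, finite in the singular case) and are
distributed to the three vertices in equal thirds — a constant-basis
quadrature of the piecewise-linear field that preserves the closure
invariants exactly (interior solid angles sum to 4π, double-layer rows sum
to 1 after auto-solid-angle completion, `T_ec 1 = 1`). Eliminating the
normal derivative requires inverting the single-layer matrix (the
row-sum-1 double-layer matrix annihilates constants and cannot be the one
inverted):

```
T_ec = S_ec + O_ec O_ee⁻¹ (I − S_ee),   T_ce = T_ecᵀ (T_ec T_ecᵀ + λI)⁻¹.
```

Forward accuracy against exterior point sources (harmonic-field oracle):
relative RMS error 0.3 % at N ≈ 2500, < 10 % at N ≈ 160, monotone in N.

λ policy: calibrated per geometry by minimizing the mean RMS difference
between reconstructed and directly computed endocardial electrograms of the
control run over a log grid `[1e-10, 1e-1]`. On noise-free simulated data
the error curve is U-shaped with a shallow minimum near the smallest
eigenvalue of `T_ec T_ecᵀ` (λ* ≈ 1e-7 on the default fixture); the
clinical-scale reference value 1.4e-5 is kept as a constant
(`noncontact.LAMBDA_REFERENCE`) but is not meaningful across
discretizations and units. The 64-electrode balloon (8 splines × 8 rings,
semi-axes 0.7 of the chamber's — the device is expanded to fill the atrium)
is placed at the chamber centroid.

## Map processing

Activation = steepest negative unipolar derivative with parabolic
sub-sample refinement, searched in (0, 160) ms after the stimulus.
Reconstructed endocardial activation maps are smoothed with a 5 mm
Gaussian over Euclidean inter-channel distances (at this scale on a
convex-ish chamber the geodesic/Euclidean difference is negligible). ATa
uses T1 = 35 ms, T2 = 300 ms, trapezoidal integration, baseline anchored at
the upper bound, normalization by interval length and by the whole-signal
standard deviation. Beat selection (relevant for experimental recordings
only) rejects any beat whose atrial activity interval
`[earliest activation, latest activation + 300 ms]` touches a QT interval,
with closed-interval overlap (a shared endpoint rejects — conservative).
ΔATa maps are smoothed differences of endocardial ATa maps (zone run minus
control); the zone is localized at the maximum.

Epi–endo correspondence in simulation is exact nearest-neighbor matching;
appendage electrodes are excluded from all agreement statistics. For
experimental-mode registration the three plaque control points are refined
by seeded random search in 2.5 mm-radius balls (projected to the surface,
i.e. effectively 5 mm-diameter discs), all three perturbed jointly per
iteration (a per-point variant is available via `joint=False`), grid
re-interpolated with regular spacing each trial and scored by pooled RMS
activation-time mismatch.

## Study profiles and problem sizes

* **Desk profile** (`pipeline.desk_config`, used by the tests and by
  `scripts/acceptance.py`): surrogate membrane, h = 0.5 mm (≈ 46 000 wall
  voxels), N ≈ 2300 virtual nodes, control + 5 zones — two at the
  GP/interatrial locations (radii 3 mm), three at the caval locations
  (radii 2, 3 and 5 mm; the large radius sits at an SVC-adjacent location,
  where only radii above 3 mm produce detectable repolarization changes).
  A full study takes ≈ 7 minutes on one CPU.
* **Full profile** (`pipeline.full_config`): detailed ionic model,
  h = 0.25 mm, dt = 20 µs, control + 7 locations × 3 radii = 22 runs.
  Provided for completeness; runtime is hours per run on one CPU.

## What the synthetic setting shows — and what it does not

The generator emulates the *best-case* experimental configuration: exact
electrode locations, a blood pool with homogeneous conductivity, no
ventricular far field, no motion, no epi–endo dissociation, no trabecular
structure, and identical geometry for the forward tissue model and the
inverse problem. Agreement statistics obtained here therefore isolate the
information loss of the 64-channel inverse reconstruction alone; they are
upper bounds for what real recordings can achieve, not predictions of
in-vivo correlation values.

Two known limitations matter when interpreting results:

1. **Spatial resolution of the inverse.** 64 electrodes over a ≈ 3000 mm²
   surface support feature scales of roughly 7 mm. The reconstructed ATa
   field behaves like a ~5 mm blur of the direct one; the narrow
   negative-ATa fringe that surrounds an ACh zone on the epicardium is
   below this scale and cannot be recovered, which is why a large zone
   centered under the dense plaque lowers the per-run epi–endo ATa
   correlation to ≈ 0.65 while zones at the anatomical (plaque-margin)
   locations correlate at ≈ 0.93–0.97.
2. **Waveform morphology.** For the same reason, reconstructed unipolar
   deflections are several times wider than contact ones, so contact-vs-
   noncontact *bipolar waveform* correlations plateau around 0.5 on this
   fixture (repolarization-phase-only correlations reach ≈ 0.8). We found
   no admissible lever — regularization weight, balloon size or position,
   chamber scale, surface refinement, pair separation or orientation —
   that lifts the full-waveform correlation to the level reported for
   richer, animal-derived geometries; treat bipolar morphology agreement
   as geometry-sensitive.
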