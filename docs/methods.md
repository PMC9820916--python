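# Methods

`airwaymorph` analyses upper-airway morphology from 3D craniofacial
landmarks and a binary airway voxel grid. This note documents the models,
the numerical choices, and what the synthetic data generator does and does
not emulate.

## Coordinate frame and reorientation

All measures are defined in an anatomical reference frame: +X anterior,
+Y subject-left, +Z superior, origin at sella (S). Input landmarks arrive
in an arbitrary scanner pose and are reoriented in two sequential rigid
steps:

1. **Frankfort alignment.** The plane through right porion and both
   orbitale points (rPo, rOr, lOr) is rotated to the horizontal via the
   minimal (Rodrigues) rotation, its normal oriented toward the side of
   sella (superior).
2. **Midsagittal alignment.** The plane through nasion, anterior nasal
   spine and the mid-posterior foramen magnum point (Na, ANS, MGNM) is
   brought to the x–z plane by a rotation about z only, so the first
   alignment is preserved. The ±Y ambiguity is resolved by requiring +X to
   point from MGNM toward Na (anterior).

Because the three midsagittal landmarks need not be coplanar with a
vertical plane after Frankfort levelling, only the horizontal component of
their plane normal is aligned; the residual |y| of those landmarks is
reported per subject as a QC metric (`midsagittal_residual_mm`). On
noise-free data the reorientation recovers canonical coordinates to below
1e-6 mm (round-trip tested), and Euclidean distances and vertex angles are
exactly rigid-invariant. The origin placement at S is a convention; no
measure depends on it. Binary grids are transformed by nearest-neighbour
resampling at the same voxel size, which preserves binarity at the cost of
a small (logged) volume change.

## Morphometric measures

The 25 measures (19 distances, 6 angles; see `docs/measures.csv`) follow
standard cephalometric definitions. Four need the reoriented frame:

- **A–B shift** is the *signed* anteroposterior component x_A − x_B of the
  Frankfort-plane projections. A signed value is required because a
  protrusive mandible yields negative shifts (published adult minima are
  negative); the lateral component is deliberately discarded.
- **HSP** (horizontal soft palate) is |x_PNS − x_LP|, with LP an explicit
  25th landmark for the most posterior soft-palate contour — the package
  consumes landmarks, not images, so the contour point must be supplied.
  A missing LP flags HSP absent (NaN) instead of failing the subject.
- **VSP** (vertical soft palate) is |z_PNS − z_TUV|, mapping "tip of the
  soft palate" to the uvula tip TUV, the only tip landmark defined;
  TUV–PNS (full Euclidean) is kept as a separate measure.
- **FMA** is the acute angle between the sagittal (x–z) projections of the
  Frankfort line rPo→rOr and the mandibular line Me→rGo, reported in
  (0°, 90°].

A missing required landmark raises an error naming the point, mirroring
the exclusion rule used when landmark sets are incomplete.

## Airway metrics

The airway is analysed between two horizontal planes of the reoriented
frame: superior at the palatal level, inferior at the most anterior point
of the C3 vertebral body. A plane through both PNS and ANS parallel to
Frankfort exists only if the two share a height, so the superior plane
uses their mean z and a warning is emitted when they disagree by more than
3 mm. Cropping keeps voxels whose centre z lies in [z_inf, z_sup] (both
boundaries inclusive). Volume is the air-voxel count × voxel³. A single
26-connected largest-component filter is applied in 3D before slicing,
emulating segmentation of one airway object; no per-slice filtering is
done. CSAmin is the minimal nonzero axial slice area (ties broken toward
the most inferior slice); its Ap/Lat dimensions are the x/y bounding-box
extents of air in that slice (inclusive voxel span × voxel size — maximal
chords would be an alternative reading; bounding boxes were chosen and are
accurate to one voxel on elliptical phantoms). On analytic phantoms at
0.3 mm voxels, volume and CSAmin errors are below 1%, and errors shrink
under repeated voxel halving (not strictly monotonically per halving —
voxel-count error oscillates with grid phase).

## Synthetic cohort generator

No public dataset of landmarked CBCT examinations with airway
segmentations exists, so the package ships a generator whose defaults
emulate the cohort conditions the analyses are designed for: n = 60
adults, 0.3 mm isotropic voxels, free head pose within ±20° per axis and
±30 mm.

- **Template.** A hand-built 25-landmark configuration in the canonical
  frame, placed so that every derived measure falls inside published adult
  ranges (e.g. S–Na ≈ 66 mm, SNA ≈ 82°, HSP ≈ 19 mm). The Frankfort
  landmarks share one z; midline landmarks lie at y = 0; rOr/lOr mirror.
- **Shape variation** is isotropic per-landmark Gaussian jitter
  (default SD 2.5 mm, chosen so measure SDs land near published cohort
  SDs and repeat-session ICCs fall in the published 0.5–0.98 band).
  Correlated anatomical covariation is *not* modelled; dependencies enter
  only through the planted model below, keeping ground truth analytic.
- **Planted effects.** Airway volume follows
  Vol = β₀ + β_HSP·HSP + β_tongue·(BEP–A) + β_mand·(Na–B) + ε with
  β_HSP = −900 mm³/mm < 0 (a longer horizontal soft palate shrinks the
  airway), β_tongue = +400, β_mand = +300, residual SD 6000 mm³; β₀ is
  calibrated so the template subject sits at the 14,460 mm³ population
  mean. CSAmin analogously with coefficients (−15, −3) on HSP and
  BEP–TUV, residual SD 80 mm², mean 206 mm². Residuals of the two models
  are correlated (ρ = 0.6): a wide airway is wide in both senses, and the
  correlation keeps the waist-below-mean-area geometric constraint from
  truncating the tails. Draws are clipped to physiologic floors/caps
  (volume ≥ 2500 mm³, waist ≤ 0.95 × mean area); with the default noise
  the clips act on rare tail draws only, and with zero residual SD the
  planted equations hold exactly (tested to 1e-9 relative).
- **Airway grids.** A vertical tube whose elliptical cross-section area
  follows one cosine period along z: A(t) = Ā − (Ā − CSAmin)·cos(2π(t −
  t_w)). The integral between the planes is exactly the volume target and
  the single interior minimum at t_w (drawn U(0.35, 0.65)) is exactly the
  CSAmin target, so voxel measurements can be validated against analytic
  truth. The x:y aspect ratio 10.2/27 reproduces published mean Ap/Lat
  extents. The tube extends 6 mm beyond both planes at the boundary area
  so that slightly misplaced cropping planes still see airway on both
  sides.
- **Frames.** Grids are generated in the subject's canonical (anatomical)
  frame; the random pose is applied to landmarks only. The pipeline
  reorients landmarks and crops the grid directly, so the small
  discrepancy between the reorientation fitted on jittered landmarks and
  the canonical frame (≈1–2°, 2–3 mm) propagates into Vol/CSAmin as
  realistic measurement noise of a few percent.
- **Repeat sessions** re-place every landmark with independent Gaussian
  error (default 1 mm), emulating a second reading a week later. Only
  landmark placement is re-done — the segmentation is fixed per subject —
  so metrics that barely depend on the cropping planes (notably CSAmin,
  whose waist is interior) can show ICC ≈ 1 while plane-sensitive Vol and
  landmark measures show ICCs in the high 0.8s–0.99.

What passing tests on this generator show: the geometry, reorientation,
voxel measurement, statistics and model-selection machinery recover known
ground truth under realistic noise. What they do not show: performance
under real CBCT segmentation error, correlated anatomical shape variation,
or landmark identification ambiguity on images.

## Statistics

- **ICC**: two-way mixed-effects, absolute-agreement, single-measure
  (ICC(A,1)), computed from the two-way ANOVA mean squares; 95% CI by the
  McGraw–Wong F-distribution method. This is the recommended form for
  intra-rater reliability with a fixed rater; it is verified in tests
  against an independent implementation and recovers
  σ²_b/(σ²_b + σ²_e) in simulation. Requires n ≥ 5 pairs.
- **Kendall τ-b** with tie correction (measurement tables contain ties
  after rounding); p-values from the asymptotic normal approximation, no
  multiple-testing correction by default (per-pair α = 0.05), with an
  optional Benjamini–Hochberg switch.
- **PCA** on the correlation matrix of z-scored variables; variable
  coordinates are loadings scaled by √eigenvalue; cos² per variable and
  dimension is the squared coordinate. Eigenvector signs are fixed by
  making each axis's largest-magnitude loading positive. Shapiro–Wilk
  normality (delegated to scipy) is reported only as a per-variable flag.

## Symbolic regression

A steady-state genetic program evolves expression trees over the building
blocks +, −, ×, ÷, exp, ln, power, √, with mean absolute error as
fitness, an 80/20 random train/validation split, and k = 10 independent
runs per target (independent splits, seeds derived from the root seed via
`SeedSequence`). Defaults: population 500, 200 generations, at most 10⁶
model evaluations per run — desk-scale budgets at which a planted linear
model with decoys is recovered exactly in ≥ 9/10 runs.

Numerical choices:

- **Feasibility**: any non-finite prediction on any row (÷0, ln ≤ 0,
  √negative, overflow) makes a model infeasible (MAE = +∞) — no protected
  operators, avoiding their pathological artifacts.
- **Linear output scaling**: every tree f is evaluated as a·f + b with
  (a, b) fit on the training split by least squares. This standard GP
  device lets the search concentrate on structure rather than output
  calibration.
- **Constant optimisation**: constants of Pareto-archive models are
  refined by local least squares every 25 generations and at the end of a
  run (models with ≤ 6 constants).
- **Complexity** is the tree node count (power exponents count as one
  constant node). The Pareto front keeps, per complexity level, the best
  training MAE, thinned to strictly improving MAE.
- **Best model** of a run: lowest validation MAE on the front, ties to
  the simpler model.
- **Power exponents** are constants clamped to |e| ≤ 10 during generation
  and mutation; overflow at evaluation still yields infeasibility.

**Variable importance** pools all Pareto-front models of all runs:
importance(v) ∝ Σ_m w_m·1[v ∈ m] with w_m = 1/(ε + validation MAE),
ε = 1e-12, normalized to sum to 1. This implements "proportion of
equations containing the variable, weighted by fit"; the exact historical
weighting scheme it paraphrases is not public, so the inverse-MAE
presence weighting is an interpretation and is documented as such.

**Sensitivity (magnitude of effects)**: for each variable in a model, the
mean over rows of ∂f/∂x_j (central difference, step 1e-4·SD(x_j)) times
SD(x_j)/SD(f). Positive means the target rises with the variable. The
signed mean derivative (rather than a magnitude with a separate sign
summary) is a documented choice. Per-variable results are averaged over
the k best models containing the variable, with the containment count
reported; rows with undefined derivatives are dropped and a variable is
flagged when they exceed 10%.

## Problem sizes used in tests and the acceptance script

Cohorts of n = 60 (the emulated study size) for end-to-end checks, n = 12
with 0.6 mm voxels for pipeline plumbing tests; SR at default budgets for
the planted-recovery check and at population 300 / 80 generations /
10 runs for the cohort experiment, where the qualitative result (HSP
first in importance, negative magnitude, present in ≈10/10 best models)
is stable. All randomness flows from a single root seed.

## Known limitations

- The generator's covariance structure is minimal by design; it cannot
  test robustness to realistic anatomical covariation.
- Ap/Lat as bounding-box extents differ from maximal-chord definitions by
  up to one voxel on convex slices, more on concave ones.
- The GP engine is a single-population steady-state search; no island
  models or parallelism.
- ICC confidence intervals assume the two-way normal ANOVA model;
  heavy-tailed measurement error will distort coverage.
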