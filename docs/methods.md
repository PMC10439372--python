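# Methods

This note records the model, its assumptions, the synthetic fixtures, the
numerical choices, and the open design decisions as implemented. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task and coordinate conventions

The task is the support (weight-bearing) phase of horizontal bimanual arm
suspension, analysed quasi-statically at three instances: early and late
support (double support, half body weight per hand) and mid support (single
support, full body weight). World frame: x anterior, y superior, z
lateral-right; right arm; glenohumeral (GH) joint centre at the origin.
Angles are degrees at interfaces and radians internally; positions are
metres; forces newtons; PCSA cm²; attachment coordinates are fractions of
longitudinal bone length in axis order (anterior-posterior, medial-lateral,
superior-inferior).

## Species parameters

Each species is one YAML configuration carrying anthropometry (human
72 kg / 1.80 m; chimpanzee 45 kg / 1.32 m), ten muscle elements with
absolute PCSA, the four probabilistic attachment distributions, the glenoid
inclination distribution and the stability profile. Human PCSA values are
the published age-corrected (doubled) figures; chimpanzee infraspinatus and
subscapularis whole-muscle PCSA is partitioned into elements by the human
element shares (infraspinatus 0.4537/0.5463; subscapularis
0.2429/0.3193/0.4378). Relative PCSA is absolute PCSA / body mass, rounded
to 3 decimals for table output. Standard deviations are identical between
species for every probabilistic input, so neither model sees artificially
wider variation than the other.

Segment lengths, mass fractions and centre-of-mass fractions follow
standard adult human anthropometry (arm/forearm/hand mass fractions
0.028/0.016/0.006) and chimpanzee-scaled analogues (0.040/0.023/0.009,
longer forearm relative to stature). These are configuration values, not
outputs.

## Stability ratios

Glenoid stability is a set of eight directional tolerance ratios (maximum
dislocating shear per unit concurrent compression) at 45° spacing around
the rim. The ancestor models' printed baseline values are not public; the
shipped human baseline is an assumed anisotropic profile — weakest
superiorly/anterosuperiorly (0.32/0.35), strongest inferiorly (0.85) —
with the inferior half calibrated once so that the deterministic
mean-geometry model of both species is feasible in all three support
instances (the package's ten-element system must carry body weight through
muscle co-contraction whose inherent shear-to-compression ratio the
profile has to admit; a profile that cannot is inconsistent with the model
it parameterises). The chimpanzee applies a +13.13% offset in all eight
directions, implemented multiplicatively (ratio × 1.1313) by default; an
additive mode (ratio + 0.1313) is selectable via `stability.offset_mode`.
The probabilistic stability input perturbs the offset percentage with
SD 4.0 jointly for all eight directions.

## Synthetic fixtures

The original motion-capture kinematics and bone geometry are unpublished,
so the fixture module generates idealized stand-ins:

* **Postures** are three-point (GH/elbow/wrist) planar configurations. The
  stored humerothoracic elevation (151°/168°/158°) is trunk-referenced —
  the suspended trunk leans — while the world-frame tilt of the hanging arm
  from vertical is small (early +5°, mid +4°, late −1.5°), as in a loaded
  pendulum; the mid-support forearm angle is solved so the grip point lies
  vertically above the GH centre (tolerance 2 cm). Elbow flexion stays
  below 30°. A seeded ±0.5° tilt jitter makes seeds meaningful while
  keeping every posture inside the stated envelope. Chimpanzee postures
  reuse the same angular program with chimpanzee segment lengths;
  `rescale_to_chimpanzee` alternatively translates a human posture's joint
  centres along unchanged segment directions and shifts the acromion
  marker to reposition the scapula without rotating any segment (default
  repositioning 3 mm inferior-medial; the radiograph-based magnitude is
  not published and larger values were found to strangle the feasible
  force space of the ten-element model).

* **Bone geometry** is a parametric landmark template, not a mesh. The
  scapula carries the glenoid centroid, the superior landmark of the
  glenoid y-axis at 3σ/tan(10°) = 5.104 cm (so ±3 SD of the 0.3 cm
  landmark shift spans ≈20° of inclination), an attachment reference point
  0.45 scapular lengths above the centroid from which fraction coordinates
  are measured (anterior +, medial +, inferior +), deltoid origin
  landmarks (the acromial origin deliberately lateral to the GH centre —
  the acromion overhangs the humeral head, which is what gives the middle
  deltoid its abduction moment arm), and the fraction bounding box used
  for clamping. The humerus carries rotator cuff insertion footprints at
  1.08 × head radius near the head equator, a head wrap sphere (cuff
  elements) and a shaft wrap cylinder of 0.3 × head radius (deltoid
  elements). Millimetre-scale seeded jitter applies to the assumed deltoid
  origins only.

What the fixtures deliberately do not emulate: scapulohumeral rhythm,
measured marker trajectories, bone meshes, subacromial geometry, and any
muscle beyond the ten modelled elements. Consequently the absolute force
distributions are properties of this geometry; parameter fidelity, the
constraint structure, and the probabilistic machinery are what the tests
verify against published values.

## Muscle paths and moment arms

Paths are taut strings with single-obstacle wrapping: the in-plane
great-circle tangent-arc solution on spheres, and the unrolled planar
tangent-arc solution on cylinders (axial coordinate linear in planar arc
length). If the straight segment clears the obstacle the path is straight;
if a perturbed attachment lands inside an obstacle the wrap is moot and
the model falls back to the straight string (the low-level `solve_path`
raises instead, preserving the geometric contract). The effective line of
action at the joint is the insertion-adjacent path segment; the moment arm
about the GH centre is **r** × **u** with **r** to the insertion. For a
wrap sphere centred at the GH joint the obstacle contact forces are radial
and torque-free about the centre, so this arm is exact, and the
tendon-excursion identity dL/dθ = −(**r** × **u**)·**a** holds (verified
numerically to 10⁻³ m).

Attachment perturbation adds SD × standard-normal deviates per axis and
clamps to the bone's fraction bounding box with a logged, counted warning;
clamping rather than rejection keeps iteration counts exact. Coupled
elements use child = parent ∘ (1 + offset) per axis, so the per-axis ratio
to the parent is invariant under any parent perturbation; a zero parent
coordinate with a nonzero relative offset is rejected as an undefined
percentage base.

## External dynamics

The hand force is vertical by default (direction configurable, e.g. along
the forearm), applied at a grip point 0.4 hand lengths beyond the wrist.
The GH moment is Σ **r** × **F** over the hand force and segment weights;
the force demand is −(hand force + segment weights). Both are exactly
linear in the applied forces. In the solver, the reaction transmitted onto
the glenoid is R = Σ fᵢ**u**ᵢ − demand = Σ fᵢ**u**ᵢ + F_ext — muscle pulls
on the humerus plus the net external force — whose medial component is the
stabilising compression. (The demand field keeps its sign convention; the
subtraction is what static equilibrium of the arm requires.)

## Force prediction

The solve runs in activation space aᵢ = fᵢ/fᵢᵐᵃˣ with bounds [0, 1]:

* objective Σ cᵢ aᵢᵖ with cᵢ = (fᵢᵐᵃˣ/PCSAᵢ)ᵖ normalised by its maximum
  (the stress cost, conditioned for the SQP solver); p ∈ {2, 3}, default 3;
* moment equilibrium as linear equalities, with identically-zero rows
  (planar problems) dropped to keep the Jacobian full-rank — a zero row
  with nonzero target is an immediate structural infeasibility;
* stability as eight linear half-planes ratio_d·C(a) − shear(a)·d̂ ≥ 0;
  opposite pairs jointly enforce C ≥ 0. The assessment function
  additionally reports the azimuth-interpolated allowable ratio (linear
  between adjacent 45° directions).

SLSQP runs from the zero vector (deterministic start, ftol 10⁻¹²,
maxiter 300); if the result violates a constraint or reports failure, it
is reseeded from a linear-programming feasibility point (HiGHS) and
polished once. An infeasible LP certifies genuine infeasibility, which is
returned as a flag with diagnostics — never an exception, never a silent
relaxation. A 10⁻⁶ N safety offset inside the stability inequality keeps
reported margins of feasible solutions nonnegative at solver precision;
feasibility requires an equilibrium residual ≤ 10⁻⁶ N·m and all margins
≥ −10⁻⁹ N. Specific tension σₘₐₓ defaults to 88 N/cm² and is exposed in
the study configuration; normalized outputs depend on it only through the
bounds.

## Monte Carlo and sensitivity

Draws are independent Gaussians per input (covariance between features is
assumed negligible and not modelled), one common n × 14 matrix per
(species, instance) run reused across the seven outputs — one model solve
yields all seven element forces, so the seven analyses share identical
model states, a computational economy with identical statistics.
Per-analysis seeds derive stably from (base seed, species, instance) via
adler32 modulo 2³¹. Infeasible iterations are counted and excluded from
the CDFs (silent imputation would bias the distributions); a run errors if
fewer than min(100, 0.8 n) feasible samples remain. Quantiles use the
linear-interpolation (type-7) rule for bit-exact reproducibility. The CDF
is tabulated at the 11 study levels {0.01, 0.1, …, 0.9, 0.99} with a
{1, 25, 50, 75, 99} percentile summary.

Sensitivity factors use the nondimensional mean-perturbation form
S = |∂p/∂μᵢ|·σᵢ/p: the base run fixes the level thresholds; the model is
re-evaluated with the input mean shifted ±0.1 σᵢ under common random
numbers; the central difference of the below-threshold probability is
scaled by σᵢ/p, then averaged over the 11 levels and over the three
support instances. The alternative σᵢ-only scaling is selectable in code.
On a linear Gaussian toy the estimator matches the closed form
φ(z_p)/p within 5% (tested). Factors for an input with zero SD, or at an
undefined probability, are excluded from averages.

## Problem sizes

Defaults reproduce the published design: 2500 iterations × 7 outputs × 3
instances × 2 species = 42 analyses. The test suite exercises the full
pipeline at 15–60 iterations per analysis (structure and invariants do not
depend on n); `scripts/acceptance.py` runs the full 2500-iteration design
and estimates sensitivity matrices from 400-iteration re-runs per shifted
mean — sizes chosen as a sensible accuracy/runtime balance on a single
CPU and stated here so they can be changed in one place.

## Known limitations

* Only ten muscle elements close the equilibrium; the real shoulder
  recruits many more, so a small percentage of strongly perturbed states
  is genuinely infeasible for this system (counted and reported; a few
  percent at the defaults, concentrated in the double-support instances).
* Absolute force percentages depend on the synthetic fixture geometry and
  the assumed stability baseline; between-species contrasts driven by the
  printed parameters (PCSA, attachment distributions, the 13.13% offset)
  are the meaningful outputs.
* Hand forces are conservative (no dynamic loading multiplier; a config
  multiplier exists via the hand-force direction/scaling hooks) and
  vertical by default.
* Muscle architecture (pennation, fibre length, force-length/velocity) is
  outside the string-muscle abstraction.
* The swing phase, electromyographic comparison and subacromial geometry
  are out of scope.
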