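# Methods

This note records the modelling assumptions, numerical choices and known
limitations of the `lvmech` pipeline, in the spirit of a model-description
appendix.

## Scope and overall design

The pipeline reproduces, on synthetic data, a contractility-estimation
study comparing patients with acute severe ST-elevation myocardial
infarction (STEMI, complicated by no-reflow) against age/sex-matched
"hyper-controls" with strictly normal blood pressure, n = 6 per group.
Because the underlying clinical images are not public, the package is
organized around a *synthetic cohort with known ground truth*: virtual
subjects are drawn from the study's population distributions, forward
simulated, observed with a realistic noise model, and then pushed through
the same inverse pipeline a clinical dataset would see. Every claim the
tests make is therefore a statement about estimator behaviour under the
stated generating model, not about patients.

## Forward model

### Quasi-static reduction

The study solved full fluid–structure LV dynamics; its biomarkers,
however, are defined at two quasi-steady states (end-diastole and
end-systole). The package therefore solves quasi-static solid equilibrium
only: the blood contributes a spatially uniform follower pressure on the
endocardium, and the viscous/inertial fluid terms are dropped. The
systolic "rapid pressure ramp" is not reproduced — only its end state is.
Consequences: no transient history effects in the ES state, and the
fading-memory force–velocity factor is at its steady value (Φ = 1). The
dynamic fading-memory model is retained at material-point level and the
test suite verifies that the quasi-static ES tension equals its long-time
limit.

### Reference configuration

The reference (stress-free) configuration is the early-diastolic
geometry, mirroring the imaging protocol that reconstructs anatomy when
LV pressure is lowest. No unloaded-configuration recovery is attempted.
The reference state is not exactly stress-free pointwise (the isotropic
term of the energy leaves a small residual a·I ≈ 0.06 kPa), which is the
standard behaviour of this constitutive family.

### Geometry

An idealized truncated prolate ellipsoid stands in for image-based
anatomy: endo- and epicardial ellipsoids with a common center, a flat
basal plane at z = 0 (apex toward −z), and a small apical truncation
(default 0.25 rad) that keeps all hexahedra well shaped; the cavity is
closed by basal and apical cap fans for volume evaluation. Circumferential
node radii carry an equal-area correction (inscribed polygon → equal
cross-sectional area) so coarse meshes preserve cavity volume; the
default-mesh discrete cavity volume is within 1% of the closed-form solid
of revolution.

Default dimensions (endo short axis 23.7 mm, long axis 60 mm, wall
8.7 mm) were calibrated once so that the healthy default inflated to
8 mmHg lands near the population end-diastolic volume (~121 mL); the STEMI
group's mean geometry scale (1.10) reflects the dilated patient
ventricles. Myofibers follow the rule-based linear transmural helix
(+60° endo → −60° epi); the sheet axis is transmural.

### Constitutive model

Passive myocardium: the anisotropic exponential fiber/sheet law (see
README for the energy). Two implementation details:

- **Tension-only fibers.** The I₄ terms contribute only when the
  respective direction is stretched (I₄ᵢ > 1), including in the analytic
  stress derivative; b → 0 limits are replaced by their Taylor forms.
- **Volumetric penalty.** Incompressibility is enforced by the Cauchy
  stress of the penalty energy β_s (ln J)², i.e. σ_pen = (β_s/J) log(J²) I
  — a penalty *pressure* −(β_s/J) log(J²) that is positive under
  compression and opposes it. β_s = 1500 kPa keeps the element-mean
  dilatation within ~1.5% of unity at peak systolic load (verified in the
  tests). The penalty is evaluated at the element-mean dilatation
  (mean-dilatation / B-bar treatment); pointwise J in single quadrature
  points may deviate more on coarse meshes.

The default stress-like parameters are the classical simple-shear-data
reference set of this constitutive family, scaled by a single population
factor (0.25) calibrated against the healthy EDV target; they are the
*starting point* of the per-subject fits, not results. Infarcted tissue is
stiffened by the factor 1 + 49φ on all four stress-like parameters
(φ = infarct fraction; 50× at the scar core), exponents unchanged.

Active tension: the fading-memory model with the canonical parameter set
of its family — length-dependence slope β₀ = 4.9, force–velocity curvature
α = 0.5, weights A = (−29, 138, 129), rates α_i = (30, 130, 625) s⁻¹ —
and a normalized-Hill activation level that equals exactly 1 at the
calcium plateau (the end-systolic analyses only use the saturated limit;
whether z/z_max at end-systole is exactly 1 is exposed as a config knob
through the Hill parameters). Active stress in partially infarcted tissue
is scaled by (1 − φ), the continuous counterpart of a purely passive scar.
β₀ = 4.9 gives a mean ES fiber stretch ≈ 0.88 and σᵃ/T^req ≈ 0.42,
consistent with the study's group-mean ratio (57/144 ≈ 0.40).

### Discretization and solver

Total-Lagrangian trilinear hexahedra with 2×2×2 Gauss quadrature; the
endocardial pressure is a follower load integrated on the deformed
bilinear faces. Basal boundary conditions are exactly the study's:
longitudinal and circumferential displacements of the basal plane are
zero, radial motion free (implemented by rotating basal dofs into a
cylindrical frame). Element tangents are assembled by batched forward
differences of the element force vectors (step 10⁻⁶ mm) — robust for the
exponential law and cheap at these sizes. Newton iteration uses a
trust-region cap (3 mm per update), a backtracking line search on the
residual norm, and adaptive load continuation (increments halved on
failure, re-grown on success); convergence is relative residual ≤ 10⁻⁸.
Repeated solves at nearby parameters (inside inverse loops) are
warm-started from the previous equilibrium and typically converge in a
handful of iterations. Refined-mesh solves can be warm-started from a
coarse solution via structured-grid interpolation.

Degenerate inputs: zero pressure returns the reference state exactly;
element inversion (det F ≤ 0) and continuation failure raise structured
errors carrying the last residual.

Units: mm, kPa, mL; mmHg converted to kPa at exactly one constant
(0.133322).

### Strain and volume extraction

Cavity volume: signed-tetrahedron sum over the triangulated closed cavity
surface (endocardium + planar cap fans) — exactly rigid-motion invariant.
Segmental circumferential strain: mass-weighted mean over each segment of
the engineering strain of circumferential material line elements,
|F c₀|/|F_ref c₀| − 1 (ED reference for systolic strain, early-diastolic
reference for diastolic strain; Green strain is intentionally not the
default, matching clinical cine-strain conventions). GLS: mean fractional
length change of six mid-wall base-to-apex polylines (three long-axis
planes), in percent.

Segments: 6 circumferential sectors × 3 longitudinal slices = 18 segments
(the study reports only its remote-segment count, 13 ± 3, not its total;
the 18-segment layout is a configuration choice). A segment is *remote*
(viable, counted by the MI objective) when its mass-weighted mean infarct
fraction is below 0.05.

## Infarct geometry

The infarct is an angular core region (φ = 1) with a linear 10 mm
transition to viable tissue (φ = 0), the distance measured by arc length
in the reference mid-wall metric. The default core is a basal–mid
circumferential wraparound. This placement is deliberate: on the
idealized ellipsoid the basal/mid/apical slices carry ~60/34/7% of LV
mass, so an apical infarct cannot reach the study's 40.5% LV-mass infarct
while leaving ≥10 of 18 segments remote; the basal–mid wraparound attains
both (40.5% mass after bisection calibration of the angular extents, 10
remote segments). On patient anatomies, where apical segments carry more
relative mass, the same mass fraction is compatible with an apical
placement. Microvascular obstruction (8.3 ± 4.5% LV mass) is recorded as
subject metadata only and does not alter mechanics.

## Synthetic cohort

Group distributions (means ± SD) are the study's: required contractility
144 ± 15 kPa (controls) and 166 ± 18 kPa (STEMI); systolic cuff pressure
129 ± 13 and 114 ± 14 mmHg; end-diastolic pressure fixed at the assigned
population values 8 (controls) and 16 mmHg (STEMI); infarct size
40.5 ± 7.8% of LV mass. Geometry scale (mean 1.0/1.10, SD 0.04) and a
lognormal passive-stiffness factor (σ = 0.2, median 1, same distribution
in both groups — the study attributes group differences to contractility,
geometry and infarct, not to remote-tissue stiffness) complete the
subject. Non-physical draws are resampled and logged.

Observation noise is multiplicative zero-bias Gaussian: relative SD 6.5%
on all strains (the intra-observer reproducibility of cine strain
analysis, which also reported near-zero bias — a bias hook exists in the
config) and 3% on volumes.

Six-month outcomes (GLS, ΔLVEF) come from a single-index Gaussian link to
baseline T^req with configurable correlation (defaults ρ = 0.86 for
6-month GLS, −0.44 for ΔLVEF, the study's observed coefficients; outcome
scales −13 ± 3% and +4 ± 5 points are plausible 6-month values for a
severe-STEMI group). This is a statistical device for validating the
correlation analysis at n = 6, not a biological model.

What the generator does *not* emulate: image formation and registration
(strains appear directly, with noise), regional contractility
heterogeneity outside the infarct, beat-to-beat variability, pericardial
constraint, and atrial/valvular mechanics. Passing tests demonstrate
estimator correctness under this generating model; transfer to real CMR
data inherits all the usual segmentation/registration uncertainties.

## Inverse problem

Diastolic stage: the 8-parameter passive law is not identifiable from one
EDV plus segmental strains, so the search space is two multiplicative
scales (isotropic a; anisotropic a_f/a_s/a_fs jointly), exponents fixed.
Nelder–Mead in log-scale space (bounds [0.2, 5], ~60 evaluations,
warm-started forward solves). The objective is the systolic functional
form applied at ED (volume term + diastolic strain term). For STEMI
subjects the remote-zone scales are fitted while the scar keeps its 50×
blended stiffening.

Systolic stage: bounded scalar minimization of Obj^HV (all segments +
ES-volume term, healthy) or Obj^MI (remote segments only, no volume term,
infarcted) over T^req ∈ [20, 500] kPa, absolute tolerance 0.5 kPa.
Optimization is deterministic given a measurement set.

**Identifiability limit.** The iso/aniso split of the diastolic stage is
only weakly determined: near the optimum the objective varies by ~10⁻⁶
along the valley against a data scale of ~10⁻², far below any realistic
measurement uncertainty. Quantities that depend only on the fitted
*diastolic* response (EDV error, recovered T^req) are insensitive to the
landing point; quantities that depend on the split are not. The
documented consequence: re-fitting at a deliberately wrong end-diastolic
pressure (8 → 15 mmHg) raises both scales ~1.9×, and because the
isotropic term is the dominant passive resistance at end-systole (fibers
are slack in compression), the re-fitted T^req and hence σᵃ/AT^nor move
by ~7% — more than the ≲1% reported by the original study's 8-parameter
pipeline, whose optimizer evidently distributed the stiffening
differently. The direction-level conclusions (passive stiffness up
strongly, contractility biomarkers comparatively stable) are reproduced.

Strain-perturbation sensitivity: subtracting 0.015 from every measured
systolic strain magnitude (~10% of a typical −0.15 strain) leaves AT^nor
nearly unchanged (≲0.2% for a control subject, where the ES-volume term
anchors the fit) while the MI objective — strain data only — shows the
strong T^req sensitivity (−20% for the default STEMI subject),
reproducing the study's reported 20% decrease.

## Statistics

Pooled two-sample t-tests for group comparisons; one-sample KS normality
(parameters estimated from the sample by default; Lilliefors correction
and fixed-parameter variants exposed); Pearson correlation with Fisher-z
CIs (SE = 1/√(n−3)) and t-based p-values; exact noncentral-t power. Two
documented reading choices: (i) the study describes its power calculation
as "paired" yet reports two independent groups of 6 — the two-sample
noncentral-t computation reproduces the printed 88% for Δ = 72 kPa,
SD = 36 kPa, α = 0.05 (the paired reading gives ~95%), so two-sample is
the default and the paired variant is an option; (ii) for r = 0.86,
n = 6 the Fisher-z CI is [0.160, 0.984], which rounds to [0.16, 0.98] —
the 0.17 lower bound printed in the source table presumably comes from a
different CI method; the package reports the Fisher-z value.

## Problem sizes

The default forward mesh is 12×8×2 elements; inverse fits, the synthetic
cohort and the acceptance script use the 8×6×2 coarse preset, where a cold
equilibrium solve takes ~10–20 s and warm-started solves well under a
second on one CPU. The mesh-refinement check doubles the default mesh in
every direction with an interpolated warm start. The noisy-recovery and
design-power checks run as scaled versions (3 noisy replicates; 60 seeded
cohorts at the sampling+statistics level, justified by the <0.1%
noise-free recovery error of the estimation stage).

## Known limitations

- The basal plane is held longitudinally (the study's boundary
  condition), which suppresses atrioventricular-plane descent; simulated
  GLS is therefore ≈ −12% rather than the clinical ≈ −20% for healthy
  subjects, and GLS-based outputs should be read as model-internal.
- Penalty (not exact) incompressibility; pointwise J on coarse meshes can
  deviate a few percent at end-systole even when the element-mean is
  within 1.5%.
- Scar stiffening is isotropic (×50 on all stress-like parameters); no
  border-zone contractility model, no regional T^req (deliberately out of
  scope), no viscoelasticity, no sheet-normal anisotropy.
- STEMI forward volumes sit slightly below the patient population's
  (EDV ~150 vs 146.6 ± 27 mL is within range, but LVEF lands near the low
  30s% vs 41 ± 5% at the default contractility) — the stiff transmural
  wraparound scar limits both filling and ejection more symmetrically
  than real infarcts appear to.
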