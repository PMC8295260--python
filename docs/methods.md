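# Methods

`lungmotion` measures diaphragm motion from paired expiration/inspiration
CT-like volumes: a mass-preserving deformable registration produces the
expiration→inspiration displacement field, the basal lung serves as a proxy
for the diaphragm surface, and per-region displacement statistics feed a
cohort-level group comparison.  Because no clinical volumes ship with the
package, every stage is validated against synthetic thoracic phantoms whose
deformation is known in closed form.

## Density model

A voxel at HU value *I* is a linear air/tissue mixture with tissue fraction

    β(I) = clip((I − hu_air) / (hu_tissue − hu_air), 0, 1),

with `hu_air = −1000` and `hu_tissue = +55` — standard lung-densitometry
constants, exposed in `DensityConfig`.  Air and tissue volumes are
voxel-volume-weighted sums of the fractions over the lung mask (litres).
Low-attenuation indices use strict thresholds: %LAA_insp counts inspiration
voxels below −950 HU, %LAA_exp expiration voxels below −856 HU.  The
emphysema distribution index per lung is the upper-to-lower-lobe %LAA_insp
ratio (right numerator computed on the pooled RUL∪RML voxel set, matching
the printed definition rather than a sum of percentages); EDI ≥ 2 types a
lung upper-lobe-predominant, below 2 diffuse, and a zero lower-lobe %LAA
raises an explicit error rather than yielding NaN.  Scan pairs whose
expiratory/inspiratory air-volume ratio is not strictly below 0.9 fail QC.

## Phantom generator

The phantom is a continuum model sampled onto a voxel grid (default 96³ at
2 mm isotropic):

* **Geometry.** Two ellipsoidal lungs (semi-axes scaling with the grid
  extent) sit above a spherical-cap diaphragm dome of height 20 mm rising
  from each lung's base plane; background soft tissue is +40 HU, parenchyma
  −850 HU at expiration plus a vessel-like positive texture (60 HU × |G|, G a
  smooth Gaussian random field interpolated with cubic splines, defined in
  material coordinates so it advects with the deformation and gives the
  registration interior signal).  Lobes are z-bands of each lung.
* **Label maps.** Segmentations are eroded by max(2 mm, one voxel) relative
  to the pleural HU boundary, as clinical lobe masks are; this keeps
  partial-volume shell voxels out of all densitometric integrals.
* **Truth deformation.** Displacement follows a cubic smoothstep ramp in
  depth from the lung apex (zero) to the basal plane (full amplitude);
  default amplitudes (dx, dy, dz) = (0.5, −2, −10) mm give dome descent with
  a smaller ventral and a small transverse component, reproducing the
  apico-basal ≥ dorsal–ventral ≥ transverse ordering of normal diaphragm
  motion, with xy-plane angles near 180° (ventral), away from the 0°/360°
  wrap where arithmetic angle statistics would be meaningless.  Because the
  field depends on z only, its Jacobian determinant is exactly
  1 + ∂u_z/∂z > 1 in the lung: inspiration inflates.
* **Mass-preserving warp.** The inspiration volume is I(y) with
  β_insp(y) = β_exp(T⁻¹(y)) / J(T⁻¹(y)): a region locally expanded by J keeps
  its tissue mass, so its tissue fraction drops by 1/J — precisely the
  assumption the SSTVD cost exploits.  T⁻¹ is evaluated by fixed-point
  iteration (20 iterations; the fields' displacement gradients are well below
  1).  The expiration volume is built with 2× supersampling and block
  averaging so edges are antialiased.  Measured tissue-volume mismatch
  between the two scans is ~0.1–0.2% at default resolution (invariant bound:
  0.5%).
* **Lesions.** Emphysema-like spheres (radius 7 mm, ≤ −960 HU) are placed
  uniformly in material coordinates (optionally restricted to named lobes)
  and re-warped, so they appear at deformation-linked positions in both
  scans; the count is iterated until measured inspiration %LAA_insp is
  within ±2 percentage points of the target (internally ±1).
* **Noise.** Additive Gaussian HU noise, SD 20, applied independently per
  scan after warping; all randomness (texture, lesions, noise) derives from
  child generators of the spec seed, so pairs are bit-reproducible.

The default phantom breathes more shallowly than a coached clinical
inspiration/expiration pair (air-volume ratio ≈ 0.9), so it sits at the QC
boundary; the QC rule is still enforced exactly as defined.

### Synthetic cohorts

`synth_cohort` has two modes.  *Fast* mode draws each subject's per-region
motion summary and densitometry indices directly from configurable group
distributions — whole-diaphragm means follow the published normal /
emphysema / IPF group values; per-subject dispersion is **not identifiable
from published group means**, so the SDs (1.0 for displacement metrics, 10°
/ 8° for angle mean/SD) are explicit, configurable study conditions.  An
optional linear coupling makes a motion metric depend on %LAA_exp
(`metric = mean + slope·(laa_exp − mean_laa) + residual`, residual shrunk so
the total SD is unchanged), giving a known generating correlation
r = slope·σ_laa/σ_metric (default −0.52 for apico-basal, −0.55 for 3D in the
emphysema group).  *Full* mode builds a phantom per subject, registers it
and runs the whole measurement pipeline; it exists for end-to-end testing
and is minutes per subject.  Fast-mode draws are unbounded Gaussians (a
metric can stray below zero in the tails): the mode exists to calibrate the
statistics, not to bound physiology.

What the phantoms do **not** emulate: airways, vessels and fissures as
anatomical structures, rib cage and cardiac motion, CT reconstruction
physics, slice-dependent noise, and sliding at the pleura (the truth field
is globally smooth).  Passing tests therefore demonstrate correctness of the
algorithms under mass-preserving, smoothly-deforming conditions — not
segmentation robustness or clinical accuracy.

## Registration

The cost is the sum of squared tissue volume difference over the evaluated
region plus a bending penalty:

    C(u) = Σ_x [ v·β_f(x) − v·J(x)·β_m(x + u(x)) ]² + λ·Σ‖Δ²c‖²,

where v is the voxel volume, β_f/β_m the fixed/moving tissue fractions (HU
clamped to [−1000, 55]), J the central-difference Jacobian determinant of
T = id + u, and the penalty is the squared second differences of the
control-point lattice (λ = 10⁻³ by default; ×10 retries on Jacobian
folding, up to twice, then a hard error).  The fixed image is the
expiration scan, so the optimum directly parameterizes the
expiration→inspiration vectors.

The transform is a cubic B-spline free-form deformation optimized
coarse-to-fine: a 3-level image pyramid (downsampling ×2 with Gaussian
prefiltering) with control spacing 24 mm at the coarsest level, halving per
level but floored at 12 mm — on smooth breathing-scale motion the coarser
finest-level lattice both regularizes and converges faster than a 6 mm one.
Each level runs L-BFGS-B with fully analytic gradients: the interpolation
term uses the exact derivative of the trilinear interpolant (clamped
coordinates have a true zero derivative), and the Jacobian term is
backpropagated through the cofactor matrix and the exact adjoint of the
central-difference stencil; a finite-difference test guards the gradient to
~10⁻⁵ relative error.  The iteration cap is 100 at the finest level,
doubling per coarser level (coarse iterations are orders of magnitude
cheaper and initialize the fine level).  Evaluation is restricted to the
lung mask dilated by 12 mm: the dilation includes the pleural and dome
interfaces, which carry most of the alignment signal.  Everything is dense
and deterministic; provenance records a config digest, the per-level cost
trace (monotone non-increasing accepted values) and convergence flags.

Measured on the default phantom (single CPU): identity pairs recover
|u| < 0.1 voxel in seconds; a uniform (0, 2, −4) mm translation is recovered
to ≪ 0.5 mm per component in ~1–2 min; the 10 mm dome descent yields a basal
apico-basal mean within ~9% of the analytic value and mean landmark error
~1.5 mm (< 1 voxel) in ~2 min.  Residual basal under-recovery is the usual
smoothness/aperture bias of parametric registration near a strongly curved
boundary.

Two caveats established during validation: with scanner noise the data term
has a field-independent noise floor, and voxels straddling the pleural edge
carry an irreducible trilinear-interpolation residual even under the exact
field — so the "truth field ≈ zero cost" property of the mass-preserving
construction is asserted noise-free on the lung interior, where it holds to
< 1%.

## Motionography

The basal band is every lung voxel within 5 mm (configurable) of its
column's lowest lung voxel, anchored on the expiration grid, subsampled by
k = max(1, round(pitch / spacing)) voxels per axis (default pitch 5 mm → a
4 mm effective pitch at 2 mm voxels; the rounding is deliberate so samples
stay on the voxel lattice).  Displacements are evaluated exactly for
analytic fields and by trilinear interpolation for dense fields.

Normalization divides displacement in **cm** by (V_IN − V_EX in **L**)^(1/3),
with V the total segmented lung volume; this unit convention reproduces the
magnitude scale of published normalized displacements (~3 for ~4 cm
excursions at ~2 L volume change) and is recorded here because the formula
itself does not fix units.

The xy-plane angle is θ = atan2(medial, dorsal) mapped to [0, 360):
0° dorsal, 90° medial, 180° ventral, 270° lateral, where "medial" is −x on
the left lung and +x on the right (+x = patient-left).  This orientation —
angles growing medial → ventral → lateral — is the one consistent with
lateral quadrants showing means above 180° and medial quadrants below; it is
a documented convention choice, configurable in the sense that the sign
convention lives in one function.  Samples with a zero xy-projection are
excluded from angle statistics only.  Angle means/SDs are arithmetic on
[0, 360), valid because observed angles cluster near 180°, far from the
wrap; they are not circular statistics.

Quadrants split each lung's basal samples at the centre point (midpoints of
the x and y coordinate ranges): anterior is y < c_y, lateral is farther from
the midline than c_x, with ties posterior/medial, mapping to Q1
antero-lateral, Q2 antero-medial, Q3 postero-medial, Q4 postero-lateral.
Region summaries pool both lungs (whole diaphragm, and per-quadrant after
per-lung assignment).  Magnitude metrics are means of per-sample norms (3D
and 2D); per-axis metrics are |mean signed component| — signed, so that
left/right opposed transverse motion cancels at the whole-diaphragm level,
which is why the whole-diaphragm transverse metric sits far below its
quadrant values on symmetric subjects.

## Cohort statistics

Group comparisons use two-sided independent t-tests (Welch by default; a
flag selects Student's pooled variant — the choice between them is not
determined by the study description), one-way ANOVA across the three
groups, and Holm step-down adjustment of the three pairwise p-values,
computed only when the ANOVA p < 0.05 (post-hoc gating).  Holm is
implemented directly (sort ascending, multiply by m − rank + 1, running
maximum, cap at 1) and cross-checked against statsmodels in the tests.
Pearson correlations report r with the two-sided t-based p; constant inputs
and single-subject groups raise errors rather than returning NaN.  Before
any statistic, subjects failing the volume-ratio QC are dropped, and — when
spirometry fields are present — emphysema subjects without airflow
obstruction (FEV1/FVC ≥ 70%).  Report tables mirror the study layout:
7 metrics (3D, 2D, transverse, apico-basal, dorsal–ventral, angle mean,
angle SD) × 5 regions with group means and adjusted p-values, an
upper-lobe-predominant vs diffuse comparison over emphysema lungs, and
correlation tables against %LAA and spirometry.

Calibration, verified over 200 seeds in the acceptance suite: type-I error
of the ANOVA pipeline at α = 0.05 stays within 5% ± 3% on identically
distributed groups; power for the reference contrast (means 3.17 vs 2.40,
SD 1.0, n = 29/50) exceeds 80% (analytically ≈ 0.91); the injected
%LAA_exp–motion correlation is recovered with correct sign on every seed
and mean |Δr| ≤ 0.15 over 50 seeds (per-seed r at n = 50 has sampling SD
≈ 0.10, so only the mean is a meaningful recovery target).

## Problem sizes and determinism

Tests and the acceptance script run phantoms at 96³ × 2 mm (registration
recovery, mass conservation) and 48–64³ at 3–4 mm (unit-level checks); the
cohort statistics use fast-mode draws at the published group sizes
(29/50/51) or n = 30–50 per group for calibration loops.  These sizes keep a
full validation run in minutes on one CPU while leaving 2–3 voxels across
the 5 mm basal band.  All randomness flows from explicit integer seeds
through `numpy.random.SeedSequence`, so every reported number is exactly
reproducible.

## Known limitations

* Basal displacement from the registered field is biased low by ~5–10%
  (parametric smoothness near the dome); the bias is measured against the
  analytic truth, not corrected.
* Angle statistics are arithmetic, not circular; they are unreliable for
  motion regimes with xy-angles near the dorsal (0°/360°) direction.
* The %LAA lesion model is binary spheres, not a continuum of destruction;
  %LAA_exp of lesioned phantoms is a by-product, not an independently
  controlled target.
* Fast-mode cohorts draw region metrics independently of each other and of
  the quadrant structure; only whole-diaphragm metrics carry the injected
  %LAA coupling.
* No automatic lung/lobe segmentation: label maps are inputs everywhere.
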