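# Methods

`tibload` estimates internal tibial loading during running from sparse
anatomical landmarks. This note documents the models, their assumptions,
the synthetic data they are exercised on, and the numerical and design
choices a maintainer would want to know about.

## Coordinate conventions and units

All modules share a right-handed shank frame: +X anterior, +Y lateral,
+Z proximal along the bone's long axis. Lengths are mm, forces N,
stresses MPa (the internal mm–N–MPa system, so Young's moduli of 17 and
1 GPa enter as 17 000 and 1 000 MPa). Axial force components follow the
internal-force convention (tension positive): stance-phase joint
compression is negative. Ankle dorsiflexion is the positive sagittal
moment. The finite element driver converts an internal axial force to
the equivalent external force on the distal surface by flipping its
sign.

## Tibia phantoms (`phantom`)

The phantom is a tapered hollow elliptical shaft: per-ring periosteal
semi-axes `a(z), b(z)` (AP, ML) with cosine-blended proximal and distal
flares, an anterior bow of the shaft axis (first and second sine
harmonics), a linear AP taper, and an endosteal surface at a constant
fraction of the periosteal semi-axes. Mid-shaft defaults (a = 13.8 mm,
b = 12.3 mm, endosteal fraction 0.51) are calibrated so the distal-third
section reproduces published adult values (CSA ≈ 393 mm², I_ML ≈
23.6 × 10³ mm⁴, I_AP ≈ 18.9 × 10³ mm⁴); length tracks stature at
398.2 mm per 166.4 cm. The proximal flare blends over the upper 45 % of
the bone so the section grows steadily toward the plateau, as a real
tibia does — this keeps the peak bending stress distal, where the bone
is slender.

Populations are drawn from independent normal distributions per
parameter (clipped at 2.5 SD) on a fixed parametric grid (default 40
rings × 24 circumferential points + 2 cap centres), so every mesh in a
population is in point correspondence and each named landmark is a fixed
affine combination of vertices. The 9-landmark palpable set comprises
the condyle and malleolus pairs, tibial tuberosity, a fibular-head
surrogate (extrapolated laterally from the proximal shaft; the phantom
models the tibia only), and anterior-border points at 25/50/75 % of the
bone. The 4-marker motion-capture set is the condyle/malleolus subset.

Two corruption mechanisms emulate real data:

* **out-of-model-span detail** (`perturb_phantom`, default 1.2–1.5 mm
  RMS): a smooth low-order harmonic radial field representing anatomy the
  parametric family cannot express. This is what makes sparse-landmark
  reconstruction genuinely imperfect, and it is the mechanism by which
  more landmarks help: they constrain the admissible in-span shape near
  more of the true surface.
* **landmark noise** (`noisy_landmarks`): isotropic Gaussian offsets;
  0.5 mm for image-digitized landmarks (validation experiment), 3 mm for
  skin-mounted markers (running study), representing soft-tissue
  artifact.

The bow, second bow harmonic and AP taper deserve comment: they are
precisely the shape dimensions the 4 end-point markers cannot observe
(the condyles and malleoli see only lengths and end widths), while the
anterior-border landmarks observe them directly. Their population
variances (2.5 mm, 2.0 mm, 0.10) therefore control how much better the
9-marker configuration is, and were chosen so the effect is robust
across training-population draws rather than tuned to one seed.

## Statistical shape model (`ssm`)

Generalized Procrustes alignment (rotation + translation; isotropic
scale available but **off** by default so that overall size stays in the
shape modes, where it dominates the first mode) followed by PCA of the
stacked vertex coordinates. Modes retained: enough for 99 % of the
post-alignment variance by default, capped at n − 1. The high-variance
modes carry the anatomy; the small-λ tail of a 30-sample PCA consists of
manifold-curvature/sampling noise, and retaining it lets a
sparse-landmark fit chase noise through the ±3 SD box (measured as an
inversion of the 9-vs-4-marker ordering), so the default cutoff is also
the pipeline's setting.

`fit_landmarks` minimizes the sum of squared distances between posed
model landmarks and observations subject to hard per-mode bounds
|b_j| ≤ k·√λ_j. The solver takes joint Gauss–Newton steps over the
scores (box-bounded, solved with BVLS) and a pose increment (rotation
vector + translation, plus log-scale when enabled), starting from b = 0
and the Procrustes pose of the mean — deterministic, typically 3–6
iterations. A pure alternation of closed-form pose and bounded scores
was tried first and stalls in shallow pose–shape gauge valleys (final
objective ~10⁻² mm² instead of ~10⁻²⁸ on in-span data); the joint step
removes this. A 10⁻¹² Tikhonov term prefers the smallest-norm score
vector among objective ties. Zero-variance modes are pinned at zero;
k = 0 short-circuits to the posed mean.

The trabecular (endosteal) surface of a new bone is not observable from
skin landmarks; it is predicted by ordinary least squares from cortical
PC scores to endosteal PC scores, both models trained on the same
population. With the phantom's constant endosteal fraction this
regression is nearly exact in-sample; for real bones it would carry the
reference regression's residual instead.

## Geometry metrics (`metrics`)

* **Jaccard index**: voxel overlap on a shared axis-aligned grid
  covering the union bounding box padded by one voxel (default 1 mm).
  The inside test casts one vertical ray per voxel column and uses
  crossing parity, with a deterministic jitter fallback when a ray
  grazes an edge. Symmetry is exact by construction; halving the voxel
  size moves J by < 0.02 on the phantom suite.
* **Surface error**: mean/max absolute per-vertex distance, either by
  index correspondence (same parametric grid) or nearest point on the
  reference surface (KD-tree over triangle centroids + exact
  point–triangle distances). Reconstructions are rigidly aligned to the
  reference via shared landmarks first — rigid only, so size errors stay
  visible.
* **Distal-third section**: the cutting plane sits at one third of the
  axial extent from the distal end; periosteal/endosteal semi-axes are
  half the maximal AP and ML extents of the raw cut contours (not a
  least-squares ellipse). CSA = π(a_o·b_o − a_i·b_i), I_ML =
  (π/4)(b_o·a_o³ − b_i·a_i³), I_AP symmetric. The section also records
  its centroid and the distal-end reference used by the beam free body.

## Gait processing and muscle forces (`musculo`)

Fourth-order zero-lag Butterworth filtering (2nd-order design, forward
and backward pass) at 10 Hz for marker-derived channels (joint moments)
and 20 Hz for force channels. Stance is the longest contiguous run with
filtered vertical GRF > 10 N; all channels are linearly resampled to 101
points (0–100 % stance). A rearfoot strike is a contact angle > 8°
(strict).

Static optimization minimizes the sum of cubed muscle stresses
Σ(f_i/PCSA_i)³ subject to equality constraints on the sagittal ankle and
knee moments and f_i ≥ 0 (no upper bounds by default; a maximal-stress
bound is available). The objective is strictly convex on the feasible
set, so the SLSQP solution from the deterministic start is the global
optimum; equality residuals are verified to 10⁻⁶·max(1, |M|) and a DOF
whose target sign no muscle can produce raises an infeasibility error.
The 11-muscle set's PCSAs derive from maximal isometric forces of a
standard full-body running model at 60 N/cm² specific tension; moment
arms and unit lines of action are plausible shank-frame magnitudes, with
plantar flexors pulling posteriorly/distally. Only the gastrocnemii
cross the knee, so the generator's knee target is a flexion moment.

The ankle joint contact force is F = (1 − fibula_share)·(RF + Σ f_i)
component-wise per sample, with fibula_share = 0.1 (the ~10 % fibular
load path; hence the 0.9 scaling). The load case is taken at the sample
of peak resultant |F| (ties → earliest sample) and records the full
per-sample series for the beam model.

## 2D beam model (`beam`)

σ_ant/post = N/CSA ± M·c/I_ML with c = a_o (periosteal AP semi-axis) and
tension positive. The bending moment at the distal-third section is a
quasi-static free body of the bone distal to the section:
M_ML = (x_A − x_c)·F_axial − (z_s − z_A)·F_AP, anterior-tension
positive; the application point defaults to 8 mm posterior to the distal
end centre (the eccentric load path through the distal articular
surface). The sign convention is validated two ways in the tests: the
eccentric-column argument (compressive force posterior to the centroid
loads the posterior cortex) and an independent r × F torque evaluation.
Peak anterior (most tensile, i.e. maximum) and posterior (most
compressive, minimum) values are extracted over the 101 stance samples.
Condition statistics run on anterior stress only; posterior stress is
descriptive.

## 3D finite elements (`fem`)

Linear elasticity on tetrahedral meshes built by splitting the phantom's
structured cylindrical cells with a conforming main-diagonal 6-tet (and
central 3-tet wedge) pattern; cortical/trabecular labels come from
whether an element centroid falls inside the endosteal boundary.
Materials: isotropic E = 17 GPa (cortical), 1 GPa (trabecular),
ν = 0.3. Boundary conditions: every DOF of the proximal plateau node set
fixed; the ankle contact force applied as a consistent **uniform
traction** over the distal articular surface (tributary-area nodal
weights — equal per-node forces are not a uniform load and break the
axial-prism exactness the test suite demands).

Element order: 4-node constant-strain tetrahedra by default (cheap
enough for 54 participant-condition solves; one factorization per
participant is reused across conditions), with 10-node quadratic
tetrahedra available behind the same interface (`promote_to_quadratic`,
straight-sided, 4-point Gauss rule). The analytic oracles quantify the
trade: the axial prism and the patch test are exact for both orders,
while in bending the linear elements oscillate element-to-element by
~±20 % and converge slowly (still ~9 % low at 2 mm on a 20 mm-deep
cantilever), so the cantilever/convergence benchmarks run quadratic
elements, which sit within 1–2 % of M·c/I. Consequently the linear-tet
study meshes overestimate peak stresses by roughly 15–30 %; because the
same mesh serves all three conditions and the problem is linear, the
condition *orderings* and percentage changes are unaffected.

Per-element (centroid) strain → stress via Hooke's law; principal
stresses are eigenvalues sorted descending. The pressure-modified von
Mises equivalent strain uses the κ-parameterized pressure-sensitive form
(first strain invariant plus the deviatoric J₂ term) normalized so κ = 1
reduces exactly to the von Mises equivalent strain and a uniaxial stress
state returns |ε_axial|; κ (compressive-to-tensile strength ratio)
defaults to 1.0 since the exact reference constant is not reproduced
here. Summaries: strained volume = Σ element volumes with equivalent
strain > 3000 µε; the 95th percentile is **volume-weighted** (sort by
strain, value at 95 % cumulative volume); peak principal stresses
exclude elements touching the fixed plateau nodes by default (the fully
fixed face is singular in the displacement formulation) — a config flag
restores raw maxima. Whether percentiles/peaks should use integration
points, element means or nodes is not standardized; element centroids
are used throughout.

Mesh convergence runs a decreasing ladder (default 5.5/3.6/2.7/2.0 mm)
and reports the first size whose three key metrics (95th-percentile
strain, peak tensile, peak compressive) all change < 5 % from the
previous entry; a ladder that never settles returns a report, not an
exception.

## Statistics (`stats`)

Friedman tests use the tie-corrected rank statistic; Kendall's
W = χ²/(n(k − 1)). P-values come from full enumeration of within-row
permutations for n ≤ 4, k = 3 (e.g. the perfect-ordering n = 3 table
gives χ² = 6, W = 1, p = 6/216) and the χ² approximation otherwise. A
table with complete within-row ties carries no rank signal and returns
χ² = 0, W = 0, p = 1 rather than an error. Wilcoxon signed-rank tests
drop zero differences, use midranks for tied magnitudes, and compute the
exact two-sided p by dynamic programming over doubled midranks for
n ≤ 25 (normal approximation with tie correction beyond); Bonferroni
correction is min(1, m·p) over the pairwise family. Spearman/MAE length
agreement, the 2D-vs-3D percentage-change agreement (mean ± SD of
absolute differences, sign concordance, identity-line table) and
per-group descriptives (ddof = 1) complete the layer. Shapiro–Wilk is
available as a screen but never drives branching.

## Study conditions of the synthetic experiments

The runner cohort draws balanced sexes with heights pooling to
166.4 ± 6.3 cm and masses to ≈ 61.6 ± 6.6 kg; an optional extra
participant at 151.8 cm falls below the shape-model screening window
(training mean ± 2 SD = 152.8–199.3 cm, bounds inclusive) and is removed
by `screen_participants`, leaving 18 analyzed. The training cohort is
taller and more variable (176.1 ± 11.6 cm). Condition effects are
multiplicative: ankle-moment scales 1.0/0.82/1.18 and reaction-force
scales 1.0/0.93/1.06 for hRFS/iRFS/iFFS, with 8 % between-participant
and 2 % within-participant variability, so peak plantar-flexion moments
order iFFS > hRFS > iRFS for every participant by construction. Foot
strike angles are drawn per condition from 14.3 ± 4.3°, 29.0 ± 5.7° and
−4.4 ± 4.7°. Base magnitudes (2.4 BW vertical GRF, −2.4 BW axial
reaction, −0.45 BW posterior shear, −2.0 N·m/kg ankle moment) were
calibrated once so the group-mean distal-third anterior stress lands
near the published ≈ 77 MPa under habitual rearfoot running.

Problem sizes for the end-to-end experiments: 30 training phantoms, 20
validation phantoms at 1 mm Jaccard voxels, 18 runners × 3 conditions
with 3.6 mm linear-tet study meshes (~50 k elements each, one
factorization per participant). These sizes keep a full replication of
both experiments in the few-minute range on a laptop core.

## What passing tests do and do not show

The synthetic study reproduces the *structure* of the real analyses —
condition orderings, full directional 2D-vs-3D concordance, the
9-vs-4-marker accuracy ordering, length-agreement direction (model
lengths slightly above marker lengths, MAE ≈ 11 mm), sex-related CSA
differences — but not real-data magnitudes. Known gaps: synthetic
landmarks are far cleaner than skin markers, so the length correlation
is ρ ≈ 1 rather than ≈ 0.67; within-participant condition effects are
purely multiplicative, so Kendall's W saturates at 1.0 and the 2D-vs-3D
mean absolute percentage-change difference (~0.3 %) is much smaller than
a real between-method difference; Jaccard values (~0.7–0.9) are higher
than imaging-validation values because the phantom family is far simpler
than real anatomy; and the constant-strain FE peaks are biased high as
described above. None of these affect the direction-level claims the
tests assert.

## Known limitations

No fibula geometry (its load share is the 0.9 scalar); homogeneous
isotropic materials (no density mapping); quasi-static loading at the
peak-AJCF instant only; the distal-third free body ignores inertial
terms and distributed muscle attachment along the shaft; inverse
dynamics from raw marker trajectories is out of scope (trials carry
joint reaction forces and moments directly); and the within-4-marker
constraint ordering (±1 vs ±2 vs ±3 SD), while usually reproducing the
reference pattern, is seed-sensitive and not asserted by the tests.
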