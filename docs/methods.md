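# Methods

This note records the models, algorithms and design choices behind
`bonessm`, and what the synthetic validation does and does not show.

## Shape representation and size normalisation

A bone instance is a closed triangulated surface. For analysis it is sampled
into a point cloud (area-uniform, stratified per face, with barycentric
normal interpolation), translated to the origin and scaled to unit centroid
size, `S = sqrt(Σ_i ||p_i − p̄||²)` (Kendall). Size is therefore removed
before shape comparison; the recorded `S` (mm) lets millimetre-valued
parameters keep their meaning on normalised clouds. Right-side bones are
mirrored across the sagittal plane before sampling; the medial–lateral axis
index is configurable (default axis 0) because segmentation pipelines differ
in coordinate conventions. Mirroring reverses face winding so normals stay
outward, and is an exact involution.

## Groupwise registration

All instances of one bone type are aligned by similarity transforms (proper
rotation, translation, isotropic scale — reflections are excluded by
construction) to an evolving mean point cloud, so that no single specimen
acts as the reference. The probabilistic model is a Gaussian mixture whose
components are the `n_mean` mean points with shared isotropic kernel σ plus
a uniform outlier component (weight 0.01). Per outer iteration:

1. each instance is aligned to the fixed mean by EM — soft responsibilities
   in the E-step, a closed-form weighted Umeyama similarity fit in the
   M-step (as in coherent point drift);
2. each mean point is re-estimated as the responsibility-weighted barycentre
   of all aligned instance points, pulled toward its previous position with
   relative weight λ (the mean moves by a factor 1/(1+λ), so λ = 10⁻⁶ is an
   essentially free mean and λ = 5·10⁻⁴ a very slightly stiffer one);
3. the mean is re-centred and re-scaled to the instances' RMS radius, which
   removes global drift (the unbiasedness device). Kendall centroid size
   grows with sqrt(point count), so scaling an `n_mean`-point mean to *its
   own* unit centroid size would make it geometrically
   sqrt(n_instance/n_mean) larger than the unit-size instances — a
   systematic mismatch that silently wrecks alignment whenever the mean is
   sparser than the instances. The mean's centroid size equals 1 exactly
   when `n_mean` matches the instances' point count.

σ is stated in millimetres and divided by the median recorded centroid size,
so the conventional σ = 3 mm remains meaningful after normalisation.

Numerical choices that proved necessary, and are therefore defaults:

* **Per-instance deterministic annealing.** Within each instance alignment
  the kernel decays geometrically from a wide start
  (max(σ, 0.3 × cloud RMS radius)) to a floor of 0.25 σ over the `n_em` EM
  iterations. A wide *outer* annealing loop (kernel shared across the whole
  outer iteration) was tried first and discarded: it blurs the evolving
  mean into a near-featureless blob for many iterations, during which
  instance orientations drift and lock into wrong rotational registers.
  Annealing per instance keeps the mean crisp — it is always rebuilt under
  the sharpest kernel.
* **Dual-candidate guard.** The annealed alignment (wide basin, can rescue a
  badly posed instance) and a sharp-kernel refinement of the incoming pose
  (never disturbs a good alignment) are both computed, and the candidate
  with the higher likelihood under the sharpest kernel wins. From the second
  outer iteration on, only the sharp refinement is run. Without the guard,
  the wide kernel occasionally scrambles already-registered instances.
* **Scale clamping.** The instances are unit-centroid-size and the mean is
  scaled to their RMS radius, so the true scale is near 1; the M-step scale
  is clamped to
  [0.85, 1.2] (translation refit in closed form). This removes the classic
  GMM-registration failure mode in which a misaligned cloud shrinks onto
  the mean and then re-expands in an arbitrary orientation.
* The kernel floor (0.25 σ) is at the scale of residual shape differences;
  evaluating candidate likelihoods at a much smaller kernel makes the
  comparison noise-dominated and was a diagnosed failure source.

Convergence is declared when the relative Frobenius change of the mean falls
below `tol` (default 10⁻⁶); non-convergence is a warning, not an error, and
downstream stages can be forced. The EM objective (mixture log-likelihood)
is recorded per E-step and is non-decreasing whenever the kernel is fixed.

## Dense correspondence

A template of N points is drawn from the converged mean cloud (a seeded
subsample; when N exceeds the mean's resolution, extra points interpolate
between neighbouring mean points). For each instance the template points are
matched one-to-one to instance points by minimising
`‖Δposition‖² + w·‖Δnormal‖²` under a linear assignment constraint.
Candidates are the 20 nearest positional neighbours per template point,
solved by sparse min-weight bipartite matching (costs shifted by +1 so true
zero costs survive sparse storage); if that graph has no perfect matching
the dense Hungarian algorithm is used. `w` defaults to 0.1 on unit-size
clouds with unit normals. Rows of the resulting matrix are in template
order, identical across instances.

The matched coordinates inherit the tangential quantisation of the sampled
instance points (≈ half the inter-point spacing). This sampling jitter is
the dominant noise source of the whole chain at desk scale and sets how
dense the sampling must be for a given shape-signal size.

## Shape model

PCA is computed by SVD of the row-centred correspondence matrix — exact, and
never forms the 3N×3N covariance (N can exceed 10⁴). Eigenvalues use the
n−1 divisor; modes are orthonormal; the sign of each mode is pinned by
making its largest-magnitude entry positive so b values reproduce across
runs. Retention keeps the modes whose variance fraction strictly exceeds the
threshold (default 5 %), never fewer than one. Shape parameters are exposed
raw and in SD units (b/√λ); group statistics are scale-invariant so the
choice does not affect p-values.

## Group statistics

Per retained mode: a Lilliefors-corrected KS normality screen (mean and SD
are estimated, so the naive KS null would be anti-conservative; the
statsmodels table approximation is the default and a seeded Monte-Carlo null
is available), a one-way fixed-effects ANOVA over the three groups, the
classic Bonferroni post-hoc (pairwise t with the pooled MSE on N−k df, raw p
×3 capped at 1; Welch pairing available), and an ANCOVA in which the group
effect is the extra-sum-of-squares F test of `b ~ group + age + gender`
against the covariate-only model. Degenerate covariates (single gender,
constant age) are dropped with a warning. A mode is flagged for a pair of
groups when the Bonferroni-adjusted p is below α (default 0.05); no
correction is applied across modes. α = 1 is treated as "flag everything".

The three groups share subjects (both ankles of each patient enter, and
optionally both ankles of bilateral controls). The analysis mirrors the
conventional independent-groups treatment but emits a warning, and
`healthy_policy="one-per-subject"` restricts bilateral controls to one
seeded-random ankle.

ANOVA and ANCOVA p-values differ slightly even when the covariates carry no
effect (two residual df are spent and random covariate–group correlation
perturbs F): by simulation the mean |Δp| is ≈ 0.04 at n ≈ 60–100 while the
signed difference is unbiased. Significance *flags* agree in ≈ 99 % of null
replicates.

## Synthetic cohort generator

The generator emulates the study conditions of a case-control subtalar
morphometry cohort:

* **Template**: a superellipsoid (semi-axes 30 × 22 × 18 mm, exponent 2.5)
  with three fixed broad lobes — an offset "head/neck", an opposing
  "tuberosity" and a ridge — plus seeded random bumps, on icosphere
  topology (default 2,562 vertices). The fixed lobes matter: without them
  the blob is nearly rotation-symmetric at the registration kernel scale
  and orientation is fundamentally unrecoverable; real tarsal bones are
  decisively asymmetric. Template geometry and planted fields are keyed by
  `template_seed` (one anatomy across replicate cohorts, as in a real
  study); the cohort seed drives draws, poses and noise.
* **Latent modes**: k orthonormal displacement fields (default k = 4), each
  a smooth polynomial profile times the vertex normal. Normal displacement
  is used because tangential displacement merely re-parametrises the
  surface and is invisible to any correspondence method. The profiles are
  projected orthogonal to the normal components of the similarity group's
  tangent fields (3 rotations, 3 translations, scaling) — a mode
  overlapping those would be correctly absorbed into pose by registration
  and the planted variance would be unidentifiable.
* **Spectrum**: latent variances (6.0, 2.0, 0.6, 0.2 mm²) of
  per-vertex RMS displacement, i.e. top-mode shape variation of ≈ 2.4 mm
  RMS on a ≈ 50 mm bone — the scale at which published tarsal SSM modes
  show clearly visible shape changes — with adjacent ratios ≥ 3 so modes
  are well separated.
* **Effect**: the group difference is a mean offset of `effect_size` SD on
  one designated latent mode (default mode 2), applied equally to the
  patients' unstable and contralateral ankles (`contralateral_fraction`
  = 1), encoding the observation that bone shape does not differ within a
  patient. Latent coordinates are drawn independently per instance; real
  contralateral pairs are additionally within-subject correlated, which
  the generator does not model (a known limitation — it makes the
  patient-vs-contralateral comparison conservative rather than
  anticonservative).
* **Nuisance**: measurement noise of 0.1 mm along vertex normals, rotations
  up to 20° (scans of a positioned foot vary moderately in orientation),
  translations up to 10 mm, scale 0.9–1.1, right-side mirroring with 62 %
  of patients right-affected; ages uniform per group (18–50 patients,
  20–55 controls), genders Bernoulli(0.5); an optional age→effect-mode
  slope plants a confound.
* **Cohort structure**: 26 patients (ipsilateral + contralateral bone
  each), 20 bilateral and 6 unilateral controls — 98 instances.

## Validation: what passing tests show

Validation runs at reduced resolution: 642-vertex meshes, 200–700 surface
samples per instance, 150–400 corresponded points, mean clouds of 150–200
points, against thousands of points in a full-scale analysis. At these sizes:

* pose recovery: similarity perturbations (rotations ≤ 30°, scale 0.8–1.2)
  are undone to RMSD < 10⁻³ on unit-size clouds in ≥ 98 % of trials (in
  most trials to machine precision);
* null calibration: with no planted difference, a retained mode is flagged
  at α = 0.05 in ≈ 4.5–5 % of replicates (pooled statistic-level and
  end-to-end);
* planted-effect recovery: a 1.5 SD offset on one latent mode is recovered
  — right mode, right group pairs, no within-patient flag — in ≥ 95 % of
  end-to-end replicates at 700 samples and 400 corresponded points per
  instance.

These results show the chain is internally consistent and statistically
calibrated under the generator's assumptions. They do not show robustness to
segmentation artefacts, missing surface regions, topological defects, or
anatomies far from the template family; real cohorts also bring
scanner-dependent resolution differences the generator does not model.

## Other limitations

* Registration is similarity-only by design; non-rigid residuals are
  handled statistically by the shape model, not geometrically.
* The correspondence is nearest-assignment, not geodesic or spectral; for
  strongly folded surfaces one-to-one Euclidean matching can shortcut
  across concavities.
* No multiplicity correction is applied across modes (conventional for
  mode-wise SSM comparisons); across-mode family-wise error grows with the
  number of retained modes.
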