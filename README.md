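# bonessm

Statistical shape modelling of bone cohorts: groupwise registration of bone
surfaces, dense surface correspondence, PCA point-distribution models, and
mode-wise statistical comparison of patient groups — with a synthetic
bone-cohort generator so that the whole chain is testable without any scan
data.

## The problem

Chronic ankle instability (CAI) — recurrent giving-way after a lateral ankle
sprain — may be linked to the three-dimensional shape of the subtalar joint
bones (talus and calcaneus). Comparing 3D bone shape across groups requires
more than a handful of calliper measurements: it calls for a statistical
shape model (SSM), built from a cohort of segmented bone surfaces, in which
every bone is described by a small number of interpretable shape parameters.

This package implements that analysis end to end for cohorts of triangulated
bone surfaces with group labels (patient ankle, the same patients'
contralateral ankle, healthy controls), side, age and gender:

1. **Pose normalisation** — right-side bones are mirrored in the sagittal
   plane; each surface is sampled into a point cloud, translated to the
   origin and scaled to unit centroid size
   (`S = sqrt(Σ ||p_i − p̄||²)`, Kendall's size measure).
2. **Unbiased groupwise registration** — all clouds are aligned by
   similarity transforms to an *evolving* Gaussian-mixture mean cloud
   (kernel width σ, `n_m` mean points, stiffness λ), so no single specimen
   biases the atlas.
3. **Dense correspondence** — a template of N points on the mean surface is
   matched one-to-one into every instance by a linear assignment on the cost
   `‖Δposition‖² + w·‖Δnormal‖²`.
4. **Shape model** — PCA of the corresponded coordinates yields the mean
   shape x̄ and orthonormal modes Φ with eigenvalues λ, so any shape is

   x = x̄ + Σₛ bₛ Φₛ

   with shape parameters b (reported raw and in SD units bₛ/√λₛ). Modes
   carrying more than 5 % of total variance are retained.
5. **Group statistics** — per retained mode: a Lilliefors-corrected KS
   normality screen, one-way ANOVA across the three groups with Bonferroni
   post-hoc pairwise tests, and an age/gender-adjusted ANCOVA.

Because real clinical CT cohorts are rarely shareable, the package ships a
generator of virtual bone populations: a watertight tarsal-bone-like
template deformed along smooth orthonormal latent modes with a planted
group difference, per-vertex noise, random poses and left/right mirroring,
in the cohort structure of a typical case-control ankle study (26 patients
with one unstable ankle, 26 controls, 98 bone instances).

## Worked example

```python
from bonessm import GeneratorConfig, sample_cohort, analyze_cohort

cfg = GeneratorConfig(subdivisions=3, effect_size=1.5, seed=11)
meshes, metadata, truth = sample_cohort(cfg)   # 98 synthetic bone surfaces
ssm, table, result = analyze_cohort(meshes, metadata, seed=11)

evr = ssm.explained_variance_ratio_
print(f"retained modes: {ssm.n_retained_}")
print(f"variance explained: {[round(float(v), 3) for v in evr[:4]]}")
print(f"significant modes: {result.significant_modes()}")
```

Output:

```
retained modes: 2
variance explained: [0.438, 0.144, 0.048, 0.029]
significant modes: {'b2': [('CAI', 'HEALTHY'), ('CAI_CONTRA', 'HEALTHY')]}
```

Two fitted modes each explain more than 5 % of the total shape variance.
Mode 2's shape parameter differs significantly between patient ankles and
healthy controls and between the patients' contralateral ankles and healthy
controls, but not between the two sides of the patients — exactly the
planted structure: a 1.5 SD offset on one latent mode, equal in both ankles
of each patient.

The same analysis is scriptable from the shell:

```bash
ssm run-all --config cohort.yaml --out results/ --seed 11
ssm simulate --out cohort/ --seed 1         # write meshes + metadata.csv
ssm build --correspondence corr.csv --threshold 0.05 --out model.npz
```

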