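"""Virtual bone cohorts with known ground truth.

Real subtalar CT cohorts are not publicly available, so every stage of the
pipeline is exercised on generated populations with planted structure:

* a watertight template surface — a superellipsoid (a compact, slightly boxy
  tarsal-bone-like blob) decorated with smooth Gaussian bumps — built on an
  icosphere topology shared by all instances;
* k orthonormal smooth displacement fields over the template vertices acting
  as latent modes of shape variation, with a strictly decreasing variance
  spectrum;
* a designated effect mode whose latent mean is shifted in the patient groups
  (ipsilateral instances by ``effect_size`` SD, contralateral ones by a
  configurable fraction, default the full effect: within a patient the two
  sides are alike, and both differ from controls);
* per-vertex measurement noise along the vertex normals, a random similarity
  transform per instance, and mirroring of right-side instances;
* the study's cohort structure: 26 patients with one unstable ankle (each
  contributing an ipsilateral and a contralateral bone), 26 controls of whom
  20 are scanned bilaterally and 6 unilaterally — 98 instances in all — with
  ages and genders per group.

Latent coordinates are drawn independently per instance; spectrum entries are
the variances (mm^2) of the per-vertex RMS displacement each mode produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import SurfaceMesh, mirror_sagittal, vertex_normals
from .transforms import SimilarityTransform, random_rotation

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "make_template",
    "make_latent_modes",
    "sample_cohort",
]

_SUBDIV_VERTS = {0: 12, 1: 42, 2: 162, 3: 642, 4: 2562}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort."""

    n_cai: int = 26
    n_healthy: int = 26
    n_bilateral_healthy: int = 20
    # template geometry (mm)
    semi_axes: tuple = (30.0, 22.0, 18.0)
    exponent: float = 2.5
    n_bumps: int = 4
    bump_amplitude: float = 6.0
    bump_sharpness: float = 5.0
    subdivisions: int = 4          # 2562 vertices
    # latent shape structure
    latent_modes: int = 4
    spectrum: tuple = (6.0, 2.0, 0.6, 0.2)     # mm^2 per-vertex RMS variance
    effect_mode: int = 2           # 1-based, mirroring the talus finding
    effect_size: float = 1.5       # group mean offset in SD units
    contralateral_fraction: float = 1.0
    noise_sd: float = 0.1          # mm, along vertex normals
    noise_isotropic: bool = False
    # pose
    max_rotation_deg: float = 20.0
    max_translation: float = 10.0  # mm
    scale_range: tuple = (0.9, 1.1)
    prob_right_affected: float = 0.62
    # covariates
    age_range_cai: tuple = (18.0, 50.0)
    age_range_healthy: tuple = (20.0, 55.0)
    gender_ratio: float = 0.5
    confound_age_slope: float = 0.0   # latent effect-mode shift per year of age
    template_seed: int = 0         # anatomy (template + planted fields); the
                                   # cohort seed drives draws, poses and noise
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.spectrum) != self.latent_modes:
            raise ValueError("spectrum length must equal latent_modes")
        if np.any(np.diff(self.spectrum) >= 0):
            raise ValueError("spectrum must be strictly decreasing")
        if not 1 <= self.effect_mode <= self.latent_modes:
            raise ValueError("effect_mode must index a latent mode (1-based)")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be >= 0")
        if self.n_bilateral_healthy > self.n_healthy:
            raise ValueError("n_bilateral_healthy cannot exceed n_healthy")
        if self.subdivisions not in _SUBDIV_VERTS:
            raise ValueError(f"subdivisions must be one of {sorted(_SUBDIV_VERTS)}")


@dataclass
class GroundTruth:
    """Planted values per instance/subject."""

    transforms: dict = field(default_factory=dict)   # instance_id -> SimilarityTransform
    latents: dict = field(default_factory=dict)      # instance_id -> (k,) latent coords
    groups: dict = field(default_factory=dict)       # instance_id -> group label
    ages: dict = field(default_factory=dict)         # subject_id -> age
    genders: dict = field(default_factory=dict)      # subject_id -> gender
    config: GeneratorConfig | None = None

    def latent_matrix(self, instance_ids: list) -> np.ndarray:
        return np.vstack([self.latents[i] for i in instance_ids])


def make_template(config: GeneratorConfig) -> SurfaceMesh:
    """Superellipsoid-with-bumps template on icosphere topology (watertight)."""
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=config.subdivisions, radius=1.0)
    u = np.asarray(ico.vertices, dtype=float)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    a, b, c = config.semi_axes
    r = config.exponent
    # radial scale t(u) with |t u_x / a|^r + |t u_y / b|^r + |t u_z / c|^r = 1
    t = (np.abs(u[:, 0] / a) ** r + np.abs(u[:, 1] / b) ** r
         + np.abs(u[:, 2] / c) ** r) ** (-1.0 / r)
    verts = t[:, None] * u

    # fixed coarse lobes: a broad offset "head/neck" and an opposing
    # "tuberosity", mimicking the decisive asymmetry of tarsal bones; without
    # them the blob is nearly rotation-symmetric at the registration kernel
    # scale and orientation cannot be recovered (real bones are never that
    # symmetric)
    head_dir = np.array([1.0, 0.35, 0.15])
    head_dir /= np.linalg.norm(head_dir)
    tuber_dir = np.array([-0.6, -0.5, 0.6])
    tuber_dir /= np.linalg.norm(tuber_dir)
    ridge_dir = np.array([0.1, 0.9, -0.45])
    ridge_dir /= np.linalg.norm(ridge_dir)
    verts = verts + (0.40 * a * np.exp(2.5 * (u @ head_dir - 1.0)))[:, None] * u
    verts = verts + (0.22 * a * np.exp(4.0 * (u @ tuber_dir - 1.0)))[:, None] * u
    verts = verts + (0.18 * a * np.exp(3.0 * (u @ ridge_dir - 1.0)))[:, None] * u

    rng = np.random.default_rng(np.random.SeedSequence((config.template_seed, 101)))
    for _ in range(config.n_bumps):
        centre = rng.normal(size=3)
        centre /= np.linalg.norm(centre)
        amp = config.bump_amplitude * rng.uniform(0.5, 1.0)
        verts = verts + (amp * np.exp(config.bump_sharpness * (u @ centre - 1.0)))[:, None] * u

    return SurfaceMesh(vertices=verts, faces=np.asarray(ico.faces, dtype=int),
                       instance_id="template")


def make_latent_modes(template: SurfaceMesh, k: int, seed: int = 0) -> np.ndarray:
    """k orthonormal smooth displacement fields, shape (k, V, 3).

    Each field displaces vertices along their outward normals by a smooth
    scalar profile — a seeded Gaussian mixture of low-order harmonic
    polynomials of the radial direction (x, y, z, xy, xz, yz, x^2-y^2,
    3z^2-1). Normal displacement is used because it genuinely changes the
    surface geometry; tangential components would merely re-parametrise the
    surface and be invisible to any correspondence method. A QR step makes the
    k fields orthonormal over the 3V vertex coordinates; smoothness is
    inherited from the polynomial profiles.
    """
    if k < 1:
        raise ValueError("need k >= 1 latent modes")
    u = template.vertices / np.linalg.norm(template.vertices, axis=1, keepdims=True)
    x, y, z = u.T
    scalars = np.stack([
        x, y, z,
        x * y, x * z, y * z, x**2 - y**2, 3.0 * z**2 - 1.0,
        x * y * z, x * (x**2 - 3 * y**2), y * (y**2 - 3 * z**2),
        z * (z**2 - 3 * x**2), x * (5 * z**2 - 1), y * (5 * x**2 - 1),
        z * (5 * y**2 - 1),
    ], axis=1)                                   # (V, 15)
    V = len(u)

    # normal-displacement profiles of the similarity group's tangent fields:
    # a mode overlapping these would be (correctly) absorbed into pose by any
    # registration, so planted shape variation must be orthogonal to them
    r = template.vertices
    n = template.normals
    pose = np.column_stack(
        [n[:, i] for i in range(3)]                       # translations
        + [np.cross(np.eye(3)[i], r).ravel().reshape(V, 3).__mul__(n).sum(1)
           for i in range(3)]                              # rotations
        + [(r * n).sum(1)]                                 # scaling
    )
    P, _ = np.linalg.qr(pose)
    resid = scalars - P @ (P.T @ scalars)

    n_cand = resid.shape[1]
    if k > n_cand:
        raise ValueError(f"k={k} exceeds the {n_cand} available basis fields")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 202)))
    profiles = resid @ rng.standard_normal((n_cand, k))     # (V, k)
    profiles = profiles - P @ (P.T @ profiles)
    cand = profiles[:, None, :] * n[:, :, None]             # (V, 3, k)
    q, _ = np.linalg.qr(cand.reshape(3 * V, k))
    return q.T.reshape(k, V, 3)


def _instance_mesh(template, fields, z, noise_sd, isotropic, rng):
    V = len(template.vertices)
    disp = np.einsum("s,svk->vk", z * np.sqrt(V), fields)
    verts = template.vertices + disp
    if noise_sd > 0:
        if isotropic:
            verts = verts + rng.normal(scale=noise_sd, size=verts.shape)
        else:
            normals = vertex_normals(verts, template.faces)
            verts = verts + normals * rng.normal(scale=noise_sd, size=(V, 1))
    return verts


def sample_cohort(config: GeneratorConfig):
    """Generate one cohort.

    Returns ``(meshes, metadata, truth)``: a list of SurfaceMesh (one per bone
    instance), a metadata DataFrame with columns subject_id, instance_id,
    group, side, age, gender, and the :class:`GroundTruth`. Deterministic
    given the config (same config and seed give identical output).
    """
    template = make_template(config)
    fields = make_latent_modes(template, config.latent_modes, seed=config.template_seed)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 303)))
    sd = np.sqrt(np.asarray(config.spectrum, dtype=float))
    e = config.effect_mode - 1

    rows = []
    meshes = []
    truth = GroundTruth(config=config)

    def emit(subject_id, group, side, age, gender, mean_shift):
        iid = f"{subject_id}_{side}"
        z = rng.normal(size=config.latent_modes) * sd
        z[e] += mean_shift
        if config.confound_age_slope:
            z[e] += config.confound_age_slope * (age - 30.0)
        verts = _instance_mesh(template, fields, z, config.noise_sd,
                               config.noise_isotropic, rng)
        mesh = SurfaceMesh(vertices=verts, faces=template.faces.copy(),
                           instance_id=iid)
        R = random_rotation(rng, config.max_rotation_deg)
        tvec = rng.uniform(-config.max_translation, config.max_translation, size=3)
        s = rng.uniform(*config.scale_range)
        tform = SimilarityTransform(rotation=R, translation=tvec, scale=s)
        if side == "R":
            mesh = mirror_sagittal(mesh)
        mesh = SurfaceMesh(vertices=tform.apply(mesh.vertices),
                           faces=mesh.faces, instance_id=iid)
        meshes.append(mesh)
        rows.append({"subject_id": subject_id, "instance_id": iid,
                     "group": group, "side": side, "age": age, "gender": gender})
        truth.transforms[iid] = tform
        truth.latents[iid] = z
        truth.groups[iid] = group

    effect = config.effect_size * sd[e]
    for i in range(config.n_cai):
        sid = f"CAI{i + 1:02d}"
        age = rng.uniform(*config.age_range_cai)
        gender = "M" if rng.random() < config.gender_ratio else "F"
        truth.ages[sid], truth.genders[sid] = age, gender
        affected = "R" if rng.random() < config.prob_right_affected else "L"
        contra = "L" if affected == "R" else "R"
        emit(sid, "CAI", affected, age, gender, effect)
        emit(sid, "CAI_CONTRA", contra, age, gender,
             config.contralateral_fraction * effect)

    for i in range(config.n_healthy):
        sid = f"HC{i + 1:02d}"
        age = rng.uniform(*config.age_range_healthy)
        gender = "M" if rng.random() < config.gender_ratio else "F"
        truth.ages[sid], truth.genders[sid] = age, gender
        if i < config.n_bilateral_healthy:
            emit(sid, "HEALTHY", "L", age, gender, 0.0)
            emit(sid, "HEALTHY", "R", age, gender, 0.0)
        else:
            emit(sid, "HEALTHY", "L", age, gender, 0.0)

    metadata = pd.DataFrame(rows)
    return meshes, metadata, truth
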