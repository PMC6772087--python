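import warnings

import numpy as np
import pytest
from scipy.spatial import cKDTree

from bonessm.mesh import MeshValidationError, PointCloud, center_and_scale, sample_surface
from bonessm.registration import (
    GroupwiseRegistration,
    RegistrationParams,
    apply_transform,
    groupwise_register,
)
from bonessm.transforms import SimilarityTransform, random_rotation


def _clouds_from_template(template, n_points, seeds):
    return [center_and_scale(sample_surface(template, n_points, seed=s))
            for s in seeds]


class TestRegistrationParams:
    @pytest.mark.parametrize("kwargs", [
        {"sigma": 0.0}, {"n_mean": 3}, {"lam": -1.0},
        {"max_iters": 0}, {"tol": 0.0},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RegistrationParams(**kwargs)


class TestApplyTransform:
    def test_identity(self, bone_template):
        cloud = center_and_scale(sample_surface(bone_template, 50, seed=0))
        out = apply_transform(cloud, SimilarityTransform.identity())
        assert np.array_equal(out.points, cloud.points)

    def test_translation(self):
        cloud = PointCloud(points=np.zeros((5, 3)))
        t = SimilarityTransform(translation=np.array([1.0, 0, 0]))
        assert np.allclose(apply_transform(cloud, t).points, [[1.0, 0, 0]] * 5)

    def test_inverse_composition_roundtrip(self, bone_template):
        rng = np.random.default_rng(2)
        t = SimilarityTransform(rotation=random_rotation(rng),
                                translation=rng.normal(size=3), scale=1.4)
        cloud = center_and_scale(sample_surface(bone_template, 80, seed=1))
        back = apply_transform(apply_transform(cloud, t), t.inverse())
        assert np.allclose(back.points, cloud.points, atol=1e-9)


class TestGroupwiseRegistration:
    def test_identical_clouds_get_identity_transforms(self, bone_template):
        cloud = center_and_scale(sample_surface(bone_template, 150, seed=0))
        twin = PointCloud(points=cloud.points.copy(),
                          normals=cloud.normals.copy(),
                          centroid_size=cloud.centroid_size)
        reg = GroupwiseRegistration(sigma=3.0, n_mean=150, max_iters=4,
                                    n_em=20, sigma_floor_frac=0.01,
                                    random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            reg.fit([cloud, twin])
        for t in reg.transforms_:
            assert np.allclose(t.rotation, np.eye(3), atol=1e-6)
            assert t.scale == pytest.approx(1.0, abs=1e-6)
            assert np.allclose(t.translation, 0.0, atol=1e-6)

    def test_recovers_known_rotation(self, bone_template):
        rng = np.random.default_rng(4)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(25.0)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
        cloud = sample_surface(bone_template, 400, seed=3)
        moved = PointCloud(points=cloud.points @ R.T,
                           normals=cloud.normals @ R.T)
        reg = GroupwiseRegistration(sigma=3.0, n_mean=400, max_iters=5,
                                    n_em=20, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            reg.fit([center_and_scale(cloud), center_and_scale(moved)])
        rel = reg.transforms_[1].rotation.T @ reg.transforms_[0].rotation
        est_angle = np.degrees(
            np.arccos(np.clip((np.trace(rel.T @ R) - 1) / 2, -1, 1)))
        assert est_angle < 0.5

    def test_run_log_echoes_parameters(self, bone_template):
        clouds = _clouds_from_template(bone_template, 60, [0, 1])
        reg = GroupwiseRegistration(sigma=3.0, n_mean=2000, lam=1e-6,
                                    max_iters=2, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            reg.fit(clouds)
        assert reg.log_["params"]["sigma"] == 3.0
        assert reg.log_["params"]["n_mean"] == 2000
        assert reg.log_["params"]["lam"] == 1e-6
        # the calcaneus setting is just a different lam
        assert GroupwiseRegistration(lam=5e-4).get_params()["lam"] == 5e-4

    def test_rejects_unnormalised_clouds(self, bone_template):
        raw = sample_surface(bone_template, 50, seed=0)  # mm, not normalised
        reg = GroupwiseRegistration(n_mean=50)
        with pytest.raises(MeshValidationError, match="center_and_scale"):
            reg.fit([raw, raw])

    def test_rejects_single_cloud(self, bone_template):
        cloud = center_and_scale(sample_surface(bone_template, 50, seed=0))
        with pytest.raises(MeshValidationError, match=">= 2"):
            GroupwiseRegistration(n_mean=50).fit([cloud])

    def test_nonconvergence_warns_not_raises(self, bone_template):
        clouds = _clouds_from_template(bone_template, 80, [0, 1, 2])
        reg = GroupwiseRegistration(sigma=3.0, n_mean=80, max_iters=1,
                                    tol=1e-15, random_state=0)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            reg.fit(clouds)
        assert reg.converged_ is False

    def test_mean_cloud_is_unbiased(self, registered_cohort):
        # no global drift: centred, and scaled to the instances' RMS radius
        mean = registered_cohort.mean_cloud.points
        assert np.linalg.norm(mean.mean(axis=0)) < 1e-6
        rms = np.sqrt(np.mean(np.sum(mean**2, axis=1)))
        # input clouds are unit-centroid-size with 200 points each, so their
        # RMS radius is exactly 1/sqrt(200); the mean must sit at that scale
        assert rms == pytest.approx(1.0 / np.sqrt(200), rel=1e-9)

    def test_mean_cloud_unit_size_when_counts_match(self, bone_template):
        # with n_mean equal to the instances' point count, the mean keeps
        # exactly unit centroid size
        clouds = _clouds_from_template(bone_template, 120, [0, 1, 2])
        reg = GroupwiseRegistration(sigma=3.0, n_mean=120, max_iters=3,
                                    random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            reg.fit(clouds)
        mean = reg.mean_cloud_.points
        size = np.sqrt(np.sum((mean - mean.mean(axis=0)) ** 2))
        assert size == pytest.approx(1.0, abs=1e-6)

    def test_objective_nondecreasing_with_fixed_kernel(self, bone_template):
        clouds = _clouds_from_template(bone_template, 100, [0, 1, 2])
        reg = GroupwiseRegistration(sigma=3.0, n_mean=100, max_iters=3,
                                    n_em=6, anneal=False, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            reg.fit(clouds)
        for outer in reg.objective_traces_:
            for trace in outer:
                diffs = np.diff(trace)
                assert np.all(diffs > -1e-6), f"EM objective decreased: {trace}"

    def test_order_invariance_weak(self, bone_template):
        clouds = _clouds_from_template(bone_template, 150, [0, 1, 2, 3])
        kw = dict(sigma=3.0, n_mean=100, max_iters=4, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m1 = GroupwiseRegistration(**kw).fit(clouds).mean_cloud_.points
            m2 = GroupwiseRegistration(**kw).fit(clouds[::-1]).mean_cloud_.points
        # mean point sets are ordered differently: compare as surfaces
        d12 = cKDTree(m1).query(m2)[0]
        d21 = cKDTree(m2).query(m1)[0]
        chamfer_rms = np.sqrt(0.5 * (np.mean(d12**2) + np.mean(d21**2)))
        assert chamfer_rms < 1e-2

    def test_transforms_are_proper_rotations(self, registered_cohort):
        for t in registered_cohort.transforms:
            assert np.allclose(t.rotation.T @ t.rotation, np.eye(3), atol=1e-6)
            assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_functional_wrapper(self, bone_template):
        clouds = _clouds_from_template(bone_template, 60, [0, 1])
        params = RegistrationParams(sigma=3.0, n_mean=60, max_iters=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cohort = groupwise_register(clouds, params, seed=0)
        assert len(cohort.clouds) == len(cohort.transforms) == 2

    def test_sklearn_param_interface(self):
        reg = GroupwiseRegistration()
        reg.set_params(sigma=5.0, lam=5e-4)
        assert reg.get_params()["sigma"] == 5.0
        with pytest.raises(ValueError):
            reg.set_params(bogus=1)
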