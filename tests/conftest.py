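import numpy as np
import pytest

from bonessm.mesh import SurfaceMesh, center_and_scale, sample_surface
from bonessm.synthetic import GeneratorConfig, make_template, sample_cohort


@pytest.fixture
def tetrahedron() -> SurfaceMesh:
    """Smallest closed mesh: a regular tetrahedron (outward winding)."""
    v = np.array([
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ])
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return SurfaceMesh(vertices=v, faces=f)


@pytest.fixture(scope="session")
def icosphere() -> SurfaceMesh:
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    return SurfaceMesh(vertices=np.asarray(ico.vertices),
                       faces=np.asarray(ico.faces))


@pytest.fixture(scope="session")
def bone_template() -> SurfaceMesh:
    return make_template(GeneratorConfig(subdivisions=3))


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale synthetic cohort: 5+5 subjects, 162-vertex meshes."""
    cfg = GeneratorConfig(n_cai=5, n_healthy=5, n_bilateral_healthy=3,
                          subdivisions=2, effect_size=0.0, seed=42)
    return sample_cohort(cfg)


@pytest.fixture(scope="session")
def registered_cohort(bone_template):
    """Four normalised samplings of the same template, groupwise registered.

    Shared by correspondence and model tests that only need a converged
    cohort, not group structure.
    """
    import warnings

    from bonessm.registration import GroupwiseRegistration

    clouds = [center_and_scale(sample_surface(bone_template, 200, seed=s))
              for s in range(4)]
    reg = GroupwiseRegistration(sigma=3.0, n_mean=150, max_iters=4, n_em=10,
                                random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        reg.fit(clouds)
    return reg.to_cohort()
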