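"""Surface meshes and point clouds: the raw representations of one bone instance.

A bone enters the pipeline as a closed triangulated surface (``SurfaceMesh``),
is mirrored to a common side if needed, sampled into a point cloud, and
normalised to zero centroid and unit centroid size before registration.

Centroid size follows Kendall's definition,
``S = sqrt(sum_i ||p_i - mean(p)||^2)``, the standard size measure removed in
morphometrics before shape comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SurfaceMesh",
    "PointCloud",
    "MeshValidationError",
    "read_mesh",
    "write_mesh",
    "mirror_sagittal",
    "center_and_scale",
    "centroid_size",
    "sample_surface",
    "vertex_normals",
]


class MeshValidationError(ValueError):
    """Raised when a mesh or point cloud violates its structural invariants."""


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-vertex outward unit normals as area-weighted averages of face normals.

    The cross product of the face edge vectors has magnitude 2·area, so simply
    accumulating un-normalised face cross products at each vertex gives the
    area weighting for free.
    """
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=int)
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    out = np.zeros_like(v)
    for k in range(3):
        np.add.at(out, f[:, k], fn)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    # isolated/degenerate vertices get an arbitrary unit vector
    bad = norms[:, 0] <= np.finfo(float).eps
    out[bad] = (0.0, 0.0, 1.0)
    norms[bad] = 1.0
    return out / norms


@dataclass
class SurfaceMesh:
    """Closed triangulated surface with per-vertex outward unit normals."""

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None
    instance_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must have shape (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must have shape (m, 3)")
        if len(self.vertices) < 4 or len(self.faces) < 4:
            raise MeshValidationError(
                f"mesh needs >=4 vertices and >=4 faces; got "
                f"{len(self.vertices)} vertices, {len(self.faces)} faces"
            )
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshValidationError("face indices out of range")
        if self.normals is None:
            self.normals = vertex_normals(self.vertices, self.faces)
        else:
            self.normals = np.asarray(self.normals, dtype=float)
            if self.normals.shape != self.vertices.shape:
                raise MeshValidationError("normals must match vertices in shape")
            lens = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(lens, 1.0, atol=1e-6):
                raise MeshValidationError("normals must have unit length")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )


@dataclass
class PointCloud:
    """Points sampled across a bone surface, with optional per-point normals.

    ``centroid_size`` records the Kendall size (in mm) measured before
    normalisation, so parameters stated in millimetres (such as the
    registration kernel width) stay meaningful on unit-size clouds.
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    centroid_size: float | None = None
    instance_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MeshValidationError("points must have shape (n, 3)")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)
            if self.normals.shape != self.points.shape:
                raise MeshValidationError("normals must match points in shape")
        if self.centroid_size is not None and not self.centroid_size > 0:
            raise MeshValidationError("centroid_size must be positive")

    def __len__(self) -> int:
        return len(self.points)


def read_mesh(path, fmt: str | None = None) -> SurfaceMesh:
    """Read a triangulated surface from PLY/STL/OBJ.

    Normals are always recomputed (area-weighted) rather than trusted from the
    file. Raises ``IOError`` on unreadable files and ``MeshValidationError`` on
    degenerate geometry.
    """
    import trimesh

    try:
        loaded = trimesh.load(str(path), file_type=fmt.lower() if fmt else None,
                              force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalise loader errors
        raise IOError(f"could not read mesh from {path}: {exc}") from exc
    if not hasattr(loaded, "faces") or len(getattr(loaded, "faces", [])) == 0:
        raise IOError(f"could not read mesh from {path}: no triangulated geometry")
    loaded.merge_vertices()  # STL stores a triangle soup; reunify shared vertices
    return SurfaceMesh(
        vertices=np.asarray(loaded.vertices, dtype=float),
        faces=np.asarray(loaded.faces, dtype=int),
        instance_id=str(path),
    )


def write_mesh(mesh: SurfaceMesh, path) -> None:
    mesh.to_trimesh().export(str(path))


def mirror_sagittal(mesh: SurfaceMesh, axis: int = 0) -> SurfaceMesh:
    """Mirror a bone across the sagittal plane (negate the medial-lateral axis).

    Face winding is reversed so normals stay outward. The axis index is a
    configuration choice; axis 0 by default, override to match the coordinate
    convention of the scans at hand. Applying the operation twice restores the
    input exactly.
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    v = mesh.vertices.copy()
    v[:, axis] = -v[:, axis]
    n = mesh.normals.copy()
    n[:, axis] = -n[:, axis]
    return SurfaceMesh(
        vertices=v,
        faces=mesh.faces[:, ::-1].copy(),
        normals=n,
        instance_id=mesh.instance_id,
    )


def centroid_size(points: np.ndarray) -> float:
    p = np.asarray(points, dtype=float)
    c = p.mean(axis=0)
    return float(np.sqrt(np.sum((p - c) ** 2)))


def center_and_scale(cloud: PointCloud) -> PointCloud:
    """Translate the centroid to the origin and scale to unit centroid size.

    The measured size is recorded (compounded with any size recorded earlier,
    so the operation is idempotent and the stored value keeps meaning mm).
    """
    if len(cloud) < 2:
        raise MeshValidationError("need at least 2 points to normalise")
    c = cloud.points.mean(axis=0)
    size = centroid_size(cloud.points)
    if size <= np.finfo(float).eps:
        raise MeshValidationError("zero centroid size: all points identical")
    prior = cloud.centroid_size if cloud.centroid_size is not None else 1.0
    return replace(
        cloud,
        points=(cloud.points - c) / size,
        centroid_size=prior * size if cloud.centroid_size is not None else size,
    )


def sample_surface(
    mesh: SurfaceMesh,
    n: int,
    seed: int,
    return_location: bool = False,
):
    """Sample ``n`` points area-uniformly on the surface.

    Allocation is stratified per face: each face receives floor(n * area
    fraction) points, the remainder going to the faces with the largest
    fractional parts (deterministic); barycentric coordinates within each face
    are drawn from the seeded generator. Normals are barycentric interpolations
    of the vertex normals, re-normalised.

    With ``return_location`` the face index and barycentric coordinates of each
    sample are also returned, so any per-vertex field can later be interpolated
    at the sampled locations.
    """
    if n < 4:
        raise ValueError("need n >= 4 sample points")
    rng = np.random.default_rng(seed)
    v, f = mesh.vertices, mesh.faces
    tri = v[f]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    frac = areas / areas.sum()
    counts = np.floor(n * frac).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(n * frac - counts), kind="stable")
        counts[order[:short]] += 1

    face_idx = np.repeat(np.arange(len(f)), counts)
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    bary = np.column_stack([1.0 - r1, r1 * (1.0 - r2), r1 * r2])

    corners = v[f[face_idx]]
    points = np.einsum("ij,ijk->ik", bary, corners)
    ncorners = mesh.normals[f[face_idx]]
    normals = np.einsum("ij,ijk->ik", bary, ncorners)
    lens = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.where(lens > 0, lens, 1.0)

    cloud = PointCloud(points=points, normals=normals, instance_id=mesh.instance_id)
    if return_location:
        return cloud, face_idx, bary
    return cloud
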