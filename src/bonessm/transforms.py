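"""Similarity transforms (rotation + translation + isotropic scale) on 3D point sets.

These are the pose parameters removed by groupwise registration. Reflections are
deliberately excluded: side-matching of left/right bones goes through explicit
sagittal mirroring of the surface, never through an improper rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimilarityTransform", "weighted_similarity", "random_rotation"]

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class SimilarityTransform:
    """A map ``p -> scale * R @ p + t`` with proper rotation ``R``.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Proper orthogonal matrix (det +1 within 1e-6).
    translation : (3,) ndarray
    scale : float
        Strictly positive isotropic scale factor.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if t.shape != (3,):
            raise ValueError(f"translation must have shape (3,), got {t.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation matrix is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError(
                "reflection (det -1) is not a valid similarity transform; "
                "use sagittal mirroring instead"
            )
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "scale", float(self.scale))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return self.scale * points @ self.rotation.T + self.translation

    def apply_normals(self, normals: np.ndarray) -> np.ndarray:
        """Rotate unit vectors (scale and translation do not act on directions)."""
        out = np.asarray(normals, dtype=float) @ self.rotation.T
        norms = np.linalg.norm(out, axis=-1, keepdims=True)
        return out / np.where(norms > 0, norms, 1.0)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform ``self o other`` (apply ``other`` first)."""
        return SimilarityTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation + self.translation,
            scale=self.scale * other.scale,
        )

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        return SimilarityTransform(
            rotation=Rinv,
            translation=-Rinv @ self.translation / self.scale,
            scale=1.0 / self.scale,
        )

    def to_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (scale folded into the linear block)."""
        M = np.eye(4)
        M[:3, :3] = self.scale * self.rotation
        M[:3, 3] = self.translation
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "SimilarityTransform":
        M = np.asarray(M, dtype=float)
        A = M[:3, :3]
        scale = float(np.cbrt(np.linalg.det(A)))
        if scale <= 0:
            raise ValueError("matrix does not encode a positive-scale similarity")
        return cls(rotation=A / scale, translation=M[:3, 3].copy(), scale=scale)

    def to_dict(self) -> dict:
        return {
            "matrix": self.to_matrix().tolist(),
            "scale": self.scale,
        }


def weighted_similarity(
    src: np.ndarray, dst: np.ndarray, weights: np.ndarray | None = None
) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``src`` onto ``dst``.

    Minimises ``sum_i w_i || s R src_i + t - dst_i ||^2`` in closed form
    (Umeyama's method with per-point weights). Degenerate inputs (all weight on
    one point, or zero spread) fall back to a pure translation.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if weights is None:
        weights = np.ones(len(src))
    w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights must have positive sum")
    wn = w / wsum

    mu_src = wn @ src
    mu_dst = wn @ dst
    xs = src - mu_src
    xd = dst - mu_dst
    cov = (xd * wn[:, None]).T @ xs  # dst-src cross-covariance
    var_src = float(np.sum(wn * np.einsum("ij,ij->i", xs, xs)))

    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    if var_src <= np.finfo(float).eps:
        return SimilarityTransform(translation=mu_dst - mu_src)
    scale = float(np.trace(np.diag(D) @ S) / var_src)
    if scale <= 0:  # pathological anti-correlated input; keep a valid transform
        scale = np.finfo(float).tiny
    t = mu_dst - scale * R @ mu_src
    return SimilarityTransform(rotation=R, translation=t, scale=scale)


def random_rotation(
    rng: np.random.Generator, max_angle_deg: float = 180.0
) -> np.ndarray:
    """Rotation about a uniformly random axis by a uniform angle in [0, max]."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)
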