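"""PCA point-distribution shape model over corresponded coordinates.

With corresponded shape vectors x_i (length 3N), the model is

    x  =  xbar + sum_{s=1..c} b_s * Phi_s

where xbar is the mean shape, Phi_s the orthonormal modes of shape variation
(eigenvectors of the sample covariance, divisor n-1) and b_s the shape
parameters. Eigendecomposition goes through the SVD of the centred data
matrix, which is exact and avoids ever forming the 3N x 3N covariance.

Shape parameters are exposed both raw and in SD units (b_s / sqrt(lambda_s)):
a subject "+2.3" in SD units sits 2.3 standard deviations from the mean shape
along that mode. Mode signs are pinned by requiring the largest-magnitude
entry of each mode to be positive, so b values are reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .correspondence import CorrespondenceMatrix

__all__ = [
    "ShapeModel",
    "ShapeParameters",
    "ShapeModelPCA",
    "build_ssm",
    "variance_explained",
    "select_modes",
    "project",
    "reconstruct",
]

_RANK_RTOL = 1e-10


@dataclass
class ShapeModel:
    """Mean shape, orthonormal modes, eigenvalues, and retained-mode count."""

    mean_shape: np.ndarray      # (3N,)
    modes: np.ndarray           # (3N, m), orthonormal columns
    eigenvalues: np.ndarray     # (m,), nonincreasing, >= 0
    retained: int
    point_count: int

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        self.eigenvalues = np.clip(np.asarray(self.eigenvalues, dtype=float), 0.0, None)
        m = self.modes.shape[1]
        if len(self.eigenvalues) != m:
            raise ValueError("one eigenvalue per mode required")
        if m and np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be nonincreasing")
        if m and not np.allclose(self.modes.T @ self.modes, np.eye(m), atol=1e-8):
            raise ValueError("modes must be orthonormal")
        if m and not (1 <= self.retained <= m):
            raise ValueError(f"retained must be in [1, {m}]")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]


@dataclass
class ShapeParameters:
    """Per-instance shape parameters, raw and in SD units."""

    b: np.ndarray               # (instances, retained)
    normalized_b: np.ndarray    # b / sqrt(eigenvalue), per mode
    instance_ids: list


class ShapeModelPCA:
    """Point-distribution model as an sklearn-style transformer.

    ``fit`` builds the model from an (instances x 3N) matrix;
    ``transform`` projects shapes onto the retained modes (returns b values);
    ``inverse_transform`` reconstructs shapes from b values.

    Parameters
    ----------
    var_threshold : float in (0, 1)
        Retain the modes whose variance fraction is strictly greater than
        this (at least one mode is always retained).

    Attributes (after ``fit``)
    --------------------------
    mean_ : (3N,)                 mean shape
    components_ : (m, 3N)         modes as rows (sklearn layout)
    eigenvalues_ : (m,)           variances along the modes
    explained_variance_ratio_ : (m,)
    n_retained_ : int
    point_count_ : int
    """

    def __init__(self, var_threshold: float = 0.05) -> None:
        self.var_threshold = var_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"var_threshold": self.var_threshold}

    def set_params(self, **params) -> "ShapeModelPCA":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "ShapeModelPCA":
        X, ids, n_pts = _as_matrix(X)
        n, p = X.shape
        if n < 3:
            raise ValueError("need >= 3 instances to build a shape model")
        if not np.all(np.isfinite(X)):
            raise ValueError("shape matrix contains non-finite entries")
        mean = X.mean(axis=0)
        centred = X - mean
        U, s, Vt = np.linalg.svd(centred, full_matrices=False)
        eig = s**2 / (n - 1)
        keep = s > s[0] * _RANK_RTOL if s.size and s[0] > 0 else np.zeros(s.size, bool)
        eig, Vt = eig[keep], Vt[keep]
        if len(eig) == 0:
            warnings.warn(
                "all instances identical: shape model has zero modes",
                RuntimeWarning, stacklevel=2,
            )
        # pin eigenvector signs: largest-magnitude entry positive
        for r in range(Vt.shape[0]):
            j = np.argmax(np.abs(Vt[r]))
            if Vt[r, j] < 0:
                Vt[r] = -Vt[r]
        self.mean_ = mean
        self.components_ = Vt
        self.eigenvalues_ = eig
        total = eig.sum()
        self.explained_variance_ratio_ = eig / total if total > 0 else eig
        self.n_retained_ = (
            _select(self.explained_variance_ratio_, self.var_threshold)
            if len(eig) else 0
        )
        self.point_count_ = n_pts if n_pts else p // 3
        self.instance_ids_ = ids
        self.training_b_ = centred @ Vt.T if len(eig) else np.zeros((n, 0))
        return self

    def transform(self, X) -> np.ndarray:
        X, _, _ = _as_matrix(X)
        if X.shape[1] != len(self.mean_):
            raise ValueError(
                f"shape length {X.shape[1]} does not match model ({len(self.mean_)})"
            )
        return (X - self.mean_) @ self.components_[: self.n_retained_].T

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, b: np.ndarray, n_modes: int | None = None) -> np.ndarray:
        b = np.atleast_2d(np.asarray(b, dtype=float))
        c = b.shape[1] if n_modes is None else n_modes
        if c > self.components_.shape[0]:
            raise ValueError(f"cannot use {c} modes; model has {self.components_.shape[0]}")
        if b.shape[1] < c:
            raise ValueError("b has fewer entries than requested modes")
        return self.mean_ + b[:, :c] @ self.components_[:c]

    def to_model(self) -> ShapeModel:
        return ShapeModel(
            mean_shape=self.mean_,
            modes=self.components_.T,
            eigenvalues=self.eigenvalues_,
            retained=max(self.n_retained_, 1) if len(self.eigenvalues_) else 0,
            point_count=self.point_count_,
        )

    def shape_parameters(self, X=None) -> ShapeParameters:
        """b values (raw and SD units) for X, default the training set."""
        if X is None:
            b = self.training_b_[:, : self.n_retained_]
            ids = self.instance_ids_
        else:
            b = self.transform(X)
            ids = _as_matrix(X)[1]
        lam = self.eigenvalues_[: self.n_retained_]
        sd = np.sqrt(np.where(lam > 0, lam, np.inf))
        return ShapeParameters(b=b, normalized_b=b / sd, instance_ids=ids)


def _as_matrix(X):
    if isinstance(X, CorrespondenceMatrix):
        return X.data, list(X.instance_ids), X.point_count
    arr = np.atleast_2d(np.asarray(X, dtype=float))
    return arr, [f"instance_{i}" for i in range(len(arr))], 0


def _select(fractions: np.ndarray, threshold: float) -> int:
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    c = int(np.sum(fractions > threshold))  # strictly greater
    return max(c, 1)


# -- functional surface ----------------------------------------------------

def build_ssm(matrix, var_threshold: float = 0.05) -> ShapeModel:
    """Build a :class:`ShapeModel` from a correspondence matrix."""
    est = ShapeModelPCA(var_threshold=var_threshold).fit(matrix)
    return est.to_model()


def variance_explained(model: ShapeModel) -> np.ndarray:
    """Per-mode variance fractions (sum to 1, nonincreasing)."""
    if model.n_modes < 1:
        raise ValueError("model has no modes")
    return model.eigenvalues / model.eigenvalues.sum()


def select_modes(model: ShapeModel, threshold: float = 0.05) -> int:
    """Number of modes whose variance fraction is strictly above threshold
    (never fewer than one)."""
    return _select(variance_explained(model), threshold)


def project(shape: np.ndarray, model: ShapeModel, n_modes: int | None = None) -> np.ndarray:
    """Shape parameters b_s = Phi_s^T (x - xbar), s = 1..retained."""
    shape = np.asarray(shape, dtype=float)
    if shape.shape[-1] != len(model.mean_shape):
        raise ValueError(
            f"shape length {shape.shape[-1]} does not match model "
            f"({len(model.mean_shape)})"
        )
    c = model.retained if n_modes is None else n_modes
    return (shape - model.mean_shape) @ model.modes[:, :c]


def reconstruct(model: ShapeModel, b: np.ndarray, c: int | None = None) -> np.ndarray:
    """x = xbar + sum_{s<=c} b_s Phi_s."""
    b = np.asarray(b, dtype=float)
    if c is None:
        c = min(b.shape[-1], model.n_modes)
    if c > model.n_modes:
        raise ValueError(f"c={c} exceeds the model's {model.n_modes} modes")
    if b.shape[-1] < c:
        raise ValueError("b has fewer entries than c")
    return model.mean_shape + b[..., :c] @ model.modes[:, :c].T
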