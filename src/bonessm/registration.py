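"""Unbiased groupwise similarity registration against an evolving mean cloud.

Every bone instance (a centred, unit-centroid-size point cloud) is aligned to a
mean point cloud that is itself re-estimated from the aligned instances, so no
single specimen acts as the reference atlas. The probabilistic model is a
Gaussian mixture: the ``n_mean`` mean points are mixture centroids with a
shared isotropic kernel of width ``sigma``, plus a small uniform outlier
component. Each instance's similarity transform is estimated by
expectation-maximisation (soft responsibilities in the E-step, a closed-form
weighted Umeyama similarity fit in the M-step, as in coherent point drift);
each mean point is then re-estimated as the responsibility-weighted barycentre
of the aligned instance points, with the trade-off parameter ``lam`` pulling
the update toward the previous mean configuration (larger lam = stiffer mean).
After every update the mean is re-centred and re-scaled to unit centroid size,
which removes global drift and keeps the procedure unbiased.

``sigma`` is stated in millimetres (the unit of the raw scans); it is divided
by the median of the instances' recorded centroid sizes so that it keeps its
physical meaning on normalised clouds. Within each outer
iteration, every instance is aligned under a deterministic-annealing kernel
schedule that decays geometrically from a wide start (a fraction of the cloud
radius, or sigma if larger) down to a small floor: the wide early kernel gives
a broad basin of attraction, the narrow late kernel removes the
soft-assignment bias so exact poses are recovered exactly. The mean is always
re-estimated under the sharpest kernel, which keeps its surface detail crisp
while it evolves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .mesh import MeshValidationError, PointCloud, centroid_size
from .transforms import SimilarityTransform, weighted_similarity

__all__ = [
    "RegistrationParams",
    "AlignedCohort",
    "GroupwiseRegistration",
    "groupwise_register",
    "apply_transform",
]

_NORM_TOL = 1e-6


@dataclass(frozen=True)
class RegistrationParams:
    """User-facing registration parameters.

    sigma : Gaussian kernel width in mm (pre-normalisation units).
    n_mean : number of points in the evolving mean cloud.
    lam : stiffness of the mean update; the mean moves by a factor 1/(1+lam)
        toward the responsibility-weighted barycentres, so lam=1e-6 is a free
        mean and lam=5e-4 a very slightly stiffer one.
    max_iters / tol : outer-loop budget and relative Frobenius convergence
        tolerance on the mean cloud.
    """

    sigma: float = 3.0
    n_mean: int = 2000
    lam: float = 1e-6
    max_iters: int = 200
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.n_mean < 4:
            raise ValueError("n_mean must be >= 4")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")


@dataclass
class AlignedCohort:
    """Registered cohort: aligned clouds, converged mean, per-instance poses."""

    clouds: list
    mean_cloud: PointCloud
    transforms: list
    iterations_run: int
    converged: bool
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.clouds) != len(self.transforms):
            raise ValueError("one transform per cloud required")


def apply_transform(cloud: PointCloud, transform: SimilarityTransform) -> PointCloud:
    """Apply a similarity transform to a cloud (normals rotate only)."""
    return PointCloud(
        points=transform.apply(cloud.points),
        normals=None if cloud.normals is None else transform.apply_normals(cloud.normals),
        centroid_size=None
        if cloud.centroid_size is None
        else cloud.centroid_size * transform.scale,
        instance_id=cloud.instance_id,
    )


class GroupwiseRegistration:
    """Groupwise GMM similarity registration, sklearn-estimator style.

    Parameters
    ----------
    sigma, n_mean, lam, max_iters, tol
        See :class:`RegistrationParams`.
    n_em : int
        EM iterations per instance per outer iteration; with annealing the
        kernel decays geometrically over these iterations.
    anneal : bool
        Anneal the kernel from the wide start to the floor within every
        instance alignment (recommended); if False a constant kernel of
        width sigma is used.
    sigma_floor_frac : float
        The kernel never decays below ``sigma_floor_frac * sigma`` (normalised).
    outlier_weight : float
        Weight of the uniform outlier component.
    init : {"first", "kmeans"}
        Mean initialisation: seeded subsample of the first instance, or k-means
        centroids of the pooled first instance.

    Attributes (after ``fit``)
    --------------------------
    mean_cloud_ : PointCloud            converged mean (unit centroid size)
    transforms_ : list[SimilarityTransform]
    aligned_ : list[PointCloud]
    n_iter_ : int
    converged_ : bool
    objective_traces_ : list[list[np.ndarray]]
        Per outer iteration, per instance, the GMM log-likelihood at each
        E-step (non-decreasing within one inner EM loop).
    log_ : dict                         run log (params, per-iter mean change)
    """

    def __init__(
        self,
        sigma: float = 3.0,
        n_mean: int = 2000,
        lam: float = 1e-6,
        max_iters: int = 200,
        tol: float = 1e-6,
        n_em: int = 12,
        anneal: bool = True,
        sigma_start_factor: float = 1.0,
        sigma_floor_frac: float = 0.25,
        outlier_weight: float = 0.01,
        scale_bounds: tuple = (0.85, 1.2),
        init: str = "first",
        random_state: int | None = 0,
    ) -> None:
        self.sigma = sigma
        self.n_mean = n_mean
        self.lam = lam
        self.max_iters = max_iters
        self.tol = tol
        self.n_em = n_em
        self.anneal = anneal
        self.sigma_start_factor = sigma_start_factor
        self.sigma_floor_frac = sigma_floor_frac
        self.outlier_weight = outlier_weight
        self.scale_bounds = scale_bounds
        self.init = init
        self.random_state = random_state

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "sigma", "n_mean", "lam", "max_iters", "tol", "n_em", "anneal", "sigma_start_factor",
                "sigma_floor_frac", "outlier_weight", "scale_bounds", "init", "random_state",
            )
        }

    def set_params(self, **params) -> "GroupwiseRegistration":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- core -------------------------------------------------------------
    @staticmethod
    def _validate_cloud(cloud: PointCloud) -> None:
        c = cloud.points.mean(axis=0)
        if np.linalg.norm(c) > _NORM_TOL:
            raise MeshValidationError(
                f"cloud {cloud.instance_id!r} is not centred (|centroid|={np.linalg.norm(c):.2e}); "
                "run center_and_scale first"
            )
        size = centroid_size(cloud.points)
        if abs(size - 1.0) > _NORM_TOL:
            raise MeshValidationError(
                f"cloud {cloud.instance_id!r} does not have unit centroid size "
                f"({size:.6f}); run center_and_scale first"
            )

    def _init_mean(self, cloud: PointCloud, rng: np.random.Generator) -> tuple:
        n = min(self.n_mean, len(cloud))
        if self.init == "kmeans":
            from sklearn.cluster import KMeans

            km = KMeans(
                n_clusters=n, n_init=1,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(cloud.points)
            pts = km.cluster_centers_
            if cloud.normals is not None:
                idx = cdist(pts, cloud.points).argmin(axis=1)
                nrm = cloud.normals[idx].copy()
            else:
                nrm = None
        elif self.init == "first":
            idx = rng.choice(len(cloud), size=n, replace=False)
            pts = cloud.points[idx].copy()
            nrm = None if cloud.normals is None else cloud.normals[idx].copy()
        else:
            raise ValueError(f"unknown init {self.init!r}")
        return pts, nrm

    def _estep(self, transform, x, mean_pts, sigma):
        n_mean = len(mean_pts)
        w = self.outlier_weight
        var2 = 2.0 * sigma * sigma
        extent = np.ptp(mean_pts, axis=0) + 6.0 * sigma
        volume = float(np.prod(extent))
        c_out = (w / max(1.0 - w, 1e-12)) * n_mean * (np.pi * var2) ** 1.5 / volume
        y = transform.apply(x)
        K = np.exp(-cdist(y, mean_pts, "sqeuclidean") / var2)
        denom = K.sum(axis=1) + c_out
        ll = float(np.sum(np.log(
            denom * (1.0 - w) / (n_mean * (np.pi * var2) ** 1.5)
            + np.finfo(float).tiny)))
        return K / denom[:, None], y, ll

    def _em_schedule(self, transform, x, mean_pts, schedule):
        """EM over a kernel schedule; returns the transform and ll trace."""
        ll_trace = []
        for sigma in schedule:
            R, y, ll = self._estep(transform, x, mean_pts, sigma)
            ll_trace.append(ll)
            wts = R.sum(axis=1)
            keep = wts > 1e-12
            if keep.sum() < 4:
                continue  # this kernel explains everything as outliers
            targets = (R[keep] @ mean_pts) / wts[keep, None]
            transform = weighted_similarity(x[keep], targets, wts[keep])
            # both the instance and the mean have unit centroid size, so the
            # true scale is near 1; clamping blocks the GMM scale-collapse
            # failure mode where a misaligned cloud shrinks onto the mean
            if not self.scale_bounds[0] <= transform.scale <= self.scale_bounds[1]:
                sc = float(np.clip(transform.scale, *self.scale_bounds))
                mu_src = (wts[keep, None] * x[keep]).sum(0) / wts[keep].sum()
                mu_dst = (wts[keep, None] * targets).sum(0) / wts[keep].sum()
                transform = SimilarityTransform(
                    rotation=transform.rotation,
                    translation=mu_dst - sc * transform.rotation @ mu_src,
                    scale=sc,
                )
        return transform, ll_trace

    def _em_instance(self, cloud, transform, mean_pts, schedule, sharp):
        """Align one instance to the fixed mean.

        Two candidate alignments are computed: the deterministic-annealing
        schedule restarted from the incoming pose (wide basin, can correct a
        badly posed instance) and a sharp-kernel refinement of the incoming
        pose (never disturbs an already good alignment). The candidate with
        the higher likelihood under the sharpest kernel wins; this keeps the
        wide kernel's exploration from scrambling instances that are already
        registered. Returns the transform, the responsibilities at the
        sharpest kernel (for the mean update), the aligned points, and the
        log-likelihood trace of the winning candidate.
        """
        x = cloud.points
        t_a, trace_a = self._em_schedule(transform, x, mean_pts, schedule)
        R_a, y_a, ll_a = self._estep(t_a, x, mean_pts, schedule[-1])
        if len(sharp):
            t_b, trace_b = self._em_schedule(transform, x, mean_pts, sharp)
            R_b, y_b, ll_b = self._estep(t_b, x, mean_pts, schedule[-1])
            if ll_b > ll_a:
                return t_b, R_b, y_b, trace_b
        return t_a, R_a, y_a, trace_a

    def fit(self, clouds: list) -> "GroupwiseRegistration":
        if len(clouds) < 2:
            raise MeshValidationError("groupwise registration needs >= 2 clouds")
        RegistrationParams(
            sigma=self.sigma, n_mean=self.n_mean, lam=self.lam,
            max_iters=self.max_iters, tol=self.tol,
        )
        for cl in clouds:
            self._validate_cloud(cl)

        rng = np.random.default_rng(self.random_state)
        sizes = [cl.centroid_size for cl in clouds if cl.centroid_size is not None]
        scale_mm = float(np.median(sizes)) if sizes else 1.0
        sigma_norm = self.sigma / scale_mm

        target_rms = float(np.mean([
            np.sqrt(np.mean(np.sum(cl.points**2, axis=1))) for cl in clouds]))
        mean_pts, _ = self._init_mean(clouds[0], rng)
        mean_pts = _renormalise(mean_pts, target_rms)
        rms_radius = float(np.sqrt(np.mean(np.sum(mean_pts**2, axis=1))))
        sigma_start = max(sigma_norm * self.sigma_start_factor,
                          0.3 * rms_radius)
        sigma_floor = max(self.sigma_floor_frac * sigma_norm, 1e-9)

        transforms = [SimilarityTransform.identity() for _ in clouds]
        if self.anneal:
            schedule = np.geomspace(sigma_start, sigma_floor, self.n_em)
            sharp = np.geomspace(max(sigma_norm, 2.0 * sigma_floor), sigma_floor,
                                 max(self.n_em // 2, 3))
        else:
            schedule = np.full(self.n_em, sigma_norm)
            sharp = np.array([])
        self.objective_traces_ = []
        mean_changes = []
        converged = False
        it = 0
        for it in range(1, self.max_iters + 1):
            num = np.zeros_like(mean_pts)
            den = np.zeros(len(mean_pts))
            nrm_num = np.zeros_like(mean_pts)
            traces = []
            # the wide exploratory schedule (with its sharp-refinement
            # guard) is only needed for the initial alignment; later outer
            # iterations refine already-posed instances under the sharp
            # schedule alone
            if it == 1 or not self.anneal:
                sched_t, guard = schedule, sharp
            else:
                sched_t, guard = sharp, np.array([])
            for i, cl in enumerate(clouds):
                transforms[i], R, y, ll = self._em_instance(
                    cl, transforms[i], mean_pts, sched_t, guard
                )
                traces.append(ll)
                num += R.T @ y
                den += R.sum(axis=0)
                if cl.normals is not None:
                    nrm_num += R.T @ transforms[i].apply_normals(cl.normals)
            self.objective_traces_.append(traces)

            new_mean = mean_pts.copy()
            ok = den > 1e-12
            new_mean[ok] = (num[ok] + self.lam * den[ok, None] * mean_pts[ok]) / (
                den[ok, None] * (1.0 + self.lam)
            )
            new_mean = _renormalise(new_mean, target_rms)
            change = float(
                np.linalg.norm(new_mean - mean_pts) / max(np.linalg.norm(mean_pts), 1e-12)
            )
            mean_changes.append(change)
            mean_pts = new_mean
            if change < self.tol:
                converged = True
                break

        if not converged:
            warnings.warn(
                f"groupwise registration did not converge in {it} iterations "
                f"(last relative mean change {mean_changes[-1]:.2e})",
                RuntimeWarning,
                stacklevel=2,
            )

        mean_normals = None
        if all(cl.normals is not None for cl in clouds):
            lens = np.linalg.norm(nrm_num, axis=1, keepdims=True)
            mean_normals = nrm_num / np.where(lens > 0, lens, 1.0)

        self.mean_cloud_ = PointCloud(
            points=mean_pts, normals=mean_normals, centroid_size=scale_mm,
            instance_id="mean",
        )
        self.transforms_ = transforms
        self.aligned_ = [apply_transform(cl, t) for cl, t in zip(clouds, transforms)]
        self.n_iter_ = it
        self.converged_ = converged
        self.log_ = {
            "params": self.get_params(),
            "sigma_normalised": sigma_norm,
            "sigma_schedule": [sigma_start, sigma_floor],
            "scale_mm": scale_mm,
            "mean_changes": mean_changes,
            "iterations_run": it,
            "converged": converged,
        }
        return self

    def to_cohort(self) -> AlignedCohort:
        return AlignedCohort(
            clouds=self.aligned_,
            mean_cloud=self.mean_cloud_,
            transforms=self.transforms_,
            iterations_run=self.n_iter_,
            converged=self.converged_,
            log=self.log_,
        )


def _renormalise(points: np.ndarray, target_rms: float | None = None) -> np.ndarray:
    """Centre the mean cloud and fix its scale (the unbiasedness device).

    Kendall centroid size depends on the point count, so "unit centroid
    size" only matches the instances' geometric scale when the mean has as
    many points as they do. The mean is therefore rescaled to the instances'
    RMS radius (for unit-size clouds of n points, 1/sqrt(n)); when no target
    is given, unit centroid size of the mean itself is used.
    """
    p = points - points.mean(axis=0)
    if target_rms is None:
        return p / centroid_size(p + 0.0)
    rms = float(np.sqrt(np.mean(np.sum(p**2, axis=1))))
    return p * (target_rms / rms)


def groupwise_register(
    clouds: list,
    params: RegistrationParams | None = None,
    seed: int = 0,
    **kwargs,
) -> AlignedCohort:
    """Functional wrapper over :class:`GroupwiseRegistration`."""
    params = params or RegistrationParams()
    est = GroupwiseRegistration(
        sigma=params.sigma, n_mean=params.n_mean, lam=params.lam,
        max_iters=params.max_iters, tol=params.tol, random_state=seed, **kwargs,
    )
    est.fit(clouds)
    return est.to_cohort()
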