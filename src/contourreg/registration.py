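"""Rigid transform estimation from pruned correspondences.

RANSAC draws minimal 3-point samples from the pruned correspondence set and
solves the orthogonal Procrustes problem in closed form (cross-covariance
SVD with reflection correction).  Hypotheses are ranked by consensus: the
number of correspondences within d_RANSAC of their prediction, ties broken
by the RMSE over that inlier set.  A hypothesis is *accepted* — terminating
the search — when its consensus covers at least half of the set, its inlier
RMSE is below d_RANSAC and the inlier pairs pass the normal-compatibility
test; otherwise the best-consensus transform is returned with the fallback
flag set.  Either way the final ("best minimal") solution is re-estimated by
least squares over its consensus pairs, which averages away the feature-
snapping noise of individual correspondences.  A plain point-to-point ICP
refiner is provided for the downstream fine-alignment step.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .geometry import InputError, SurfaceMesh
from .matching import CorrespondenceSet


class DegenerateSampleError(ValueError):
    """Raised when a minimal sample is collinear or too small."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Rotation (3x3, det +1) plus translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if np.abs(self.rotation @ self.rotation.T - np.eye(3)).max() > 1e-6:
            raise InputError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise InputError("rotation has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def apply_normals(self, normals: np.ndarray) -> np.ndarray:
        return np.asarray(normals) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def to_json(self, path, **extra) -> None:
        payload = {
            "rotation": self.rotation.reshape(-1).tolist(),
            "translation": self.translation.tolist(),
            **extra,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["rotation"]).reshape(3, 3),
                   np.asarray(payload["translation"]))


@dataclass
class RansacParams:
    """RANSAC settings.

    max_iterations : hypothesis budget (default 1000).
    d_ransac : float, mm — RMSE acceptance threshold; 5 mm suits the rigid
        benchmark, 10 mm deformed or noisy data.
    a_normals : float, degrees — maximum allowed angle between a rotated
        moving normal and its target normal (default 60° to absorb some
        deformation).
    min_sample : minimal sample size (3 points determine a rigid transform).
    seed : RNG seed for the sample draws.
    """

    max_iterations: int = 1000
    d_ransac: float = 5.0
    a_normals: float = 60.0
    min_sample: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise InputError("max_iterations must be >= 1")
        if self.d_ransac <= 0:
            raise InputError("d_ransac must be positive")
        if not 0 < self.a_normals < 180:
            raise InputError("a_normals must be in (0, 180) degrees")
        if self.min_sample < 3:
            raise InputError("min_sample must be >= 3")


@dataclass
class RegistrationResult:
    """Outcome of :func:`ransac_rigid`."""

    transform: RigidTransform
    rmse: float
    inliers: CorrespondenceSet | None
    accepted: bool
    fallback: bool
    seed: int = 0

    def to_json(self, path) -> None:
        self.transform.to_json(
            path,
            rmse_mm=self.rmse,
            accepted=self.accepted,
            fallback=self.fallback,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# Closed-form rigid fit
# ---------------------------------------------------------------------------

_COLLINEAR_RTOL = 1e-6


def estimate_rigid(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src onto dst (Kabsch/Umeyama).

    Minimises sum ||R s_i + t - d_i||^2 via SVD of the cross-covariance, with
    the determinant correction that excludes reflections.  Requires at least
    three non-collinear pairs.
    """
    src = np.atleast_2d(np.asarray(src, dtype=np.float64))
    dst = np.atleast_2d(np.asarray(dst, dtype=np.float64))
    if src.shape != dst.shape or src.shape[0] < 3 or src.shape[1] != 3:
        raise DegenerateSampleError("need >= 3 point pairs of matching shape")
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    A = (dst - dc).T @ (src - sc)
    sv = np.linalg.svd(src - sc, compute_uv=False)
    if sv[1] < _COLLINEAR_RTOL * sv[0]:
        raise DegenerateSampleError("source points are (nearly) collinear")
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    t = dc - R @ sc
    return RigidTransform(R, t)


def normal_test(
    normals_m: np.ndarray,
    normals_t: np.ndarray,
    transform: RigidTransform,
    a_normals: float = 60.0,
) -> bool:
    """True iff every rotated moving normal is within a_normals of its target.

    Zero (flagged) normals are skipped with a warning rather than failing the
    test — they carry no orientation information.
    """
    nm = np.atleast_2d(np.asarray(normals_m, dtype=np.float64))
    nt = np.atleast_2d(np.asarray(normals_t, dtype=np.float64))
    lm = np.linalg.norm(nm, axis=1)
    lt = np.linalg.norm(nt, axis=1)
    ok = (lm > 1e-9) & (lt > 1e-9)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-normal pairs skipped in "
                      "normal test", stacklevel=2)
    if not ok.any():
        return True
    rn = transform.apply_normals(nm[ok] / lm[ok, None])
    cosang = np.einsum("ij,ij->i", rn, nt[ok] / lt[ok, None])
    return bool((cosang >= np.cos(np.deg2rad(a_normals)) - 1e-12).all())


# ---------------------------------------------------------------------------
# RANSAC
# ---------------------------------------------------------------------------

def ransac_rigid(
    C_p: CorrespondenceSet,
    moving_positions: np.ndarray,
    target_positions: np.ndarray,
    moving_normals: np.ndarray | None = None,
    target_normals: np.ndarray | None = None,
    params: RansacParams | None = None,
) -> RegistrationResult:
    """Robust rigid estimation over the pruned correspondence set.

    Parameters
    ----------
    moving_positions, target_positions : (n_features, 3) arrays
        Feature coordinates indexed by the correspondence m/t indices.
    moving_normals, target_normals : optional matching normal arrays
        When absent the normal test is skipped (treated as passing).

    Notes
    -----
    Hypotheses are scored by consensus size at ``d_ransac`` (ties by inlier
    RMSE); acceptance additionally requires a majority consensus and the
    normal test on the inlier pairs.  With no accepted hypothesis the best-
    consensus transform is returned, flagged ``fallback`` — downstream
    refinement often still converges from it.  The returned transform is
    always re-fit by least squares over its consensus pairs.
    """
    params = params or RansacParams()
    n = len(C_p)
    if n < params.min_sample:
        raise InputError(
            f"only {n} pruned correspondences; need >= {params.min_sample}. "
            "Relax matching parameters (more features, larger k, larger "
            "sigma_d/sigma_b) to retain more candidates."
        )
    mi = C_p.m_indices
    ti = C_p.t_indices
    src_all = np.asarray(moving_positions, dtype=np.float64)[mi]
    dst_all = np.asarray(target_positions, dtype=np.float64)[ti]
    nm = None if moving_normals is None else np.asarray(moving_normals)[mi]
    nt = None if target_normals is None else np.asarray(target_normals)[ti]

    rng = np.random.default_rng(params.seed)
    majority = max(params.min_sample, int(np.ceil(0.5 * n)))
    best_count = -1
    best_rmse = np.inf
    best_tf: RigidTransform | None = None
    accepted = False
    for _ in range(params.max_iterations):
        pick = rng.choice(n, size=params.min_sample, replace=False)
        try:
            tf = estimate_rigid(src_all[pick], dst_all[pick])
        except DegenerateSampleError:
            continue
        resid = np.linalg.norm(tf.apply(src_all) - dst_all, axis=1)
        inl = resid < params.d_ransac
        count = int(inl.sum())
        rmse = float(np.sqrt((resid[inl] ** 2).mean())) if count else np.inf
        if count > best_count or (count == best_count and rmse < best_rmse):
            best_count = count
            best_rmse = rmse
            best_tf = tf
        if count >= majority and rmse < params.d_ransac:
            if nm is None or nt is None or normal_test(nm[inl], nt[inl], tf,
                                                       params.a_normals):
                accepted = True
                break
    if best_tf is None:
        raise InputError("all RANSAC samples degenerate; correspondences "
                         "may be collinear")
    # final least-squares re-fit over the consensus ("final") pairs
    tf = best_tf
    inlier_mask = np.zeros(n, dtype=bool)
    for _ in range(2):
        resid = np.linalg.norm(tf.apply(src_all) - dst_all, axis=1)
        inlier_mask = resid < params.d_ransac
        if inlier_mask.sum() < params.min_sample:
            inlier_mask = resid <= np.partition(resid, params.min_sample - 1)[
                params.min_sample - 1]
        try:
            tf = estimate_rigid(src_all[inlier_mask], dst_all[inlier_mask])
        except DegenerateSampleError:
            break
    resid = np.linalg.norm(tf.apply(src_all) - dst_all, axis=1)
    final_mask = resid < params.d_ransac
    if final_mask.sum() >= params.min_sample:
        inlier_mask = final_mask
    rmse = float(np.sqrt((resid[inlier_mask] ** 2).mean())) \
        if inlier_mask.any() else best_rmse
    inliers = CorrespondenceSet(
        [C_p.pairs[i] for i in np.flatnonzero(inlier_mask)], stage="inliers"
    )
    return RegistrationResult(
        transform=tf,
        rmse=rmse,
        inliers=inliers,
        accepted=accepted,
        fallback=not accepted,
        seed=params.seed,
    )


def dense_rmse(
    moving: SurfaceMesh | np.ndarray,
    target: SurfaceMesh | np.ndarray,
    transform: RigidTransform,
) -> float:
    """Closest-point RMSE of the transformed moving vertices to the target.

    The dense alternative to the correspondence-set RMSE that RANSAC scores;
    available behind this separate entry point for diagnostics.
    """
    mv = moving.vertices if isinstance(moving, SurfaceMesh) else np.asarray(moving)
    tv = target.vertices if isinstance(target, SurfaceMesh) else np.asarray(target)
    d, _ = cKDTree(tv).query(transform.apply(mv))
    return float(np.sqrt((d**2).mean()))


# ---------------------------------------------------------------------------
# ICP refinement
# ---------------------------------------------------------------------------

def refine_icp(
    moving: SurfaceMesh | np.ndarray,
    target: SurfaceMesh | np.ndarray,
    init: RigidTransform,
    max_iter: int = 50,
    tol: float = 1e-4,
    trim_fraction: float = 0.0,
) -> RigidTransform:
    """Point-to-point ICP from an initial transform.

    Alternates nearest-neighbour pairing with the closed-form rigid fit until
    the closest-point RMSE improves by less than ``tol`` (mm).  With
    ``trim_fraction`` > 0 the worst pairs are dropped each iteration, which
    tolerates partial overlap.  The RMSE trace is non-increasing; if the
    update would increase it, the previous iterate is returned.
    """
    mv = moving.vertices if isinstance(moving, SurfaceMesh) else np.asarray(moving)
    tv = target.vertices if isinstance(target, SurfaceMesh) else np.asarray(target)
    tree = cKDTree(tv)
    n_keep = max(3, int(np.ceil(len(mv) * (1 - trim_fraction))))

    def _score(transform):
        d, nn = tree.query(transform.apply(mv))
        kept = np.sort(d)[:n_keep]
        return float(np.sqrt((kept**2).mean())), d, nn

    tf = init
    prev, d, nn = _score(tf)
    for _ in range(max_iter):
        keep = np.argsort(d)[:n_keep]
        try:
            cand = estimate_rigid(mv[keep], tv[nn[keep]])
        except DegenerateSampleError:
            break
        rmse, d2, nn2 = _score(cand)
        if rmse > prev:
            break
        tf, d, nn = cand, d2, nn2
        if prev - rmse < tol:
            prev = rmse
            break
        prev = rmse
    return tf


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_registration(
    transform: RigidTransform,
    moving_points: np.ndarray,
    truth_points: np.ndarray,
) -> dict:
    """Per-point registration error against ground truth (mm).

    ``truth_points[i]`` is where ``moving_points[i]`` should land; the
    returned dict carries the per-point errors and their mean / std / max —
    for marker data this is the target registration error (TRE) distribution.
    """
    moving_points = np.atleast_2d(np.asarray(moving_points, dtype=np.float64))
    truth_points = np.atleast_2d(np.asarray(truth_points, dtype=np.float64))
    if len(moving_points) == 0:
        raise InputError("ground truth is empty")
    if moving_points.shape != truth_points.shape:
        raise InputError("moving and truth point arrays must match in shape")
    err = np.linalg.norm(transform.apply(moving_points) - truth_points, axis=1)
    return {
        "per_point_mm": err,
        "mean_mm": float(err.mean()),
        "std_mm": float(err.std()),
        "max_mm": float(err.max()),
    }


def marker_alignment_tre(markers_before: np.ndarray,
                         markers_after: np.ndarray) -> dict:
    """Best-case rigid TRE between two marker configurations.

    Fits the least-squares rigid transform from the markers in one state to
    the other and reports the residual TRE distribution — the floor any rigid
    registration of the two states can reach (e.g. implanted-marker
    validation of a deforming phantom).
    """
    tf = estimate_rigid(markers_before, markers_after)
    return evaluate_registration(tf, markers_before, markers_after)
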