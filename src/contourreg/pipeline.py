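"""End-to-end workflow: precompute the moving side, then register targets.

The moving (preoperative) surface can be processed once ahead of time —
feature sampling, descriptors, feature-to-feature and feature-to-ridge
geodesics are all pose-independent — and cached, so that registering an
intraoperative target only pays for the target-side computation.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from . import features as F
from . import geometry as G
from . import matching as MM
from . import registration as R

log = logging.getLogger("contourreg")

CACHE_SCHEMA = "contourreg-cache-1"


class CacheError(RuntimeError):
    """Raised when a precompute cache is missing fields or mismatched."""


@dataclass
class PipelineConfig:
    """All tunable parameters of the registration pipeline.

    Defaults follow the validated operating point: sigma_d = sigma_b = 0.3,
    alpha = 0.6, 1000 RANSAC iterations, a_normals = 60 degrees, d_ransac =
    5 mm for rigid scenarios (use 10 mm for deformed or noisy targets).
    The moving surface carries denser features (300) than the target (100):
    correspondence position noise is bounded by half the moving-side feature
    spacing, and the moving side is precomputed before surgery so its
    density is free at registration time.
    """

    n_features_moving: int = 300
    n_features_target: int = 100
    k: int = 5
    sampling: str = "fps"  # fps | nss | gfps
    toldi_radius: float | None = None  # mm; None -> radius_fraction * M diag
    toldi_radius_fraction: float = 0.10
    toldi_L: int = 20
    prune_max_size: int = 25
    sigma_d: float = 0.3
    sigma_b: float = 0.3
    alpha: float = 0.6
    eps: float = 1e-8
    ransac_iterations: int = 1000
    d_ransac: float = 5.0
    a_normals: float = 60.0
    reconstruct_edge_length: float = 2.0
    reconstruct_trim: float = 2.0
    refine: bool = True
    refine_trim_fraction: float | None = None  # None -> from area overlap
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling not in ("fps", "nss", "gfps"):
            raise G.InputError(f"unknown sampling strategy {self.sampling!r}")
        if min(self.n_features_moving, self.n_features_target) < 3:
            raise G.InputError("feature counts must be >= 3")
        if self.k < 1:
            raise G.InputError("k must be >= 1")
        if self.prune_max_size < 3:
            raise G.InputError("prune_max_size must be >= 3")
        # delegate range checks to the parameter dataclasses
        self.affinity_params()
        self.ransac_params()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise G.InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def affinity_params(self) -> MM.AffinityParams:
        return MM.AffinityParams(self.sigma_d, self.sigma_b, self.alpha,
                                 self.eps)

    def ransac_params(self, seed: int | None = None) -> R.RansacParams:
        return R.RansacParams(
            max_iterations=self.ransac_iterations,
            d_ransac=self.d_ransac,
            a_normals=self.a_normals,
            seed=self.seed if seed is None else seed,
        )


def derive_seed(seed: int, *stages: int) -> int:
    """Stable per-stage sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, *stages]).generate_state(1)[0]
               % (2**31 - 1))


def _sample_features(mesh, n, strategy, mask, seed):
    n = min(n, mesh.n_vertices if mask is None else len(np.atleast_1d(mask)))
    if strategy == "fps":
        return F.farthest_point_sampling(mesh, n, mask=mask, seed=seed)
    if strategy == "gfps":
        return F.geodesic_farthest_point_sampling(mesh, n, mask=mask, seed=seed)
    return F.normal_space_sampling(mesh, n, mask=mask, seed=seed)


@dataclass
class SideData:
    """Everything the matcher needs about one surface."""

    mesh: G.SurfaceMesh
    features: F.FeatureSet
    descriptors: F.DescriptorSet
    geodesics: np.ndarray  # feature x feature, mm
    contour: MM.ContourSet | None = None

    @property
    def positions(self) -> np.ndarray:
        return self.features.positions

    @property
    def normals(self) -> np.ndarray:
        return self.mesh.normals[self.features.vertex_indices]


def prepare_side(
    mesh: G.SurfaceMesh,
    contour_points: np.ndarray | None,
    config: PipelineConfig,
    mask=None,
    seed: int | None = None,
    toldi_radius: float | None = None,
    contour_vertices: np.ndarray | None = None,
    n_features: int | None = None,
) -> SideData:
    """Sample features, describe them, and precompute their geodesics.

    ``contour_points`` are ordered 3D ridge-line points in the surface's own
    frame (snapped to vertices); alternatively pass ``contour_vertices``
    already on the mesh.  ``n_features`` defaults to the moving-side count;
    the register workflow passes the target-side count explicitly.
    """
    if mesh.normals is None:
        mesh = G.compute_normals(mesh)
    seed = config.seed if seed is None else seed
    n = config.n_features_moving if n_features is None else n_features
    feats = _sample_features(mesh, n, config.sampling, mask, seed)
    radius = toldi_radius if toldi_radius is not None else (
        config.toldi_radius if config.toldi_radius is not None
        else config.toldi_radius_fraction * mesh.bbox_diagonal()
    )
    desc = F.compute_toldi(mesh, feats, radius=radius, L=config.toldi_L)
    geod = G.geodesic_matrix(mesh, feats.vertex_indices, feats.vertex_indices)
    contour = None
    if contour_vertices is not None:
        contour = MM.ContourSet(contour_vertices)
    elif contour_points is not None:
        contour = MM.snap_contour(np.asarray(contour_points), mesh)
    if contour is not None:
        contour = MM.contour_distances(mesh, contour, feats.vertex_indices)
    return SideData(mesh, feats, desc, geod, contour)


# ---------------------------------------------------------------------------
# Cache
# ---------------------------------------------------------------------------

def save_cache(path, side: SideData, config: PipelineConfig) -> None:
    """Serialise the precomputed moving side into a single .npz archive."""
    payload = {
        "schema": np.array(CACHE_SCHEMA),
        "vertices": side.mesh.vertices,
        "triangles": side.mesh.triangles,
        "normals": side.mesh.normals,
        "feature_indices": side.features.vertex_indices,
        "strategy": np.array(side.features.strategy),
        "descriptors": side.descriptors.vectors,
        "descriptor_valid": side.descriptors.valid,
        "toldi_radius": np.array(side.descriptors.radius),
        "toldi_L": np.array(side.descriptors.L),
        "geodesics": side.geodesics,
        "config_json": np.array(_config_json(config)),
    }
    if side.contour is not None:
        payload["contour_vertices"] = side.contour.contour_vertices
        payload["feature_to_contour"] = side.contour.feature_to_contour
    np.savez_compressed(path, **payload)


def _config_json(config: PipelineConfig) -> str:
    import json

    return json.dumps(config.to_dict())


def load_cache(path) -> tuple[SideData, PipelineConfig]:
    try:
        data = np.load(path, allow_pickle=False)
    except Exception as exc:  # noqa: BLE001
        raise CacheError(f"cannot read cache {path}: {exc}") from exc
    if "schema" not in data or str(data["schema"]) != CACHE_SCHEMA:
        raise CacheError(
            f"cache {path} has schema {data.get('schema', '<missing>')}, "
            f"expected {CACHE_SCHEMA}"
        )
    import json

    config = PipelineConfig.from_dict(json.loads(str(data["config_json"])))
    mesh = G.SurfaceMesh(data["vertices"], data["triangles"],
                         normals=data["normals"], role="M")
    feats = F.FeatureSet(mesh, data["feature_indices"],
                         strategy=str(data["strategy"]))
    desc = F.DescriptorSet(
        data["descriptors"],
        radius=float(data["toldi_radius"]),
        L=int(data["toldi_L"]),
        valid=data["descriptor_valid"],
    )
    contour = None
    if "contour_vertices" in data:
        contour = MM.ContourSet(data["contour_vertices"],
                                data["feature_to_contour"])
    return SideData(mesh, feats, desc, data["geodesics"], contour), config


# ---------------------------------------------------------------------------
# Registration workflow
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    registration: R.RegistrationResult
    refined: R.RigidTransform | None
    candidates: MM.CorrespondenceSet
    pruned: MM.CorrespondenceSet
    moving: SideData
    target: SideData

    @property
    def transform(self) -> R.RigidTransform:
        return self.refined if self.refined is not None else \
            self.registration.transform


def register(
    moving: SideData,
    target_surface: G.SurfaceMesh | G.PointCloud,
    target_contour_points: np.ndarray | None,
    config: PipelineConfig,
    algorithm: str = "SM+R2",
    seed: int | None = None,
    target_contour_vertices: np.ndarray | None = None,
    target_side: SideData | None = None,
) -> PipelineResult:
    """Run reconstruct -> sample -> describe -> match -> prune -> RANSAC.

    ``algorithm`` selects the pruning variant: ``"R"`` feeds the raw
    candidate set to RANSAC, ``"SM+R1"`` prunes with the rigidity term only
    (alpha forced to 1), ``"SM+R2"`` prunes with the full contour-constrained
    affinity.
    """
    if algorithm not in ("R", "SM+R1", "SM+R2"):
        raise G.InputError(f"unknown algorithm {algorithm!r}")
    seed = config.seed if seed is None else seed

    needs_contour = algorithm == "SM+R2" and config.alpha < 1.0
    if target_side is not None:
        target = target_side
    else:
        if isinstance(target_surface, G.PointCloud):
            log.info("reconstructing interpolated surface S from %d points",
                     len(target_surface.points))
            target_mesh = G.reconstruct_surface(
                target_surface,
                target_edge_length=config.reconstruct_edge_length,
                trim_tolerance=config.reconstruct_trim,
            )
        else:
            target_mesh = target_surface
        if target_mesh.normals is None:
            target_mesh = G.compute_normals(target_mesh)
        target = prepare_side(
            target_mesh,
            target_contour_points,
            config,
            seed=derive_seed(seed, 1),
            toldi_radius=moving.descriptors.radius,
            contour_vertices=target_contour_vertices,
            n_features=config.n_features_target,
        )
    if needs_contour and target.contour is None:
        raise MM.MissingContourError(
            "the contour-constrained algorithm needs the target ridge line; "
            "supply target contour points or use algorithm='SM+R1'"
        )

    C = F.candidate_correspondences(moving.descriptors, target.descriptors,
                                    k=config.k)
    if algorithm == "R":
        pruned = C
    else:
        params = config.affinity_params()
        if algorithm == "SM+R1":
            params = MM.AffinityParams(params.sigma_d, params.sigma_b, 1.0,
                                       params.eps)
        W = MM.build_affinity(
            C, moving.geodesics, target.geodesics, params,
            contour_m=moving.contour, contour_t=target.contour,
        )
        pruned = MM.spectral_prune(W, C, max_size=config.prune_max_size)

    result = R.ransac_rigid(
        pruned,
        moving.positions,
        target.positions,
        moving_normals=moving.normals,
        target_normals=target.normals,
        params=config.ransac_params(seed=derive_seed(seed, 2)),
    )
    refined = None
    if config.refine:
        trim = config.refine_trim_fraction
        if trim is None:
            # only the overlap region should drive ICP: a partial target
            # covers a fraction of M roughly equal to the area ratio
            overlap = min(
                1.0,
                1.2 * target.mesh.triangle_areas().sum()
                / moving.mesh.triangle_areas().sum(),
            )
            trim = max(0.0, 1.0 - overlap)
        refined = R.refine_icp(
            moving.mesh, target.mesh, result.transform,
            trim_fraction=trim,
        )
    log.info(
        "register[%s]: rmse=%.2f mm accepted=%s fallback=%s |C|=%d |C_p|=%d",
        algorithm, result.rmse, result.accepted, result.fallback,
        len(C), len(pruned),
    )
    return PipelineResult(result, refined, C, pruned, moving, target)
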