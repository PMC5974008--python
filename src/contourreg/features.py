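"""Feature sampling and local shape description.

Features are mesh vertices picked either by farthest point sampling (uniform
surface coverage) or by normal-space sampling (even coverage of normal
directions, hence fewer points on flat regions).  Each feature gets a TOLDI
descriptor — Triple Orthogonal Local Depth Images: the support neighbourhood
is expressed in a repeatable local reference frame and rendered as three
orthogonal depth images, making the descriptor invariant to rigid motion.
Candidate correspondences pair every target feature with its k nearest
moving-surface features in descriptor space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import InputError, SurfaceMesh, compute_normals
from .matching import Correspondence, CorrespondenceSet


@dataclass
class VisibilityMask:
    """Vertex indices of the moving mesh expected to be visible in theatre.

    Restricting the moving-side features to this set removes candidate
    matches on anatomically impossible (hidden) liver regions.
    """

    vertex_indices: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_indices = np.unique(
            np.asarray(self.vertex_indices, dtype=np.int64)
        )
        if len(self.vertex_indices) == 0:
            raise InputError("visibility mask must be non-empty")


@dataclass
class FeatureSet:
    """Sampled feature vertices of one surface."""

    mesh: SurfaceMesh
    vertex_indices: np.ndarray
    strategy: str = "fps"

    def __post_init__(self) -> None:
        self.vertex_indices = np.asarray(self.vertex_indices, dtype=np.int64)
        if len(np.unique(self.vertex_indices)) != len(self.vertex_indices):
            raise InputError("feature indices must be unique")
        if len(self.vertex_indices) and (
            self.vertex_indices.min() < 0
            or self.vertex_indices.max() >= self.mesh.n_vertices
        ):
            raise InputError("feature index out of range")

    def __len__(self) -> int:
        return len(self.vertex_indices)

    @property
    def positions(self) -> np.ndarray:
        return self.mesh.vertices[self.vertex_indices]


@dataclass
class DescriptorSet:
    """Fixed-length descriptors, one per feature; invalid ones are flagged.

    ``vectors`` has shape (n_features, 3 * L**2) with entries in [0, 1].
    """

    vectors: np.ndarray
    radius: float
    L: int
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.valid is None:
            self.valid = np.ones(len(self.vectors), dtype=bool)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3 * self.L**2:
            raise InputError("descriptor length must be 3 * L^2")

    def __len__(self) -> int:
        return len(self.vectors)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _resolve_mask(mesh: SurfaceMesh, mask) -> np.ndarray:
    if mask is None:
        return np.arange(mesh.n_vertices, dtype=np.int64)
    if isinstance(mask, VisibilityMask):
        idx = mask.vertex_indices
    else:
        idx = np.unique(np.asarray(mask, dtype=np.int64))
    if len(idx) == 0:
        raise InputError("visibility mask must be non-empty")
    if idx.min() < 0 or idx.max() >= mesh.n_vertices:
        raise InputError("mask index out of range")
    return idx


def farthest_point_sampling(
    mesh: SurfaceMesh, n: int, mask=None, seed: int = 0
) -> FeatureSet:
    """Greedy Euclidean farthest point sampling over (masked) vertices.

    The seed picks the start vertex; every later pick maximises the distance
    to the already-selected set, giving uniform surface coverage.  Ties break
    to the lowest vertex index, so the result is fully deterministic.
    """
    cand = _resolve_mask(mesh, mask)
    if not 1 <= n <= len(cand):
        raise InputError(f"n={n} outside [1, {len(cand)}]")
    rng = np.random.default_rng(seed)
    pts = mesh.vertices[cand]
    start = int(rng.integers(len(cand)))
    chosen = [start]
    mind = np.linalg.norm(pts - pts[start], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(pts - pts[nxt], axis=1))
    return FeatureSet(mesh, cand[np.asarray(chosen)], strategy="fps")


def geodesic_farthest_point_sampling(
    mesh: SurfaceMesh, n: int, mask=None, seed: int = 0
) -> FeatureSet:
    """FPS under geodesic (surface) distance instead of Euclidean."""
    from .geometry import geodesic_distances

    cand = _resolve_mask(mesh, mask)
    if not 1 <= n <= len(cand):
        raise InputError(f"n={n} outside [1, {len(cand)}]")
    rng = np.random.default_rng(seed)
    start = int(cand[rng.integers(len(cand))])
    chosen = [start]
    mind = geodesic_distances(mesh, [start]).distances
    for _ in range(n - 1):
        nxt = int(cand[np.argmax(np.where(np.isfinite(mind[cand]), mind[cand], -1))])
        chosen.append(nxt)
        mind = np.minimum(mind, geodesic_distances(mesh, [nxt]).distances)
    return FeatureSet(mesh, np.asarray(chosen), strategy="gfps")


def _sphere_bins(normals: np.ndarray, bins: int) -> np.ndarray:
    """Assign unit normals to roughly equal-area cells of the sphere."""
    n_z = max(int(np.round(np.sqrt(bins / 2))), 1)
    n_az = max(int(np.ceil(bins / n_z)), 1)
    z = np.clip(normals[:, 2], -1.0, 1.0)
    iz = np.minimum(((z + 1.0) / 2.0 * n_z).astype(int), n_z - 1)
    az = np.arctan2(normals[:, 1], normals[:, 0])  # [-pi, pi]
    ia = np.minimum(((az + np.pi) / (2 * np.pi) * n_az).astype(int), n_az - 1)
    return iz * n_az + ia


def normal_space_sampling(
    mesh: SurfaceMesh, n: int, bins: int = 32, mask=None, seed: int = 0
) -> FeatureSet:
    """Sample so normal directions are covered as evenly as possible.

    Normals are bucketed on a sphere grid of ~``bins`` cells and samples are
    drawn round-robin from the occupied buckets; flat regions (one dominant
    normal direction) therefore contribute few samples.  No bucket receives
    more than ceil(n / #occupied) samples.
    """
    if bins < 1:
        raise InputError("bins must be >= 1")
    if n < 0:
        raise InputError("n must be >= 0")
    cand = _resolve_mask(mesh, mask)
    if n == 0:
        return FeatureSet(mesh, np.empty(0, dtype=np.int64), strategy="nss")
    if n > len(cand):
        raise InputError(f"n={n} exceeds {len(cand)} available vertices")
    m = mesh if mesh.normals is not None else compute_normals(mesh)
    normals = m.normals[cand]
    ok = np.linalg.norm(normals, axis=1) > 0.5  # skip zero-normal vertices
    cand = cand[ok]
    normals = normals[ok]
    labels = _sphere_bins(normals, bins)
    rng = np.random.default_rng(seed)
    buckets = []
    for lab in np.unique(labels):
        members = cand[labels == lab]
        buckets.append(rng.permutation(members))
    order = rng.permutation(len(buckets))
    chosen: list[int] = []
    depth = 0
    while len(chosen) < n:
        progressed = False
        for bi in order:
            if len(chosen) >= n:
                break
            if depth < len(buckets[bi]):
                chosen.append(int(buckets[bi][depth]))
                progressed = True
        if not progressed:
            break
        depth += 1
    return FeatureSet(mesh, np.asarray(chosen[:n], dtype=np.int64), strategy="nss")


# ---------------------------------------------------------------------------
# TOLDI descriptor
# ---------------------------------------------------------------------------

def _toldi_lrf(p: np.ndarray, support: np.ndarray, radius: float) -> np.ndarray:
    """Repeatable local reference frame of a support neighbourhood.

    z-axis: smallest-eigenvalue direction of the distance-weighted covariance
    of the support, signed so that the support lies on its negative side.
    x-axis: sign-disambiguated weighted sum of the support vectors projected
    into the tangent plane, weighting near and well-off-plane points higher.
    Returns a 3x3 matrix with rows (x, y, z).
    """
    q = support - p
    d = np.linalg.norm(q, axis=1)
    w1 = (radius - d) ** 2
    cov = (q * w1[:, None]).T @ q / max(w1.sum(), 1e-300)
    evals, evecs = np.linalg.eigh(cov)
    z = evecs[:, 0]
    if (q @ z).sum() > 0:
        z = -z
    proj = q - np.outer(q @ z, z)
    w2 = (q @ z) ** 2
    x = (proj * (w1 * w2)[:, None]).sum(axis=0)
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        # degenerate (perfectly symmetric) neighbourhood: any tangent axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(z @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        x = ref - (ref @ z) * z
        nx = np.linalg.norm(x)
    x = x / nx
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def _depth_images(q: np.ndarray, radius: float, L: int) -> np.ndarray:
    """Three orthogonal LxL depth images of LRF-space support points.

    For each view axis the remaining two coordinates index the pixel and the
    pixel stores the *nearest* depth, scaled to [0, 1]; empty pixels read 1
    (background at the far plane).
    """
    img = np.ones((3, L, L))
    views = ((0, 1, 2), (1, 2, 0), (2, 0, 1))  # (u, v, depth axis)
    for vi, (ua, va, da) in enumerate(views):
        u = np.clip(((q[:, ua] + radius) / (2 * radius) * L).astype(int), 0, L - 1)
        v = np.clip(((q[:, va] + radius) / (2 * radius) * L).astype(int), 0, L - 1)
        depth = np.clip((q[:, da] + radius) / (2 * radius), 0.0, 1.0)
        flat = u * L + v
        order = np.argsort(depth, kind="stable")[::-1]  # nearest written last
        plane = img[vi].reshape(-1)
        plane[flat[order]] = depth[order]
    return img


def _barycentric_grid(order: int) -> np.ndarray:
    """Barycentric sample coordinates of order q, corners excluded."""
    coords = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            k = order - i - j
            if order in (i, j, k):  # corner = mesh vertex, already present
                continue
            coords.append((i / order, j / order, k / order))
    return np.asarray(coords)


_DENSE_CACHE: dict[int, tuple[SurfaceMesh, np.ndarray]] = {}


def _dense_surface_points(mesh: SurfaceMesh, order: int = 3) -> np.ndarray:
    """Mesh vertices plus a deterministic barycentric grid on every face.

    Densifies the support cloud so TOLDI depth images describe the surface
    rather than its tessellation; cached per mesh object.
    """
    key = id(mesh)
    hit = _DENSE_CACHE.get(key)
    if hit is not None and hit[0] is mesh:
        return hit[1]
    tri = mesh.vertices[mesh.triangles]  # (m, 3, 3)
    bary = _barycentric_grid(order)  # (s, 3)
    extra = np.einsum("sk,mkd->msd", bary, tri).reshape(-1, 3)
    pts = np.vstack([mesh.vertices, extra])
    if len(_DENSE_CACHE) > 16:
        _DENSE_CACHE.clear()
    _DENSE_CACHE[key] = (mesh, pts)
    return pts


def compute_toldi(
    mesh: SurfaceMesh,
    features: FeatureSet,
    radius: float | None = None,
    L: int = 20,
    min_support: int = 5,
    supersample_order: int = 3,
) -> DescriptorSet:
    """TOLDI descriptors of the feature vertices.

    Parameters
    ----------
    radius : float, mm
        Support radius; defaults to 15% of the mesh bounding-box diagonal.
    L : int
        Depth-image side length; the descriptor has 3 * L**2 entries in
        [0, 1].
    min_support : int
        Features with fewer support vertices are flagged invalid and excluded
        from matching.
    supersample_order : int
        Barycentric sampling order per face for the support cloud (0 uses
        raw vertices only).  Dense support makes the depth images vary
        smoothly along the surface, which k-NN candidate generation relies
        on.
    """
    if radius is None:
        radius = 0.15 * mesh.bbox_diagonal()
    if radius <= 0:
        raise InputError("radius must be positive")
    if L < 2:
        raise InputError("L must be >= 2")
    cloud = (mesh.vertices if supersample_order < 1
             else _dense_surface_points(mesh, supersample_order))
    tree = cKDTree(cloud)
    vectors = np.zeros((len(features), 3 * L * L))
    valid = np.zeros(len(features), dtype=bool)
    for i, vi in enumerate(features.vertex_indices):
        p = mesh.vertices[vi]
        idx = tree.query_ball_point(p, radius)
        support = cloud[idx]
        if len(support) < min_support:
            continue
        lrf = _toldi_lrf(p, support, radius)
        q = (support - p) @ lrf.T
        vectors[i] = _depth_images(q, radius, L).reshape(-1)
        valid[i] = True
    return DescriptorSet(vectors, radius=radius, L=L, valid=valid)


# ---------------------------------------------------------------------------
# Candidate correspondences
# ---------------------------------------------------------------------------

def candidate_correspondences(
    desc_m: DescriptorSet, desc_t: DescriptorSet, k: int = 5
) -> CorrespondenceSet:
    """Pair each target feature with its k nearest moving descriptors (L2).

    k is clamped to the number of valid moving features.  Invalid descriptors
    on either side never enter the candidate set.
    """
    if len(desc_m) == 0 or len(desc_t) == 0:
        raise InputError("descriptor sets must be non-empty")
    if k < 1:
        raise InputError("k must be >= 1")
    m_valid = np.flatnonzero(desc_m.valid)
    t_valid = np.flatnonzero(desc_t.valid)
    if len(m_valid) == 0 or len(t_valid) == 0:
        raise InputError("no valid descriptors to match")
    k = min(k, len(m_valid))
    tree = cKDTree(desc_m.vectors[m_valid])
    dist, nn = tree.query(desc_t.vectors[t_valid], k=k)
    dist = np.atleast_2d(dist.T).T if k == 1 else dist
    nn = np.atleast_2d(nn.T).T if k == 1 else nn
    pairs = [
        Correspondence(int(m_valid[nn[r, c]]), int(t_valid[r]),
                       descriptor_distance=float(dist[r, c]))
        for r in range(len(t_valid))
        for c in range(k)
    ]
    return CorrespondenceSet(pairs, stage="initial")
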