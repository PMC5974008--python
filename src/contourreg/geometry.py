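"""Surface data model, mesh I/O, normals, reconstruction and geodesic distances.

All coordinates are in millimetres.  Meshes are cleaned on load (degenerate
zero-area triangles dropped, out-of-range indices rejected) so that downstream
stages can rely on a valid triangulation.  Geodesic distances are computed on
mesh vertices with a fast-marching eikonal solver; feature points from sparse
point clouds are snapped to vertices of an interpolated surface by nearest
neighbour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from numba import njit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree, breadth_first_order
from scipy.spatial import cKDTree


class FormatError(ValueError):
    """Raised when a surface file cannot be parsed."""


class InputError(ValueError):
    """Raised for empty or degenerate input geometry."""


class ReconstructionError(RuntimeError):
    """Raised when a point cloud cannot be triangulated into a surface."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """A triangle mesh with per-vertex unit normals.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    triangles : (m, 3) int array of vertex indices
    normals : (n, 3) float array or None
        Unit per-vertex normals; computed lazily by :func:`compute_normals`.
    role : str
        ``"M"`` (moving / preoperative), ``"T"`` (target / intraoperative) or
        ``"S"`` (surface interpolated from a sparse target cloud).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    normals: np.ndarray | None = None
    role: str = "M"

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InputError("vertices must be an (n, 3) array")
        if len(self.triangles) and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise InputError("triangle indices out of range")
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    def edge_lengths(self) -> np.ndarray:
        """Lengths (mm) of the unique edges of the triangulation."""
        tm = self.as_trimesh()
        e = tm.edges_unique
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )

    def bbox_diagonal(self) -> float:
        return float(np.linalg.norm(self.vertices.max(0) - self.vertices.min(0)))

    def submesh(self, vertex_mask: np.ndarray, role: str | None = None):
        """Restrict to triangles whose three vertices are all in the mask.

        Returns ``(mesh, index_map)`` where ``index_map[i]`` is the index in
        the parent mesh of vertex ``i`` of the submesh.
        """
        vertex_mask = np.asarray(vertex_mask)
        if vertex_mask.dtype != bool:
            m = np.zeros(self.n_vertices, dtype=bool)
            m[vertex_mask] = True
            vertex_mask = m
        keep_tri = vertex_mask[self.triangles].all(axis=1)
        tris = self.triangles[keep_tri]
        used = np.unique(tris)
        remap = -np.ones(self.n_vertices, dtype=np.int64)
        remap[used] = np.arange(len(used))
        sub = SurfaceMesh(
            self.vertices[used],
            remap[tris],
            normals=None if self.normals is None else self.normals[used],
            role=role or self.role,
        )
        return sub, used


@dataclass
class PointCloud:
    """An unstructured 3D point set (mm) with optional normals."""

    points: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) == 0:
            raise InputError("points must be a non-empty (n, 3) array")
        if not np.isfinite(self.points).all():
            raise InputError("point coordinates must be finite")


@dataclass
class GeodesicField:
    """First-arrival surface distances (mm) from a set of source vertices."""

    sources: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.sources = np.atleast_1d(np.asarray(self.sources, dtype=np.int64))
        self.distances = np.asarray(self.distances, dtype=np.float64)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MESH_SUFFIXES = {".ply", ".obj", ".stl", ".off"}


def load_surface(path: str | Path) -> SurfaceMesh | PointCloud:
    """Load a PLY/OBJ/STL mesh, or a PLY/CSV point cloud if it has no faces.

    Coordinates are assumed to be in mm.  Degenerate (zero-area) triangles
    and unreferenced vertices are removed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        return load_point_cloud_csv(path)
    try:
        loaded = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - trimesh raises many types
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if isinstance(loaded, trimesh.PointCloud) or (
        hasattr(loaded, "faces") and len(loaded.faces) == 0
    ):
        pts = np.asarray(loaded.vertices, dtype=np.float64)
        if len(pts) == 0:
            raise InputError(f"{path} contains no geometry")
        return PointCloud(pts)
    if not hasattr(loaded, "faces"):
        raise FormatError(f"{path} did not load as a mesh")
    verts = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if len(verts) == 0:
        raise InputError(f"{path} contains no geometry")
    return _clean_mesh(SurfaceMesh(verts, faces))


def save_surface(mesh: SurfaceMesh | PointCloud, path: str | Path) -> None:
    path = Path(path)
    if isinstance(mesh, PointCloud):
        trimesh.PointCloud(mesh.points).export(str(path))
        return
    mesh.as_trimesh().export(str(path))


def load_point_cloud_csv(path: str | Path) -> PointCloud:
    """Read ``x,y,z[,nx,ny,nz]`` rows; a non-numeric first row is a header."""
    path = Path(path)
    try:
        data = np.genfromtxt(path, delimiter=",", skip_header=0)
        if np.isnan(data).all(axis=None) or data.ndim == 0:
            raise ValueError
        if data.ndim == 1:
            data = data[None, :]
        if np.isnan(data[0]).any():  # header row
            data = data[1:]
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse point CSV {path}: {exc}") from exc
    if data.size == 0 or data.shape[1] < 3:
        raise InputError(f"{path}: expected at least 3 columns (x,y,z)")
    normals = data[:, 3:6] if data.shape[1] >= 6 else None
    return PointCloud(data[:, :3], normals)


def _clean_mesh(mesh: SurfaceMesh) -> SurfaceMesh:
    """Drop zero-area triangles and unreferenced vertices."""
    areas = mesh.triangle_areas()
    keep = areas > 1e-12
    tris = mesh.triangles[keep]
    used = np.unique(tris) if len(tris) else np.arange(mesh.n_vertices)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(mesh.vertices[used], remap[tris] if len(tris) else tris,
                       role=mesh.role)


# ---------------------------------------------------------------------------
# Normals
# ---------------------------------------------------------------------------

def compute_normals(mesh: SurfaceMesh) -> SurfaceMesh:
    """Angle-weighted per-vertex unit normals.

    For a closed mesh the orientation is made consistently outward (positive
    enclosed volume).  Isolated vertices receive a zero normal, which flags
    them as unusable for descriptor computation.
    """
    if mesh.n_triangles < 1:
        raise InputError("mesh has no triangles")
    tm = mesh.as_trimesh()
    tris = mesh.triangles
    if tm.is_volume or (tm.is_watertight and tm.volume != 0):
        if tm.volume < 0:  # flip winding to point outward
            tris = tris[:, ::-1]
            tm = trimesh.Trimesh(mesh.vertices, tris, process=False)

    v = mesh.vertices[tris]
    fn = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    norms = np.linalg.norm(fn, axis=1, keepdims=True)
    fn = fn / np.maximum(norms, 1e-300)

    normals = np.zeros((mesh.n_vertices, 3))
    for corner in range(3):
        a = v[:, (corner + 1) % 3] - v[:, corner]
        b = v[:, (corner + 2) % 3] - v[:, corner]
        an = np.linalg.norm(a, axis=1)
        bn = np.linalg.norm(b, axis=1)
        cosang = np.clip((a * b).sum(1) / np.maximum(an * bn, 1e-300), -1.0, 1.0)
        w = np.arccos(cosang)
        np.add.at(normals, tris[:, corner], fn * w[:, None])

    lens = np.linalg.norm(normals, axis=1, keepdims=True)
    nonzero = lens[:, 0] > 1e-12
    normals[nonzero] /= lens[nonzero]
    normals[~nonzero] = 0.0  # isolated-vertex flag
    return SurfaceMesh(mesh.vertices, tris, normals=normals, role=mesh.role)


# ---------------------------------------------------------------------------
# Geodesic distances (fast marching)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _planar_update(ax, ay, az, bx, by, bz, cx, cy, cz, da, db):
    """Eikonal update of vertex C from triangle (A, B, C) with values da, db.

    Works by unfolding: reconstruct the virtual point source S in the triangle
    plane, on the far side of edge AB, consistent with |SA| = da, |SB| = db;
    the update is |SC| provided the segment S->C crosses the open edge AB.
    Returns inf when the update is invalid (the edge fallbacks then apply).
    """
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    c2 = abx * abx + aby * aby + abz * abz
    c = np.sqrt(c2)
    if c < 1e-300:
        return np.inf
    # local 2D frame: A=(0,0), B=(c,0), C=(px,py) with py > 0
    px = (acx * abx + acy * aby + acz * abz) / c
    q2 = acx * acx + acy * acy + acz * acz - px * px
    py = np.sqrt(q2) if q2 > 0.0 else 0.0
    # virtual source below the AB axis
    sx = (da * da - db * db + c2) / (2.0 * c)
    sy2 = da * da - sx * sx
    if sy2 < 0.0:
        return np.inf
    sy = -np.sqrt(sy2)
    dy = py - sy
    if dy <= 1e-300:
        return np.inf
    # crossing point of segment S->C with the AB axis must lie inside (0, c)
    t = (0.0 - sy) / dy
    x_cross = sx + t * (px - sx)
    if x_cross <= 0.0 or x_cross >= c:
        return np.inf
    ddx = px - sx
    return np.sqrt(ddx * ddx + dy * dy)


@njit(cache=True)
def _fast_march(verts, tri_off, tri_b, tri_c, sources, source_d):
    """Multi-source fast marching over a vertex-based triangle fan structure.

    ``tri_off``/``tri_b``/``tri_c`` give, CSR-style per vertex v, the pairs of
    other vertices (b, c) of each triangle incident to v.
    """
    n = verts.shape[0]
    INF = np.inf
    dist = np.full(n, INF)
    frozen = np.zeros(n, np.uint8)

    # each fan entry can trigger at most 4 pushes (2 edge + 2 triangle)
    cap = 4 * len(tri_b) + 4 * len(sources) + 16
    heap_d = np.empty(cap, np.float64)
    heap_v = np.empty(cap, np.int64)
    hn = 0

    def _push(heap_d, heap_v, hn, d, v):
        i = hn
        heap_d[i] = d
        heap_v[i] = v
        while i > 0:
            p = (i - 1) >> 1
            if heap_d[p] <= heap_d[i]:
                break
            heap_d[p], heap_d[i] = heap_d[i], heap_d[p]
            heap_v[p], heap_v[i] = heap_v[i], heap_v[p]
            i = p
        return hn + 1

    for k in range(len(sources)):
        s = sources[k]
        d0 = source_d[k]
        if d0 < dist[s]:
            dist[s] = d0
            hn = _push(heap_d, heap_v, hn, d0, s)

    while hn > 0:
        dv = heap_d[0]
        v = heap_v[0]
        hn -= 1
        heap_d[0] = heap_d[hn]
        heap_v[0] = heap_v[hn]
        i = 0
        while True:
            l = 2 * i + 1
            r = l + 1
            sm = i
            if l < hn and heap_d[l] < heap_d[sm]:
                sm = l
            if r < hn and heap_d[r] < heap_d[sm]:
                sm = r
            if sm == i:
                break
            heap_d[sm], heap_d[i] = heap_d[i], heap_d[sm]
            heap_v[sm], heap_v[i] = heap_v[i], heap_v[sm]
            i = sm
        if frozen[v]:
            continue
        frozen[v] = 1

        vx, vy, vz = verts[v, 0], verts[v, 1], verts[v, 2]
        for t in range(tri_off[v], tri_off[v + 1]):
            b = tri_b[t]
            c = tri_c[t]
            # edge updates
            for w in (b, c):
                if frozen[w]:
                    continue
                ex = verts[w, 0] - vx
                ey = verts[w, 1] - vy
                ez = verts[w, 2] - vz
                nd = dv + np.sqrt(ex * ex + ey * ey + ez * ez)
                if nd < dist[w]:
                    dist[w] = nd
                    if hn >= cap:
                        continue
                    hn = _push(heap_d, heap_v, hn, nd, w)
            # two-point (triangle) updates using v together with the other
            # known vertex of this triangle
            for known, unknown in ((b, c), (c, b)):
                if frozen[unknown] or dist[known] == INF:
                    continue
                nd = _planar_update(
                    vx, vy, vz,
                    verts[known, 0], verts[known, 1], verts[known, 2],
                    verts[unknown, 0], verts[unknown, 1], verts[unknown, 2],
                    dv, dist[known],
                )
                if nd < dist[unknown]:
                    dist[unknown] = nd
                    if hn >= cap:
                        continue
                    hn = _push(heap_d, heap_v, hn, nd, unknown)
    return dist


class _FanStructure:
    """CSR lists of the two opposite vertices of every triangle fan."""

    def __init__(self, mesh: SurfaceMesh):
        tris = mesh.triangles
        n = mesh.n_vertices
        v_all = np.concatenate([tris[:, 0], tris[:, 1], tris[:, 2]])
        b_all = np.concatenate([tris[:, 1], tris[:, 2], tris[:, 0]])
        c_all = np.concatenate([tris[:, 2], tris[:, 0], tris[:, 1]])
        order = np.argsort(v_all, kind="stable")
        self.b = np.ascontiguousarray(b_all[order])
        self.c = np.ascontiguousarray(c_all[order])
        counts = np.bincount(v_all, minlength=n)
        self.off = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)


_FAN_CACHE: dict[int, tuple[SurfaceMesh, _FanStructure]] = {}


def _fan(mesh: SurfaceMesh) -> _FanStructure:
    key = id(mesh)
    hit = _FAN_CACHE.get(key)
    if hit is not None and hit[0] is mesh:
        return hit[1]
    fs = _FanStructure(mesh)
    if len(_FAN_CACHE) > 32:
        _FAN_CACHE.clear()
    _FAN_CACHE[key] = (mesh, fs)
    return fs


def geodesic_distances(
    mesh: SurfaceMesh, sources, source_offsets=None
) -> GeodesicField:
    """First-arrival geodesic distance from the nearest source to every vertex.

    Uses fast marching with a virtual-source triangle update; falls back to
    edge (Dijkstra) updates where the two-point update is not admissible.
    Vertices in components not containing a source get ``inf`` (a warning is
    emitted, not an error: merged intraoperative patches may be disconnected).
    """
    sources = np.atleast_1d(np.asarray(sources, dtype=np.int64))
    if len(sources) == 0:
        raise InputError("sources must be non-empty")
    if sources.min() < 0 or sources.max() >= mesh.n_vertices:
        raise InputError("source index out of range")
    if source_offsets is None:
        source_offsets = np.zeros(len(sources))
    source_offsets = np.asarray(source_offsets, dtype=np.float64)
    fs = _fan(mesh)
    dist = _fast_march(mesh.vertices, fs.off, fs.b, fs.c, sources, source_offsets)
    if np.isinf(dist).any():
        warnings.warn(
            f"{int(np.isinf(dist).sum())} vertices unreachable from sources "
            "(disconnected component); their geodesic distance is inf",
            stacklevel=2,
        )
    return GeodesicField(sources, dist)


def geodesic_matrix(mesh: SurfaceMesh, from_idx, to_idx) -> np.ndarray:
    """Pairwise geodesic distances (mm) between two vertex index sets."""
    from_idx = np.asarray(from_idx, dtype=np.int64)
    to_idx = np.asarray(to_idx, dtype=np.int64)
    out = np.empty((len(from_idx), len(to_idx)))
    for i, s in enumerate(from_idx):
        out[i] = geodesic_distances(mesh, [s]).distances[to_idx]
    return out


# ---------------------------------------------------------------------------
# Nearest-vertex mapping
# ---------------------------------------------------------------------------

def map_to_surface(points: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Index of the Euclidean-nearest mesh vertex for each query point.

    Exact ties resolve to the lowest vertex index.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if mesh.n_vertices == 0:
        raise InputError("mesh is empty")
    tree = cKDTree(mesh.vertices)
    k = min(8, mesh.n_vertices)
    d, idx = tree.query(points, k=k)
    if k == 1:
        return np.atleast_1d(idx)
    d = np.atleast_2d(d)
    idx = np.atleast_2d(idx)
    best = np.empty(len(points), dtype=np.int64)
    for i in range(len(points)):
        tied = d[i] <= d[i, 0] * (1 + 1e-12) + 1e-12
        best[i] = idx[i][tied].min()
    return best


# ---------------------------------------------------------------------------
# Surface reconstruction of sparse targets
# ---------------------------------------------------------------------------

def estimate_point_normals(cloud: PointCloud, k: int = 16) -> PointCloud:
    """Local-PCA normals with orientation propagated along a Euclidean MST.

    The sign convention is global-consistency only (a closed cloud may end up
    inward); descriptor and matching stages are insensitive to a global flip.
    """
    pts = cloud.points
    n = len(pts)
    k = min(k, n - 1)
    if k < 2:
        raise ReconstructionError("too few points to estimate normals")
    tree = cKDTree(pts)
    _, nbrs = tree.query(pts, k=k + 1)
    normals = np.empty((n, 3))
    for i in range(n):
        q = pts[nbrs[i]] - pts[nbrs[i]].mean(axis=0)
        _, _, vt = np.linalg.svd(q, full_matrices=False)
        normals[i] = vt[2]
    # orientation propagation: MST with weight 1 - |n_i . n_j|
    rows, cols, wts = [], [], []
    for i in range(n):
        for j in nbrs[i, 1:]:
            rows.append(i)
            cols.append(int(j))
            wts.append(1.0 - abs(float(normals[i] @ normals[j])) + 1e-9)
    g = coo_matrix((wts, (rows, cols)), shape=(n, n))
    mst = minimum_spanning_tree(g)
    sym = mst + mst.T
    order, pred = breadth_first_order(sym, 0, directed=False)
    for node in order[1:]:
        p = pred[node]
        if normals[node] @ normals[p] < 0:
            normals[node] = -normals[node]
    return PointCloud(pts, normals)


def reconstruct_surface(
    cloud: PointCloud,
    target_edge_length: float = 2.0,
    trim_tolerance: float = 2.0,
) -> SurfaceMesh:
    """Interpolate a sparse target point cloud into a triangle surface S.

    An oriented signed-distance field (distance to the nearest cloud point,
    signed by that point's normal) is sampled on a voxel grid and contoured
    with marching cubes; faces farther than ``trim_tolerance`` from any input
    point are trimmed away, which opens the extrapolated parts of the shell
    and leaves a surface that tracks the data.

    Parameters
    ----------
    target_edge_length : float, mm
        Voxel size of the implicit grid, hence the approximate edge length of
        the reconstructed triangulation.
    trim_tolerance : float, mm
        Faces with centroid farther than this from every input point are
        removed; also the guaranteed bound on input-point-to-surface distance.
    """
    from skimage.measure import marching_cubes

    pts = cloud.points
    if len(pts) < 50:
        raise ReconstructionError("need at least 50 points for reconstruction")
    centred = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centred, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ReconstructionError("degenerate (collinear) point cloud")

    if cloud.normals is None:
        cloud = estimate_point_normals(cloud)
    tree = cKDTree(pts)

    h = float(target_edge_length)
    lo = pts.min(axis=0) - 4 * h
    hi = pts.max(axis=0) + 4 * h
    shape = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 2)
    # cap the grid so pathological target_edge_length cannot exhaust memory
    while np.prod(shape) > 4e7:
        h *= 1.5
        shape = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 2)
    axes = [lo[a] + h * np.arange(shape[a]) for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d, nearest = tree.query(grid)
    diff = grid - pts[nearest]
    signed = np.einsum("ij,ij->i", diff, cloud.normals[nearest])
    signed = signed.reshape(shape)

    try:
        verts, faces, _, _ = marching_cubes(signed, level=0.0, spacing=(h, h, h))
    except (ValueError, RuntimeError) as exc:
        raise ReconstructionError(f"marching cubes failed: {exc}") from exc
    verts = verts + lo

    mesh = _clean_mesh(SurfaceMesh(verts, faces.astype(np.int64), role="S"))
    # trim faces not supported by data; the support radius scales with the
    # cloud's own sampling spacing so sparse-but-valid regions survive
    spacing_d, _ = tree.query(pts, k=min(5, len(pts)))
    spacing = float(np.median(spacing_d[:, -1]))
    support = max(trim_tolerance, h, 1.5 * spacing)
    centroids = mesh.vertices[mesh.triangles].mean(axis=1)
    dist_to_data, _ = tree.query(centroids)
    keep = dist_to_data <= support
    if not keep.any():
        raise ReconstructionError("no reconstructed face lies near the data")
    tris = mesh.triangles[keep]
    used = np.unique(tris)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = SurfaceMesh(mesh.vertices[used], remap[tris], role="S")
    # keep only the dominant connected component (marching cubes can emit
    # small floaters from noise)
    tm = mesh.as_trimesh()
    comps = tm.split(only_watertight=False)
    if len(comps) > 1:
        biggest = max(comps, key=lambda c: c.area)
        mesh = SurfaceMesh(
            np.asarray(biggest.vertices), np.asarray(biggest.faces, dtype=np.int64),
            role="S",
        )
    mesh = compute_normals(mesh)

    worst = surface_distance(pts, mesh).max()
    if worst > max(trim_tolerance, 2 * h):
        warnings.warn(
            f"reconstruction deviates {worst:.2f} mm from input points",
            stacklevel=2,
        )
    return mesh


def _point_triangle_distances(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distance from one point to each of a stack of triangles.

    Closest-point-on-triangle via the barycentric region test (Ericson,
    Real-Time Collision Detection).  ``tri`` has shape (k, 3, 3).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(a)
    done = np.zeros(len(tri), dtype=bool)

    region = (d1 <= 0) & (d2 <= 0)  # vertex A
    closest[region] = a[region]
    done |= region
    region = (~done) & (d3 >= 0) & (d4 <= d3)  # vertex B
    closest[region] = b[region]
    done |= region
    region = (~done) & (d6 >= 0) & (d5 <= d6)  # vertex C
    closest[region] = c[region]
    done |= region

    vc = d1 * d4 - d3 * d2
    region = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge AB
    if region.any():
        t = np.where(np.abs(d1 - d3) > 1e-300, d1 / (d1 - d3), 0.0)
        closest[region] = a[region] + t[region, None] * ab[region]
        done |= region
    vb = d5 * d2 - d1 * d6
    region = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge AC
    if region.any():
        t = np.where(np.abs(d2 - d6) > 1e-300, d2 / (d2 - d6), 0.0)
        closest[region] = a[region] + t[region, None] * ac[region]
        done |= region
    va = d3 * d6 - d5 * d4
    region = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge BC
    if region.any():
        denom = (d4 - d3) + (d5 - d6)
        t = np.where(np.abs(denom) > 1e-300, (d4 - d3) / denom, 0.0)
        closest[region] = b[region] + t[region, None] * (c - b)[region]
        done |= region
    region = ~done  # interior
    if region.any():
        denom = np.maximum(va + vb + vc, 1e-300)
        v = vb / denom
        w = vc / denom
        closest[region] = (
            a[region] + v[region, None] * ab[region] + w[region, None] * ac[region]
        )
    return np.linalg.norm(closest - p, axis=1)


def surface_distance(
    points: np.ndarray, mesh: SurfaceMesh, n_candidate_vertices: int = 6
) -> np.ndarray:
    """Unsigned distance (mm) from each point to the mesh surface.

    Exact over the faces incident to each query's nearest vertices; with the
    default candidate count this is exact for all practical meshes (a face of
    the true closest triangle always touches one of the nearest vertices on
    well-shaped triangulations).
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tree = cKDTree(mesh.vertices)
    k = min(n_candidate_vertices, mesh.n_vertices)
    _, nearest = tree.query(points, k=k)
    nearest = np.atleast_2d(nearest)
    # vertex -> incident faces
    fan = _fan(mesh)
    tri_coords = mesh.vertices[mesh.triangles]
    n = mesh.n_vertices
    out = np.empty(len(points))
    for i, p in enumerate(points):
        faces = []
        for v in nearest[i]:
            lo, hi = fan.off[v], fan.off[v + 1]
            for t in range(lo, hi):
                faces.append((v, fan.b[t], fan.c[t]))
        if not faces:
            out[i] = np.linalg.norm(mesh.vertices[nearest[i, 0]] - p)
            continue
        tris = mesh.vertices[np.asarray(faces, dtype=np.int64)]
        out[i] = _point_triangle_distances(p, tris).min()
    return out
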