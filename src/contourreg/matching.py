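"""Contour-constrained spectral correspondence pruning.

Candidate correspondences between the preoperative (moving, M) and
intraoperative (target, T) surfaces are the nodes of an association graph.
Its affinity matrix W carries descriptor similarity on the diagonal and, off
the diagonal, a mix of two pairwise geometric-consistency terms:

* a *rigidity* term comparing the geodesic distance between two features on M
  with the distance between their proposed matches on T, and
* a *contour* term comparing each feature's geodesic distance to the liver
  ridge line on its own surface with that of its proposed match.

The dominant mutually-consistent cluster of candidates is extracted from the
principal eigenvector of W with a greedy one-to-one selection, yielding the
pruned set C_p handed to RANSAC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import GeodesicField, InputError, SurfaceMesh, geodesic_distances, map_to_surface


class MissingContourError(ValueError):
    """Raised when the contour term is requested without both ridge lines."""


# ---------------------------------------------------------------------------
# Correspondences
# ---------------------------------------------------------------------------

@dataclass
class Correspondence:
    """One candidate pairing of moving feature ``m`` with target feature ``t``.

    Indices address positions *within the feature sets*, not mesh vertices.
    """

    m: int
    t: int
    descriptor_distance: float = 0.0
    descriptor_similarity: float = 1.0
    eigen_score: float = 0.0


@dataclass
class CorrespondenceSet:
    """An ordered set of candidate pairs with a pipeline-stage tag.

    ``stage`` is ``"initial"`` (C), ``"pruned"`` (C_p) or ``"inliers"``
    (post-RANSAC).  Pruned sets are one-to-one in both m and t.
    """

    pairs: list[Correspondence]
    stage: str = "initial"

    def __post_init__(self) -> None:
        seen = set()
        for p in self.pairs:
            key = (p.m, p.t)
            if key in seen:
                raise InputError(f"duplicate correspondence {key}")
            seen.add(key)
        if self.stage == "pruned":
            ms = [p.m for p in self.pairs]
            ts = [p.t for p in self.pairs]
            if len(set(ms)) != len(ms) or len(set(ts)) != len(ts):
                raise InputError(f"stage {self.stage!r} must be one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def m_indices(self) -> np.ndarray:
        return np.array([p.m for p in self.pairs], dtype=np.int64)

    @property
    def t_indices(self) -> np.ndarray:
        return np.array([p.t for p in self.pairs], dtype=np.int64)

    @property
    def descriptor_distances(self) -> np.ndarray:
        return np.array([p.descriptor_distance for p in self.pairs])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "m_index": self.m_indices,
                "t_index": self.t_indices,
                "eigen_score": [p.eigen_score for p in self.pairs],
                "descriptor_distance": self.descriptor_distances,
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Contours
# ---------------------------------------------------------------------------

@dataclass
class ContourSet:
    """The ridge line of one surface and each feature's distance to it.

    ``contour_vertices`` are the ordered ridge points snapped to mesh
    vertices; ``feature_to_contour`` holds, per feature, the geodesic
    distance (mm) to the nearest contour point, d_g(x, b_x).
    """

    contour_vertices: np.ndarray
    feature_to_contour: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.contour_vertices = np.atleast_1d(
            np.asarray(self.contour_vertices, dtype=np.int64)
        )
        if len(self.contour_vertices) == 0:
            raise InputError("contour must contain at least one point")


def snap_contour(points: np.ndarray, mesh: SurfaceMesh) -> ContourSet:
    """Snap an ordered 3D ridge polyline onto mesh vertices."""
    return ContourSet(map_to_surface(points, mesh))


def contour_distances(
    mesh: SurfaceMesh, contour: ContourSet, feature_vertices
) -> ContourSet:
    """Fill in d_g(x, b_x) for each feature by multi-source fast marching."""
    gf = geodesic_distances(mesh, contour.contour_vertices)
    feats = np.asarray(feature_vertices, dtype=np.int64)
    return ContourSet(contour.contour_vertices, gf.distances[feats])


# ---------------------------------------------------------------------------
# Affinity terms
# ---------------------------------------------------------------------------

@dataclass
class AffinityParams:
    """Bandwidths and mixing weight of the affinity matrix.

    sigma_d : dimensionless bandwidth of the rigidity kernel on the
        geodesic-ratio consistency (how much non-rigid deformation the
        pairwise term tolerates).  Default 0.3.
    sigma_b : same, for the contour term.  Default 0.3 (in practice kept
        equal to sigma_d: both express tolerated variation in geodesic
        ratios).
    alpha : weight of the rigidity term against the contour term, in [0, 1].
        alpha = 1 disables the contour constraint.  Default 0.6.
    eps : ratio guard (mm) keeping the consistency ratio finite when a
        geodesic distance vanishes.
    w_min : truncation level for off-diagonal affinities.  Entries below it
        are zeroed, so pairs departing far from isometric consistency give
        *no* support instead of weak support; without this the dense
        background of half-consistent wrong pairs on a smooth organ swamps
        the principal eigenvector.  The default exp(-2) zeroes support
        beyond two sigma of consistency departure.
    """

    sigma_d: float = 0.3
    sigma_b: float = 0.3
    alpha: float = 0.6
    eps: float = 1e-8
    w_min: float = float(np.exp(-2.0))

    def __post_init__(self) -> None:
        if self.sigma_d <= 0 or self.sigma_b <= 0:
            raise InputError("sigma_d and sigma_b must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise InputError("alpha must lie in [0, 1]")
        if self.eps <= 0:
            raise InputError("eps must be positive")
        if not 0.0 <= self.w_min < 1.0:
            raise InputError("w_min must lie in [0, 1)")


def geodesic_consistency(dg_m, dg_t, eps: float = 1e-8):
    """Ratio consistency of two geodesic distances, in [0, 1].

    ``min(dg_m / (dg_t + eps), dg_t / (dg_m + eps))`` — equal to 1 when the
    distances agree, symmetric, and invariant to a common rescaling of both
    distances (up to the eps guard).
    """
    dg_m = np.asarray(dg_m, dtype=np.float64)
    dg_t = np.asarray(dg_t, dtype=np.float64)
    if (dg_m < 0).any() or (dg_t < 0).any():
        raise InputError("geodesic distances must be non-negative")
    if eps <= 0:
        raise InputError("eps must be positive")
    c = np.minimum(dg_m / (dg_t + eps), dg_t / (dg_m + eps))
    return c if c.ndim else float(c)


def rigidity_kernel(c, sigma: float):
    """Gaussian kernel around perfect consistency: exp(-(c-1)^2 / 2 sigma^2).

    sigma sets how much departure from isometry (c < 1) is tolerated before a
    pair of candidate correspondences stops supporting each other.
    """
    if sigma <= 0:
        raise InputError("sigma must be positive")
    c = np.asarray(c, dtype=np.float64)
    g = np.exp(-((c - 1.0) ** 2) / (2.0 * sigma * sigma))
    return g if g.ndim else float(g)


def contour_term(dm_i, dt_i, dm_j, dt_j, sigma_b: float, eps: float = 1e-8):
    """Average contour-consistency of two candidate pairs.

    Each pair contributes the rigidity kernel of the consistency between its
    feature-to-ridge geodesic distance on M and on T; the two contributions
    are averaged so the term stays symmetric in (i, j).
    """
    gi = rigidity_kernel(geodesic_consistency(dm_i, dt_i, eps), sigma_b)
    gj = rigidity_kernel(geodesic_consistency(dm_j, dt_j, eps), sigma_b)
    return 0.5 * (gi + gj)


def descriptor_similarity(dist, sigma_f: float | None = None):
    """Gaussian similarity of a descriptor distance, in (0, 1].

    ``sigma_f`` defaults to the median of the supplied distances (the median
    heuristic); an all-zero batch gets a 1e-8 floor.
    """
    dist = np.asarray(dist, dtype=np.float64)
    if (dist < 0).any():
        raise InputError("descriptor distances must be non-negative")
    if sigma_f is None:
        sigma_f = float(np.median(dist))
    sigma_f = max(sigma_f, 1e-8)
    sim = np.exp(-(dist**2) / (2.0 * sigma_f * sigma_f))
    return sim if sim.ndim else float(sim)


# ---------------------------------------------------------------------------
# Affinity matrix
# ---------------------------------------------------------------------------

@dataclass
class AffinityMatrix:
    """Symmetric non-negative affinity over candidate correspondences."""

    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=np.float64)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise InputError("W must be square")
        self.W = W


def build_affinity(
    C: CorrespondenceSet,
    geodesics_m: np.ndarray,
    geodesics_t: np.ndarray,
    params: AffinityParams,
    contour_m: ContourSet | None = None,
    contour_t: ContourSet | None = None,
) -> AffinityMatrix:
    """Assemble the affinity matrix W over the candidate set C.

    Parameters
    ----------
    geodesics_m, geodesics_t : square arrays
        Pairwise geodesic distances (mm) between the *features* of M and of T
        (indexed like the feature sets the correspondences refer to).
    contour_m, contour_t : ContourSet, optional
        Feature-to-ridge distances on each surface; required unless
        ``params.alpha == 1`` (pure rigidity, no contour constraint).

    Notes
    -----
    The diagonal holds the unary descriptor similarities.  Candidates sharing
    a moving or a target feature are mutually exclusive assignments, so their
    entry is zeroed rather than allowed to reinforce each other.  Candidate
    pairs with an infinite geodesic on either surface (disconnected patches)
    contribute zero affinity.
    """
    n = len(C)
    if n == 0:
        raise InputError("empty correspondence set")
    mi = C.m_indices
    ti = C.t_indices
    if params.alpha < 1.0 and (contour_m is None or contour_t is None):
        raise MissingContourError(
            "the contour term (alpha < 1) needs ridge-line contours on both "
            "surfaces; supply contour_m and contour_t or set alpha = 1"
        )

    dm = np.asarray(geodesics_m)[np.ix_(mi, mi)]
    dt = np.asarray(geodesics_t)[np.ix_(ti, ti)]
    finite = np.isfinite(dm) & np.isfinite(dt)
    with np.errstate(invalid="ignore"):
        c = np.minimum(dm / (dt + params.eps), dt / (dm + params.eps))
    c = np.where(finite, c, 0.0)
    g = np.where(finite, rigidity_kernel(c, params.sigma_d), 0.0)

    if params.alpha < 1.0:
        bm = np.asarray(contour_m.feature_to_contour, dtype=np.float64)[mi]
        bt = np.asarray(contour_t.feature_to_contour, dtype=np.float64)[ti]
        ok = np.isfinite(bm) & np.isfinite(bt)
        cb = np.where(
            ok,
            np.minimum(bm / (bt + params.eps), bt / (bm + params.eps)),
            0.0,
        )
        gb_unary = np.where(ok, rigidity_kernel(cb, params.sigma_b), 0.0)
        gb = 0.5 * (gb_unary[:, None] + gb_unary[None, :])
        W = params.alpha * g + (1.0 - params.alpha) * gb
    else:
        W = g.copy()

    # conflicting assignments must not support each other
    conflict = (mi[:, None] == mi[None, :]) | (ti[:, None] == ti[None, :])
    W[conflict] = 0.0
    if params.w_min > 0:
        W[W < params.w_min] = 0.0

    sims = descriptor_similarity(C.descriptor_distances)
    sims = np.atleast_1d(sims)
    for k, p in enumerate(C.pairs):
        p.descriptor_similarity = float(sims[k])
    W[np.diag_indices(n)] = sims
    W = 0.5 * (W + W.T)  # exact symmetry against float asymmetries
    return AffinityMatrix(W)


# ---------------------------------------------------------------------------
# Spectral pruning
# ---------------------------------------------------------------------------

def principal_eigenvector(
    W: np.ndarray, tol: float = 1e-8, max_iter: int = 10_000
) -> np.ndarray:
    """Power iteration from the all-ones vector; non-negative for W >= 0."""
    n = W.shape[0]
    x = np.ones(n) / np.sqrt(n)
    for _ in range(max_iter):
        y = W @ x
        nrm = np.linalg.norm(y)
        if nrm < 1e-300:
            return np.zeros(n)
        y /= nrm
        if np.linalg.norm(y - x) < tol:
            return y
        x = y
    return x


def spectral_prune(
    W: AffinityMatrix | np.ndarray,
    C: CorrespondenceSet,
    rel_threshold: float = 1e-3,
    max_size: int | None = 25,
) -> CorrespondenceSet:
    """Extract the dominant one-to-one correspondence cluster from W.

    Candidates are considered greedily in order of decreasing principal-
    eigenvector component, skipping any candidate that conflicts (shares m
    or t) with an accepted one.  The greedy stops when the next component
    falls below ``rel_threshold`` times the largest, when accepting the next
    candidate would *decrease* the mean mutual affinity of the selection
    (the per-candidate assignment objective the eigenvector relaxes), or —
    as a safety cap — after ``max_size`` accepts.  The score-based stop is
    what keeps C_p at the scale of the mutually-consistent cluster so the
    RANSAC stage sees a mostly-inlier set.
    """
    Wm = W.W if isinstance(W, AffinityMatrix) else np.asarray(W, dtype=np.float64)
    if len(C) != Wm.shape[0]:
        raise InputError("W and C dimension mismatch")
    x = principal_eigenvector(Wm)
    x = np.abs(x)  # Perron vector is non-negative; guard the sign convention
    if x.max() <= 0:
        warnings.warn("all-zero affinity matrix: no correspondences survive",
                      stacklevel=2)
        return CorrespondenceSet([], stage="pruned")
    cutoff = rel_threshold * x.max()
    order = np.argsort(-x, kind="stable")
    used_m: set[int] = set()
    used_t: set[int] = set()
    selected: list[Correspondence] = []
    sel_idx: list[int] = []
    total = 0.0  # sum of W over the selected block
    for idx in order:
        if x[idx] <= cutoff:
            break
        if max_size is not None and len(selected) >= max_size:
            break
        p = C.pairs[idx]
        if p.m in used_m or p.t in used_t:
            continue
        gain = 2.0 * Wm[idx, sel_idx].sum() + Wm[idx, idx]
        r = len(selected)
        if r >= 1 and (total + gain) / (r + 1) < total / r:
            break  # mean mutual affinity would drop: cluster exhausted
        total += gain
        sel_idx.append(int(idx))
        used_m.add(p.m)
        used_t.add(p.t)
        selected.append(
            Correspondence(
                p.m, p.t, p.descriptor_distance, p.descriptor_similarity,
                eigen_score=float(x[idx]),
            )
        )
    return CorrespondenceSet(selected, stage="pruned")


def assignment_energy(
    C: CorrespondenceSet, geodesics_m: np.ndarray, geodesics_t: np.ndarray
) -> float:
    """Diagnostic quadratic-assignment energy of a correspondence set.

    Sum of descriptor distances plus the squared disagreement of all pairwise
    geodesic distances.  Never optimised directly — the affinity/spectral
    route above replaces it — but useful to compare candidate sets.
    """
    if len(C) == 0:
        return 0.0
    mi = C.m_indices
    ti = C.t_indices
    dm = np.asarray(geodesics_m)[np.ix_(mi, mi)]
    dt = np.asarray(geodesics_t)[np.ix_(ti, ti)]
    finite = np.isfinite(dm) & np.isfinite(dt)
    pair = np.where(finite, (dm - dt) ** 2, 0.0)
    return float(C.descriptor_distances.sum() + pair.sum())
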