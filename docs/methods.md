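# Methods

## Problem and model

The tool solves the coarse-alignment problem of laparoscopic liver
image-guidance: estimate, without any initial pose, the rigid transform
placing the preoperative CT liver mesh *M* onto an intraoperative surface
*T* that covers only a small fraction of the organ, is deformed
(pneumoperitoneum), and may be sparse and noisy (merged stereo patches).
The output is meant to be refined by an ICP-family fine-alignment method;
the accuracy bar is therefore "well inside the basin of convergence of
ICP" (a few mm at mesh resolution), not sub-millimetre.

Matching is a quadratic assignment: minimise descriptor dissimilarity
between paired features while preserving pairwise geodesic distances. It is
relaxed spectrally. Candidate pairs (each target feature with its k = 5
nearest moving descriptors) are the nodes of an association graph whose
affinity matrix W carries descriptor similarity on the diagonal and, off
the diagonal, a mixture (weight α = 0.6) of a geodesic-rigidity kernel and
a ridge-line (contour) consistency kernel. Both kernels are Gaussians in
the departure of a distance ratio from 1; the bandwidths σ_d = σ_b = 0.3
set how much non-isometric deformation is tolerated. The principal
eigenvector of W ranks candidates; greedy one-to-one selection extracts the
dominant mutually-consistent cluster C_p; RANSAC over C_p produces the
transform.

### Why the contour term exists

On near-flat liver regions the same constellation of features fits in many
places — pairwise geodesic consistency alone cannot tell a constellation
from its translated copy. The ridge line (the sharp anterior-inferior
liver edge, delineated by the operator on both surfaces) anchors each
feature through its geodesic distance to the ridge, removing the
translational ambiguity perpendicular to it. The package's test suite
reproduces this effect on an undulating flat patch: with the contour term
the number of displaced-duplicate matches among the top-ranked pairs drops
measurably. The effect requires candidates that contain roughly-correct
options at all; on a perfectly featureless plane (descriptors exactly
degenerate) no ranking can recover the correct cluster.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sigma_d`, `sigma_b` | 0.3 (dimensionless) | tolerance of the rigidity / contour kernels to deformation-induced geodesic-ratio changes |
| `alpha` | 0.6 | weight of the rigidity term against the contour term |
| `eps` | 1e-8 mm | ratio guard for vanishing geodesic distances |
| `w_min` | exp(−2) ≈ 0.135 | affinity truncation: pairs departing > 2σ from isometric consistency give no support |
| `n_features_moving` | 300 | preoperative feature count; bounds correspondence snapping noise by half the feature spacing (~5–6 mm at liver scale) |
| `n_features_target` | 100 | intraoperative feature count |
| `k` | 5 | descriptor nearest neighbours per target feature |
| `toldi_radius` | 10% of M's bbox diagonal (~23 mm) | TOLDI support radius; small enough to survive boundary truncation in 7%-area views |
| `toldi_L` | 20 | depth-image side; descriptor length 3·L² = 1200 |
| `prune_max_size` | 25 | safety cap on the greedy cluster selection |
| `ransac_iterations` | 1000 | hypothesis budget |
| `d_ransac` | 5 mm (rigid) / 10 mm (deformed) | consensus residual threshold and acceptance RMSE bound |
| `a_normals` | 60° | maximum angle between rotated moving normals and target normals |

All coordinates are millimetres throughout; geodesic distances are never
normalised internally (the consistency ratio is scale-free).

## Numerical choices

**Geodesics.** Fast marching on mesh vertices with a virtual-source
triangle update (reconstruct the unfolding-consistent source behind the
known edge; fall back to Dijkstra edge updates where the two-point update
is inadmissible), numba-compiled. Exact on flat triangulations, ~1.3%
error at icosphere antipodes. Vertices in components without a source get
infinity and are excluded from candidate support rather than raising
(merged stereo patches may be disconnected).

**TOLDI.** Local reference frame from the distance-weighted covariance of
the support (z = smallest eigenvector, signed against the support;
x = sign-disambiguated weighted projection sum), then three orthogonal
L×L nearest-depth images scaled to [0, 1]; empty pixels read 1. The
support cloud is the mesh surface super-sampled with a deterministic
barycentric grid per face, so the descriptor describes the surface rather
than its tessellation. Descriptors of the same point under a rigid motion
agree to ~1e-12.

**Spectral pruning.** Power iteration (tolerance 1e-8, all-ones start,
at most 10 000 iterations) gives the Perron eigenvector. The greedy
one-to-one selection stops when (a) the next component falls below 1e-3 of
the maximum, (b) accepting the next candidate would lower the mean mutual
affinity of the selection — the assignment objective restricted to
indicator vectors, which is what makes the stop parameter-free and exact on
planted clusters — or (c) the `prune_max_size` cap is hit. Candidates
sharing a moving or target feature have their mutual affinity zeroed
(conflicting assignments must not reinforce each other).

**RANSAC.** Minimal 3-point samples with collinearity rejection (second
singular value < 1e-6 of the first); the closed-form Kabsch/Umeyama fit
with reflection correction; consensus scoring (inlier count at `d_ransac`,
ties by inlier RMSE); acceptance requires a majority consensus, inlier RMSE
below `d_ransac`, and the normal test on the consensus pairs with normals
rotated by the candidate transform; the returned transform is re-fit by
least squares over its consensus set. Full-set RMSE scoring was measured
to be unusable here: with the raw candidate set (~90% outliers) it never
recovers the pose, whereas consensus scoring reproduces the expected
behaviour of all three benchmark variants. A dense closest-point RMSE
scorer is available separately (`registration.dense_rmse`) for diagnostics.

**Normal test direction.** The acceptance condition is
angle(R·n_m, n_t) ≤ a_normals. Writing it as dot(n_m, n_t) < cos(a)
(i.e. accepting pairs whose normals differ by *more* than the threshold)
contradicts the intent of discarding incompatible orientations and is
treated as a sign slip.

**Surface reconstruction.** Sparse targets are interpolated by an oriented
signed-distance field (local-PCA normals, orientation propagated along a
Euclidean minimum spanning tree; distance to the nearest point signed by
its normal) contoured with marching cubes at the configured voxel size
(default 2 mm), then trimmed: faces farther from the data than
max(tolerance, voxel, 1.5 × median point spacing) are removed, which opens
the extrapolated shell. Degenerate (collinear) clouds and clouds under 50
points are rejected. Geodesics measured on a reconstruction of a 30%
subsample agree with source-mesh geodesics to well under 10%.

**ICP refiner.** Plain trimmed point-to-point ICP; the trim fraction
defaults to one minus the target/moving area ratio, so only the overlap
region drives the fit — with a fixed trim a 23% partial target drags the
non-overlapping liver into the target and destroys a perfect coarse
alignment. The trimmed-RMSE trace is non-increasing by construction.

## Synthetic benchmark: what it emulates and what it does not

`bench.make_liver_mesh` maps an icosphere to a ~230 mm asymmetric wedge
with a crease (the ridge-line stand-in) and four fixed smooth bumps
(lobe bulges, fossa-like indentations). The bumps are part of the phantom
design: a real liver has no mirror symmetry, and a perfectly smooth
symmetric blob would make the matching problem ill-posed in a way real
anatomy is not.

Targets are generated per run by: geodesic-disk cropping to a prescribed
area fraction, seeded at a ridge vertex (laparoscopic views show the
anterior ridge; a crop without any ridge would leave the contour term
undefined); optional morphing toward an RBF-deformed shape (Gaussian
control-point displacements of 30 mm on the left lobe, linear vertex
morphing over 17 levels); a uniformly random rigid motion (axis uniform on
the sphere, angle up to 180°, translation up to one bounding-box
diagonal); optional Gaussian noise along vertex normals. The error metric
is the mean distance between the estimated placement of the cropped
vertices and their true (possibly deformed) target positions, via the
crop's index map.

What the benchmark does **not** emulate: stereo-reconstruction artefacts
(holes, seams between merged patches, anisotropic noise), segmentation
error in the delineated contours, and real pneumoperitoneum mechanics
(the RBF field is a smooth surrogate). Passing the synthetic studies
therefore shows robustness to partiality, pose, smooth deformation and
additive normal noise — not to clinical reconstruction pathology.

**Problem sizes.** The benchmark liver uses icosphere subdivision 4
(2562 vertices, mean edge ≈ 5.4 mm). Robustness cells are run at 50 seeded
runs (15 per deformation level in the sweep), a desk-scale replication of
the original 500-run protocol; run counts are configurable.

## Measured behaviour (recomputed by `scripts/acceptance.py` and the test suite)

At a 23% partial view the contour-constrained variant recovers the pose
within twice the mean edge length in ≥ 90% of runs (measured ~96%), and
all three variants register well, with the ordering
SM+R2 < SM+R1 < R in mean error. Under increasing deformation at a 23%
view SM+R2 degrades last. At a 7% view SM+R2 is the only variant that
still succeeds and dominates on mean error by a factor ≈ 2–3, but its
outcome distribution is bimodal (clean ~5 mm successes plus outright
failures whose magnitude scales with the random translation range), so its
error *standard deviation* is not reliably below that of the uniformly
failing baselines under these study conditions.

## Known limitations

- The spectral stage needs candidate sets that contain roughly-correct
  options; on surfaces whose descriptors are globally degenerate the
  method fails gracefully (fallback flag, large residual) but cannot
  recover the pose.
- Geodesic consistency assumes the liver does not change topology or
  self-contact during the early pneumoperitoneum phase.
- The contour is assumed delineated on both surfaces; contour segments
  missing from the intraoperative view shorten B^T and weaken (but do not
  invalidate) the contour term.
- Exact Levenberg–Marquardt ICP is out of scope; the provided refiner is
  plain trimmed point-to-point ICP.
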