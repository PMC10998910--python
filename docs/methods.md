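# Methods

`spinemorph` measures the 3D shape of dendritic spines reconstructed from
confocal microscopy and asks whether experimental conditions shift the
composition of a spine population. This note describes the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic test harness does and does not show.

## From volume to surface

Input stacks are assumed deconvolved. Segmentation artifacts in the form of
isolated zero-valued pixels are repaired per 2D slice: a pixel of value 0
whose eight in-plane neighbors are all positive is replaced by their mean, in
a single pass over the original values so replacements never cascade.

Segmentation uses morphological active contours without edges (Chan–Vese),
with smoothing weight µ = 1, inside/outside intensity weights λ₁ = 1 and
λ₂ = 9, and a fixed 100 iterations. The high outside weight reflects the
sparse bright foreground of fluorescence stacks. The algorithm's
initialization is not part of its published description; the default here is
the Otsu threshold of the slice-wise min–max-normalized stack (checkerboard
is available). Slice-wise normalization makes the result invariant to global
affine intensity rescaling.

The binary volume is converted to a triangle surface by marching cubes at
iso-level 0.5 with the physical voxel spacing applied, default
(0.24, 0.05, 0.05) µm for (z, y, x). The z value is smaller than the 0.35 µm
optical section because axial distances in oil-immersion confocal imaging
are compressed by spherical aberration; the correction is exposed as a
single configurable scale on the z spacing rather than a full optical model.
Foreground touching the grid border is padded with one background layer
(with a warning) so the extracted surface is closed.

A fixed point worth knowing: morphological ACWE applies one discrete
curvature-smoothing pass per iteration. Even from a perfect initialization
on a noiseless binary object this reassigns a thin shell of high-curvature
boundary voxels, and structures only one or two voxels thick (sub-voxel
spine necks, the z-compressed axis at 0.24 µm) can be smoothed away
entirely. On a spine resolved well above the voxel scale the noiseless
round trip is exact up to that boundary shell — every mismatched voxel lies
within one voxel of the true surface (Dice ≈ 0.989) — and a stack degraded
to SNR 5 with a 0.1 µm PSF still segments at Dice ≈ 0.91. Consequences for
real data: necks near the resolution limit will be thinned or lost, which
is a property of the smoothing term, not of this implementation.

## Mesh repair

Reconstructed or manually cut meshes pass through a fixed optimization
sequence: bounding box → target edge length = box diagonal / 100 ("normal"
detail; /50 at "reduced") → remove collinear (zero-area) triangles → remove
isolated vertices → remove self-intersecting faces → remove duplicated
faces → remove isolated vertices again → convex-hull probe → remove
triangles with an interior angle above 179° (strict, exact arccos) → remove
duplicated faces and vertices → integrity assessment. If integrity fails at
normal detail the sequence restarts once at reduced detail, then errors.
Integrity means edge-manifold (no edge in more than two faces) with a
computable positive-volume convex hull; watertightness is *not* required
because a cut spine is legitimately open at its base. Self-intersection
uses a segment-interval triangle–triangle test with a 1e-9 µm tolerance;
face pairs that merely touch, and coplanar pairs, are not flagged (exact
duplicates are caught by the duplicate-face step). Intersecting faces are
deleted, not remeshed. Repair is idempotent: a second pass removes nothing.

## The ten features

All features are measured from the *spine base center* S_bc, defined as the
mean coordinate of the vertices whose neighbor count equals the mesh-wide
minimum among referenced vertices — on a cut mesh these are boundary
vertices of the base hole. The gravity center G_c is the unweighted vertex
centroid.

| feature | definition | units |
|---|---|---|
| L  | mean of the ⌈0.05·N⌉ largest vertex–S_bc distances (ties at the cutoff included, 1e-9 relative tolerance) | µm |
| S  | Σ ½·\|AB×AC\| over faces | µm² |
| V  | \|Σ signed tetrahedra\| to apex G_c, after capping the base hole by fan triangulation to S_bc | µm³ |
| HV | convex hull volume of the vertices (Qhull) | µm³ |
| HR | (HV − V)/V | — |
| AD | mean vertex–S_bc distance | µm |
| CVD| population SD (divide by N) of distances / AD | — |
| OA | mean angle between the unit S_bc→G_c axis and unit S_bc→vertex vectors, dot products clamped to [−1,1], vertices coincident with S_bc skipped | rad |
| MC | total integral mean curvature (Σ ½·ℓ·θ over edges, convex positive) / closed surface area | 1/µm |
| GC | total angle defect (2πN − Σ corner angles) / closed surface area | 1/µm² |

Design points:

* **Capping.** V, MC and GC need a closed surface. The single base loop is
  fan-triangulated to S_bc; the cap faces traverse each boundary edge in
  the reverse of its owning face, which preserves consistent winding
  without a search (with a winding-repair fallback for inconsistently
  oriented input). Meshes with more than one boundary loop are rejected.
* **Curvature normalization.** Both curvatures are total integral measures
  divided by the total (capped) surface area; per-face division by tiny
  areas is numerically unstable. With the angle-defect form, Gauss–Bonnet
  makes GC·S = 4π exact (to float round-off) for every closed genus-0
  mesh, which the tests use as a tessellation-independent identity.
* **Equivariance.** Scaling a mesh by c multiplies L and AD by c, S by c²,
  V and HV by c³, divides MC by c and GC by c², and leaves HR, CVD and OA
  unchanged; all ten are invariant to rigid motions (verified at 1e-6
  relative tolerance).

## Feature selection, scaling and PCA

Spine features are strongly redundant. Pairs with Pearson |r| at or above
0.9 (the conventional "very strong" band) are pruned by visiting features
in a priority order — L, S, HR, CVD, OA, then the rest — and dropping any
feature that correlates at threshold with an already-kept one. On data with
the expected redundancy structure (AD ≈ L; V, HV ∝ S) this retains
{L, S, HR, CVD, OA}. Retained features are standardized to zero mean and
unit population SD, and PCA (default three components) is fitted once on
the pooled multi-condition dataset so all groups share one PC space. Each
component's sign is fixed by making its largest-magnitude loading positive,
which makes refits reproducible under row permutation.

## Clustering

K-Means (k-means++ initialization, 10 restarts, fixed seed) runs on the PC
scores. The cluster count is chosen by three scores over k = 3..11:
silhouette (argmax), Calinski–Harabasz (argmax), and the elbow of the
inertia curve, formalized as the point of maximum perpendicular distance to
the chord joining the first and last inertia values. The consensus is the
majority, with ties resolved in favor of the silhouette winner. Fitted
clusters are relabeled by ascending centroid PC1 so cluster identities are
deterministic across runs and row orderings.

Per-cluster group comparisons use cluster-membership proportions and KDE
shift maps: a Gaussian KDE (Scott bandwidth) of each group's members in
(PC1, PC2) on a 100×100 grid spanning the pooled range ± 3 bandwidths, each
grid renormalized to integrate to exactly 1; the shift vector is the
difference of the member centroids. A no-PCA clustering variant (scaled
features directly) is available as a robustness check via `--no-pca`.

## Group statistics

* **Density**: spines/µm per cell, summarized per group as mean ± SD with
  cell and mouse counts.
* **t-test**: classical pooled-variance two-sample Student t, two-sided.
* **Cohen's d**: mean difference over the (n−1)-weighted pooled SD. The
  interpretation bands follow the shifted convention in which |d| < 0.01 is
  "very small" and |d| < 0.20 "small"; the upper bands continue at 0.5
  (medium), 0.8 (large), 1.2 (very large), 2.0 (huge) as upper bounds.
* **Agresti–Caffo**: p̃ᵢ = (xᵢ+1)/(nᵢ+2), SE = √(Σ p̃ᵢ(1−p̃ᵢ)/(nᵢ+2)),
  two-sided normal p-value on z = Δp̃/SE, 95% CI = Δp̃ ± 1.96·SE. Applied
  per cluster without multiplicity correction by default (raw per-cluster
  p-values are the reporting convention here); Holm step-down is available.
  Under a simulated null (p = 0.2, n = 200 per group, 10 000 replicates)
  the empirical type-I error at α = 0.05 falls within [0.035, 0.065].
* **ICC**: one-way random-effects ICC(1) = (MSB − MSW)/(MSB + (k̄−1)·MSW)
  with the balanced-equivalent group size k̄ = (N − Σnᵢ²/N)/(a−1). Default
  grouping is mouse; cell-within-mouse is available. The estimator matches
  pingouin's ICC(1,1) to machine precision and recovers ICC = 0.75 ± 0.05
  from σ²_b/σ²_w = 3/1 simulations.

## Synthetic spines

The test harness builds spines as solids of revolution: a head that is the
portion of a sphere (radius `head_radius`) above the plane where its
cross-section equals `neck_radius`, meeting a cylindrical neck of length
`neck_length` on a shared ring; a stubby spine is the spherical cap sitting
directly on the open base. `tilt` bends the neck centerline into a circular
arc with that total turning angle — by Pappus' theorems the lateral surface
(2πr·ℓ) and volume (πr²·ℓ) of the bent tube stay exact, so every generated
mesh carries a closed-form surface and volume. Meshes are rings of m
azimuthal segments (12/24/48/96 for resolution levels 1–4) with near-square
quads split into triangles; they pass repair with zero removals, and their
measured surface/volume errors against the closed forms shrink
monotonically with resolution.

Populations draw per-spine parameters as base × exp(mouse + cell +
residual) with zero-mean Gaussian effects truncated at ±2 SD: mouse and
cell effects (SD 0.05 each on the log scale) are shared within the
hierarchy, and residuals are drawn independently per parameter (head 0.06,
neck 0.15, length 0.08 on the log scale; bend ±0.18 rad additive; stubby
base/head ratio 0.08). Independent per-parameter residuals were chosen over
a single shared size factor because real spine families are not perfectly
allometric, and a shared factor degenerates each family into a
one-dimensional cloud in feature space. Default hierarchy: 4 mice × 5
cells.

Five regimes echo the recurring cluster archetypes — small stubby, long
mushroom, large-surface mushroom, straight thin, and bent thin (the bend is
what produces a high hull ratio) — with base parameters chosen so the
regimes are well separated. Under these defaults, the full pipeline
(features → prune → scale → PCA → k-selection → K-Means) on 1000 spines
recovers k = 5 by all three scores and matches the generating families at
adjusted Rand index ≥ 0.99 across every generator seed tried (1–13 and the
fixture seed).

What the harness does *not* emulate: photon statistics and detector noise
models, dendrite context (spines are generated free-standing), spine-head
filopodia, anisotropic PSF shapes, or touching/overlapping spines. Passing
recovery tests show the pipeline is correct and well calibrated on shapes
whose ground truth is known; they do not show that five clusters — or any
particular k — is the right description of a given real dataset.

Imaging degradation voxelizes the base-capped solid by parity ray casting
along z (voxel-center-in-solid, grid offset half a voxel so flat faces
never align with voxel centers), blurs with a Gaussian PSF specified in µm
and converted per axis, and adds Gaussian noise clipped at zero, all under
one seed.

## Numerical conventions

* Degenerate triangles: area below 1e-12 × (target edge)²; obtuse removal
  is strictly > 179°.
* Tie handling for the 5% length subset: all distances within 1e-9
  (relative) of the cutoff are included, making L stable under rigid
  motions of symmetric meshes.
* KDE grids renormalize to unit mass over the finite grid.
* Zero-variance columns, coplanar vertex sets, empty masks, watertight
  inputs to base-dependent features, and multi-loop boundaries raise typed
  errors naming the offending quantity rather than returning NaN.

## Known limitations

* The base-center rule depends on the minimum neighbor count; on meshes cut
  with highly irregular boundaries the minimum-count subset can be a sparse
  subset of the boundary ring, shifting S_bc slightly off the hole
  centroid.
* Thin structures at or below ~2 voxels are not recoverable by the
  smoothing-regularized active contour (see above).
* The repair loop deletes offending faces rather than remeshing, so a mesh
  with extensive self-intersections can lose surface area.
* ICC here is the one-way variant; two-way models (rater-style designs) are
  out of scope.
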