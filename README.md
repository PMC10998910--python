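# spinemorph

3D morphometry of dendritic spines: from segmented confocal volumes to
triangulated spine surfaces, ten shape descriptors per spine, unsupervised
clustering of spine populations, and the group statistics needed to compare
experimental conditions. Built for neuroscientists quantifying structural
plasticity — e.g. how odor learning or sensory deprivation reshapes the
spines of adult-born olfactory-bulb granule cells — but applicable to any
spine imaging study with pre-cut spine meshes or deconvolved stacks.

## What it computes

**Reconstruction.** A deconvolved multi-page TIFF is repaired (isolated
zero-pixel artifacts replaced by their 8-neighbor mean), segmented with
morphological active contours without edges (µ = 1, λ₁ = 1, λ₂ = 9, 100
iterations), and surfaced by marching cubes with anisotropic voxel spacing
(default 0.24/0.05/0.05 µm). A mesh optimization loop removes degenerate,
duplicated, self-intersecting and near-collinear (>179°) triangles, with one
reduced-detail retry.

**Morphometry.** With S_bc the spine base center (mean of the
minimum-neighbor-count vertices at the dendrite cut) and G_c the vertex
centroid, each spine gets ten descriptors:

- Length `L` — mean of the 5% largest ‖vᵢ − S_bc‖ (µm)
- Surface `S = Σ ½|AB×AC|` (µm²) and Volume `V` (signed tetrahedra to G_c
  after capping the base, µm³)
- Hull Volume `HV` (Qhull) and Hull Ratio `HR = (HV − V)/V`
- Average Distance `AD` and its coefficient of variation
  `CVD = σ_pop(‖vᵢ − S_bc‖)/AD`
- Open Angle `OA = (1/N) Σ arccos(û · v̂ᵢ)` about the base→centroid axis
- Mean Curvature `MC` (edge-dihedral integral / S, 1/µm) and Mean Gaussian
  Curvature `GC` (angle defect / S, 1/µm²; `GC·S = 4π` on closed genus-0
  meshes)

**Population analysis.** Features with Pearson |r| ≥ 0.9 are pruned (keeping
the conventional ones: L, S, HR, CVD, OA), standardized, and reduced to
three principal components; K-Means clusters the PC scores with the cluster
count selected by silhouette, Calinski–Harabasz and elbow scores. Groups are
compared per feature (Student t, Cohen's d), per cluster (Agresti–Caffo
adjusted two-proportion z test), per mouse/cell (one-way ICC for
pseudo-replication), and visually via KDE cluster-shift maps in PC space.

**Synthetic spines.** A generator builds stubby / mushroom / thin spine
meshes with closed-form surface and volume, hierarchical mouse/cell effects,
and confocal-style degradation (voxelization, PSF blur, noise), so the whole
pipeline is testable without microscopy data.

## Worked example

```python
from spinemorph import SpineParams, make_spine_mesh, compute_features, agresti_caffo

mesh, truth = make_spine_mesh(SpineParams(
    "mushroom", head_radius=0.5, neck_radius=0.15,
    neck_length=1.2, tilt=0.4, mesh_resolution=3))
for name, value in compute_features(mesh).as_dict().items():
    print(f"{name:>3} = {value:.4f}")
```

```
  L = 2.1360     # µm: neck (1.2) plus head, reduced a little by the bend
  S = 4.1893     # µm²: analytic lateral surface is 4.2002
  V = 0.6039     # µm³: analytic solid volume is 0.6076
 HV = 0.8821
 HR = 0.4606     # hull exceeds the solid by 46% — the bent neck is concave
 AD = 0.9223
CVD = 0.6406     # high: head-and-neck geometry spreads base distances
 OA = 0.3533     # rad: narrow opening, typical of thin/mushroom spines
 MC = 2.3581
 GC = 2.9500     # GC·S_closed = 4π exactly (Gauss–Bonnet)
```

The mesh estimates sit within 0.7% of the generator's closed-form surface
and volume. The same statistics used for cluster comparisons are available
directly; for two groups with 239/1334 and 107/767 spines in a cluster:

```python
res = agresti_caffo(239, 1334, 107, 767)
print(f"z = {res.z:.3f}, p = {res.p_two_sided:.3f}")
# z = 2.398, p = 0.017
```

On the command line, `spinemorph simulate` writes a synthetic population,
`spinemorph measure` turns a directory of PLY/OBJ/STL spine meshes into a
feature CSV, `spinemorph cluster` prunes/scales/projects/clusters it, and
`spinemorph compare` produces the group-statistics report. `spinemorph run
--config pipeline.json` chains everything with a reproducible manifest.

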