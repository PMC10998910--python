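"""Synthetic spines with known ground truth.

Three classical shape families are emulated as solids of revolution:

* ``stubby``  — spherical cap (hemisphere) sitting directly on the open base;
* ``mushroom`` — sphere head fused to a cylindrical neck, open at the base;
* ``thin``    — long narrow neck with a small head.

The head is the portion of a sphere of radius ``head_radius`` above the plane
where its cross-section radius equals ``neck_radius``, so head and neck meet
exactly on a shared ring. ``tilt`` bends the neck centerline into a circular
arc with that total turning angle; Pappus' theorems keep the analytic lateral
surface (2π·r·ℓ) and volume (π·r²·ℓ) exact for the bent tube, which makes
bent thin spines concave (high hull ratio) without losing the ground truth.

Populations draw per-spine size parameters as
``base × exp(mouse + cell + residual)`` with independent zero-mean Gaussian
effects on the log scale (multiplicative, so radii stay positive), emulating
the hierarchical mouse/cell structure of an imaging study. Imaging
degradation (anisotropic voxelization, Gaussian PSF blur, additive noise) is
provided by :func:`voxelize_and_degrade`.

Coordinate convention: vertex columns are (z, y, x) in µm with the spine
growing along +z from the open base at z = 0, matching the axis order of
image stacks and marching-cubes meshes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .mesh import TriMesh
from .morphometry import cap_base, compute_features
from .segmentation import ImageStack, BinaryVolume

__all__ = [
    "SpineParams",
    "SpineRecord",
    "SyntheticPopulation",
    "FAMILY_BASE_PARAMS",
    "FIVE_REGIMES",
    "make_spine_mesh",
    "voxelize_and_degrade",
    "make_population",
]

_SEGMENTS_PER_LEVEL = {1: 12, 2: 24, 3: 48, 4: 96}


@dataclass(frozen=True)
class SpineParams:
    family: str
    head_radius: float
    neck_radius: float
    neck_length: float
    tilt: float = 0.0
    mesh_resolution: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("stubby", "mushroom", "thin"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.head_radius <= 0 or self.neck_radius <= 0:
            raise ValueError("radii must be > 0")
        if self.neck_length < 0:
            raise ValueError("neck_length must be >= 0")
        if self.family == "stubby" and self.neck_length != 0:
            raise ValueError("stubby spines have neck_length = 0")
        if self.head_radius < self.neck_radius:
            raise ValueError("head_radius must be >= neck_radius (head caps the neck)")
        if self.tilt > 0 and self.neck_length > 0:
            if self.neck_length / self.tilt <= self.neck_radius:
                raise ValueError("tilt too strong: bend radius smaller than neck radius")
        if self.mesh_resolution not in _SEGMENTS_PER_LEVEL:
            raise ValueError(f"mesh_resolution must be one of {sorted(_SEGMENTS_PER_LEVEL)}")


#: per-family base size parameters (µm); realistic for granule-cell spines
FAMILY_BASE_PARAMS = {
    "stubby": dict(family="stubby", head_radius=1.15, neck_radius=1.15,
                   neck_length=0.0, tilt=0.0),
    "mushroom": dict(family="mushroom", head_radius=0.55, neck_radius=0.18,
                     neck_length=2.4, tilt=0.2),
    "thin": dict(family="thin", head_radius=0.24, neck_radius=0.15,
                 neck_length=1.5, tilt=0.3),
}

#: five parameter regimes echoing the cluster archetypes (small stubby, long
#: mushroom, large-surface mushroom, straight thin, bent/complex thin)
FIVE_REGIMES = {
    "stubby_small": dict(family="stubby", head_radius=1.0, neck_radius=1.0,
                         neck_length=0.0, tilt=0.0),
    "mushroom_long": dict(family="mushroom", head_radius=0.6, neck_radius=0.18,
                          neck_length=2.8, tilt=0.35),
    "mushroom_large": dict(family="mushroom", head_radius=1.1, neck_radius=0.35,
                           neck_length=0.6, tilt=0.1),
    "thin_straight": dict(family="thin", head_radius=0.18, neck_radius=0.12,
                          neck_length=1.1, tilt=0.1),
    "thin_bent": dict(family="thin", head_radius=0.18, neck_radius=0.11,
                      neck_length=3.0, tilt=2.2),
}


# ---------------------------------------------------------------------------
# Mesh construction

def _ring_frames(neck_length: float, tilt: float, t: np.ndarray):
    """Centerline point, tangent and in-plane basis at arc parameters t."""
    if tilt == 0 or neck_length == 0:
        centers = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
        tangents = np.tile([1.0, 0.0, 0.0], (len(t), 1))
        e1 = np.tile([0.0, 0.0, 1.0], (len(t), 1))
    else:
        R = neck_length / tilt
        phi = t / R
        # arc in the z-x plane, starting at the origin pointing +z
        centers = np.column_stack([R * np.sin(phi), np.zeros_like(phi), R * (1 - np.cos(phi))])
        tangents = np.column_stack([np.cos(phi), np.zeros_like(phi), np.sin(phi)])
        e1 = np.column_stack([-np.sin(phi), np.zeros_like(phi), np.cos(phi)])
    e2 = np.tile([0.0, 1.0, 0.0], (len(t), 1))
    return centers, tangents, e1, e2


def make_spine_mesh(params: SpineParams) -> tuple[TriMesh, dict]:
    """Build a spine mesh and return it with the analytic {surface, volume}.

    The surface is the lateral surface of the idealized solid (the open base
    disk is not counted); the volume is the enclosed solid volume.
    """
    hr, nr, nl = params.head_radius, params.neck_radius, params.neck_length
    m = _SEGMENTS_PER_LEVEL[params.mesh_resolution]
    theta = np.arange(m) * (2 * math.pi / m)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    ds = 2 * math.pi * nr / m          # target ring spacing ~ azimuthal step
    n_neck = max(1, math.ceil(nl / ds)) if nl > 0 else 0
    t_vals = np.linspace(0.0, nl, n_neck + 1) if nl > 0 else np.array([0.0])
    centers, tangents, e1, e2 = _ring_frames(nl, params.tilt, t_vals)

    rings = []
    for c, b1, b2 in zip(centers, e1, e2):
        rings.append(c + nr * (cos_t[:, None] * b1 + sin_t[:, None] * b2))

    # head: sphere of radius hr, center offset along the end tangent
    off = math.sqrt(max(hr * hr - nr * nr, 0.0))
    head_center = centers[-1] + off * tangents[-1]
    alpha_max = math.acos(-off / hr)          # polar angle of the junction ring
    n_cap = max(2, math.ceil(alpha_max * m / (2 * math.pi)) + 1)
    alphas = np.linspace(alpha_max, 0.0, n_cap + 1)[1:-1]   # junction ring shared; pole added last
    T, b1, b2 = tangents[-1], e1[-1], e2[-1]
    for a in alphas:
        r_ring = hr * math.sin(a)
        c_ring = head_center + hr * math.cos(a) * T
        rings.append(c_ring + r_ring * (cos_t[:, None] * b1 + sin_t[:, None] * b2))

    verts = np.vstack(rings + [head_center + hr * T])
    pole = len(verts) - 1
    faces = []
    n_rings = len(rings)
    for i in range(n_rings - 1):
        a0, b0 = i * m, (i + 1) * m
        for j in range(m):
            jn = (j + 1) % m
            faces.append([a0 + j, a0 + jn, b0 + j])
            faces.append([b0 + j, a0 + jn, b0 + jn])
    last = (n_rings - 1) * m
    for j in range(m):
        faces.append([last + j, last + (j + 1) % m, pole])

    mesh = TriMesh(verts, np.asarray(faces, dtype=np.int64))
    cap_h = hr + off
    truth = {
        "surface": 2 * math.pi * nr * nl + 2 * math.pi * hr * cap_h,
        "volume": math.pi * nr * nr * nl + math.pi * cap_h * cap_h * (3 * hr - cap_h) / 3.0,
    }
    return mesh, truth


# ---------------------------------------------------------------------------
# Imaging degradation

def _voxelize_closed(mesh: TriMesh, spacing, pad: int) -> tuple[np.ndarray, np.ndarray]:
    """Parity-fill voxelization of a closed mesh; returns (mask, origin)."""
    sp = np.asarray(spacing, dtype=float)
    # half-voxel offset: keeps flat faces of the solid (the base plane sits
    # at z = 0 by construction) from aligning exactly with voxel centers,
    # which would bias the mask by a full boundary slab
    lo = mesh.vertices.min(axis=0) - (pad - 0.5) * sp
    hi = mesh.vertices.max(axis=0) + pad * sp
    shape = np.maximum(np.ceil((hi - lo) / sp).astype(int) + 1, 1)
    if np.any((mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)) < sp):
        raise ValueError("spacing larger than the mesh extent along an axis: empty mask")
    mask = np.zeros(shape, dtype=bool)

    tris = mesh.vertices[mesh.faces]          # (F, 3 verts, 3 coords=(z,y,x))
    # columns of voxel centers in the (y, x) plane; rays run along z
    yc = lo[1] + np.arange(shape[1]) * sp[1] + 1.2345e-7 * sp[1]
    xc = lo[2] + np.arange(shape[2]) * sp[2] + 2.3457e-7 * sp[2]
    zc0, dz = lo[0], sp[0]

    hits: dict[tuple[int, int], list[float]] = {}
    for tri in tris:
        p = tri[:, 1:]                         # (y, x) projections
        ylo, yhi = p[:, 0].min(), p[:, 0].max()
        xlo, xhi = p[:, 1].min(), p[:, 1].max()
        j0 = max(0, int(math.ceil((ylo - lo[1]) / sp[1])) - 1)
        j1 = min(shape[1] - 1, int((yhi - lo[1]) / sp[1]) + 1)
        k0 = max(0, int(math.ceil((xlo - lo[2]) / sp[2])) - 1)
        k1 = min(shape[2] - 1, int((xhi - lo[2]) / sp[2]) + 1)
        if j1 < j0 or k1 < k0:
            continue
        d = np.array([[p[1, 0] - p[0, 0], p[2, 0] - p[0, 0]],
                      [p[1, 1] - p[0, 1], p[2, 1] - p[0, 1]]])
        det = d[0, 0] * d[1, 1] - d[0, 1] * d[1, 0]
        if det == 0:
            continue                           # triangle vertical to the ray plane
        yy, xx = np.meshgrid(yc[j0:j1 + 1], xc[k0:k1 + 1], indexing="ij")
        ry, rx = yy - p[0, 0], xx - p[0, 1]
        u = (d[1, 1] * ry - d[0, 1] * rx) / det
        v = (-d[1, 0] * ry + d[0, 0] * rx) / det
        inside = (u >= 0) & (v >= 0) & (u + v <= 1)
        if not inside.any():
            continue
        z = tri[0, 0] + u * (tri[1, 0] - tri[0, 0]) + v * (tri[2, 0] - tri[0, 0])
        jj, kk = np.nonzero(inside)
        for a, b, zval in zip(jj + j0, kk + k0, z[inside]):
            hits.setdefault((int(a), int(b)), []).append(float(zval))

    for (j, k), zs in hits.items():
        zs = sorted(zs)
        if len(zs) % 2:
            zs = zs[:-1]
        for z_in, z_out in zip(zs[0::2], zs[1::2]):
            # tolerance keeps grid-aligned surfaces (e.g. the base plane)
            # from losing their boundary slice to float round-off
            i0 = int(math.ceil((z_in - zc0) / dz - 1e-9))
            i1 = int(math.floor((z_out - zc0) / dz + 1e-9))
            if i1 >= i0:
                mask[max(i0, 0):min(i1, shape[0] - 1) + 1, j, k] = True
    return mask, lo


def voxelize_and_degrade(mesh: TriMesh, spacing=(0.24, 0.05, 0.05),
                         psf_sigma: float = 0.0, noise_sd: float = 0.0,
                         seed: int = 0, pad: int = 3) -> tuple[ImageStack, BinaryVolume]:
    """Emulate confocal acquisition of a spine mesh.

    The (closed or base-capped) mesh is voxelized at the given anisotropic
    spacing, blurred with a Gaussian PSF of ``psf_sigma`` µm (converted to
    per-axis voxel sigmas) and corrupted with additive Gaussian noise of
    standard deviation ``noise_sd`` (foreground intensity is 1), clipped at 0.
    Returns the degraded stack and the ground-truth binary volume.
    """
    closed = cap_base(mesh)
    mask, _ = _voxelize_closed(closed, spacing, pad)
    if not mask.any():
        raise ValueError("voxelization produced an empty mask (spacing too coarse)")
    img = mask.astype(np.float64)
    if psf_sigma > 0:
        img = gaussian_filter(img, sigma=[psf_sigma / s for s in spacing])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return (ImageStack(voxels=img, spacing=tuple(spacing)),
            BinaryVolume(mask=mask, spacing=tuple(spacing)))


# ---------------------------------------------------------------------------
# Hierarchical populations

@dataclass
class SpineRecord:
    spine_id: str
    family: str
    regime: str
    mouse_id: str
    cell_id: str
    params: SpineParams
    mesh: TriMesh
    truth: dict


@dataclass
class SyntheticPopulation:
    spines: list[SpineRecord]
    seed: int
    between_mouse_sd: float
    between_cell_sd: float
    residual_sds: dict

    def __len__(self) -> int:
        return len(self.spines)

    def features_table(self) -> pd.DataFrame:
        """Compute the ten features of every spine, with hierarchy metadata."""
        rows = []
        for rec in self.spines:
            feats = compute_features(rec.mesh).as_dict()
            rows.append(dict(spine_id=rec.spine_id, family=rec.family,
                             regime=rec.regime, mouse_id=rec.mouse_id,
                             cell_id=rec.cell_id, **feats))
        return pd.DataFrame(rows)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for rec in self.spines:
            d = dict(spine_id=rec.spine_id, family=rec.family, regime=rec.regime,
                     mouse_id=rec.mouse_id, cell_id=rec.cell_id,
                     true_surface=rec.truth["surface"], true_volume=rec.truth["volume"])
            d.update({f"param_{k}": v for k, v in asdict(rec.params).items()})
            rows.append(d)
        return pd.DataFrame(rows)


#: per-parameter residual SDs (log scale; tilt in rad, additive): biological
#: variability touches head size, neck caliber, neck length and bend
#: independently — a single shared size factor would spread every family
#: along one axis, which neither real populations nor clusterable phantoms do
DEFAULT_RESIDUALS = {"head": 0.06, "neck": 0.15, "length": 0.08,
                     "tilt": 0.18, "stubby_ratio": 0.08}


def _tdraw(rng, sd: float) -> float:
    """Zero-mean normal draw truncated at ±2 SD (no extreme-outlier spines)."""
    if sd == 0:
        return 0.0
    return float(np.clip(rng.normal(0.0, sd), -2 * sd, 2 * sd))


def make_population(n_per_family: int = 100,
                    families: dict | None = None,
                    hierarchy: tuple[int, int] = (4, 5),
                    between_mouse_sd: float = 0.05,
                    between_cell_sd: float = 0.05,
                    residual_sds: dict | None = None,
                    mesh_resolution: int = 2,
                    seed: int = 0) -> SyntheticPopulation:
    """Generate a hierarchical spine population with known family labels.

    Size parameters of each spine are the family base values multiplied by
    ``exp(mouse + cell + residual)``: the mouse and cell effects are shared
    by all spines of the same mouse/cell, while the residual is drawn
    independently per size parameter (see :data:`DEFAULT_RESIDUALS`). All
    effects are truncated at ±2 SD. ``hierarchy`` is
    ``(n_mice, cells_per_mouse)``; spines are assigned to cells uniformly.
    """
    if n_per_family < 1:
        raise ValueError("n_per_family must be >= 1")
    res = dict(DEFAULT_RESIDUALS)
    if residual_sds:
        res.update(residual_sds)
    for name, sd in [("between_mouse_sd", between_mouse_sd),
                     ("between_cell_sd", between_cell_sd)] + list(res.items()):
        if sd < 0:
            raise ValueError(f"variance component {name} must be >= 0")
    families = families or FAMILY_BASE_PARAMS
    n_mice, cells_per_mouse = hierarchy
    rng = np.random.default_rng(seed)
    mouse_eff = np.clip(rng.normal(0.0, between_mouse_sd, size=n_mice),
                        -2 * between_mouse_sd, 2 * between_mouse_sd)
    cell_eff = np.clip(rng.normal(0.0, between_cell_sd, size=(n_mice, cells_per_mouse)),
                       -2 * between_cell_sd, 2 * between_cell_sd)

    spines: list[SpineRecord] = []
    idx = 0
    for regime, base in families.items():
        base = dict(base)
        for _ in range(n_per_family):
            mi = int(rng.integers(n_mice))
            ci = int(rng.integers(cells_per_mouse))
            shared = mouse_eff[mi] + cell_eff[mi, ci]
            head_radius = base["head_radius"] * math.exp(shared + _tdraw(rng, res["head"]))
            tilt = max(0.0, base.get("tilt", 0.0) + _tdraw(rng, res["tilt"]))
            if base["family"] == "stubby":
                # spherical cap: base rim continuously near-hemispheric
                tilt, neck_length = 0.0, 0.0
                neck_radius = head_radius * math.exp(-abs(_tdraw(rng, res["stubby_ratio"])))
            else:
                neck_length = base["neck_length"] * math.exp(shared + _tdraw(rng, res["length"]))
                neck_radius = min(base["neck_radius"] * math.exp(shared + _tdraw(rng, res["neck"])),
                                  head_radius)
                if tilt > 0 and neck_length / tilt <= neck_radius:
                    tilt = 0.9 * neck_length / neck_radius
            params = SpineParams(
                family=base["family"],
                head_radius=head_radius,
                neck_radius=neck_radius,
                neck_length=neck_length,
                tilt=tilt,
                mesh_resolution=mesh_resolution,
                seed=int(rng.integers(2**31 - 1)),
            )
            mesh, truth = make_spine_mesh(params)
            spines.append(SpineRecord(
                spine_id=f"sp{idx:05d}", family=base["family"], regime=regime,
                mouse_id=f"m{mi:02d}", cell_id=f"m{mi:02d}c{ci:02d}",
                params=params, mesh=mesh, truth=truth))
            idx += 1
    return SyntheticPopulation(spines=spines, seed=seed,
                               between_mouse_sd=between_mouse_sd,
                               between_cell_sd=between_cell_sd,
                               residual_sds=res)
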