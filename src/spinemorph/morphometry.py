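"""Spine base center and the ten morphometric features.

A spine mesh arrives cut from its dendrite, leaving one open boundary loop
(the base hole). Every distance-based feature is measured from the *spine
base center* ``S_bc``: the mean coordinate of the vertices whose neighbor
count equals the mesh-wide minimum (cut-boundary vertices are the least
connected ones). The features are:

========  =============================================================
L         mean of the 5% largest vertex-to-base distances (µm)
S         total triangle area (µm²)
V         enclosed volume after capping the base hole (µm³)
HV        convex-hull volume of the vertices (µm³)
HR        (HV − V)/V, shape complexity (dimensionless)
AD        mean vertex-to-base distance (µm)
CVD       population SD of vertex-to-base distances divided by AD
OA        mean angle between the base→centroid axis and each
          base→vertex vector (rad)
MC        total integral mean curvature / surface (1/µm)
GC        total angle defect / surface (1/µm²); Gauss–Bonnet makes
          GC·S = 4π for any closed genus-0 mesh
========  =============================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import trimesh as _trimesh
from scipy.spatial import ConvexHull, QhullError

from .mesh import TriMesh, boundary_edges, vertex_neighbor_counts

__all__ = [
    "SpineGeometry",
    "FeatureVector",
    "NoBaseError",
    "UndefinedFeatureError",
    "FEATURE_NAMES",
    "find_base_center",
    "boundary_loops",
    "cap_base",
    "compute_geometry",
    "feature_length",
    "feature_surface",
    "feature_volume",
    "feature_hull",
    "feature_distance_stats",
    "feature_open_angle",
    "feature_curvatures",
    "compute_features",
]

FEATURE_NAMES = ("L", "S", "V", "HV", "HR", "AD", "CVD", "OA", "MC", "GC")


class NoBaseError(ValueError):
    """Mesh has no open boundary, so the spine base center is undefined."""


class UndefinedFeatureError(ValueError):
    """A feature is undefined for this geometry (named in the message)."""


@dataclass(frozen=True)
class FeatureVector:
    L: float
    S: float
    V: float
    HV: float
    HR: float
    AD: float
    CVD: float
    OA: float
    MC: float
    GC: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SpineGeometry:
    """Per-mesh quantities shared by the feature formulas."""

    base_center: np.ndarray          # S_bc, µm
    gravity_center: np.ndarray       # G_c = unweighted vertex centroid, µm
    displacements: np.ndarray        # (N, 3) vertex − S_bc
    distances: np.ndarray            # (N,) |displacement|
    n_vertices: int
    n_faces: int
    n_longest: int                   # ceil(0.05·N), >= 1

    @classmethod
    def from_mesh(cls, mesh: TriMesh, base_center=None) -> "SpineGeometry":
        sbc = np.asarray(base_center, dtype=float) if base_center is not None \
            else find_base_center(mesh)
        disp = mesh.vertices - sbc
        dist = np.linalg.norm(disp, axis=1)
        n = mesh.n_vertices
        return cls(base_center=sbc,
                   gravity_center=mesh.vertices.mean(axis=0),
                   displacements=disp, distances=dist,
                   n_vertices=n, n_faces=mesh.n_faces,
                   n_longest=max(1, math.ceil(0.05 * n)))


# ---------------------------------------------------------------------------
# Base detection and capping

def find_base_center(mesh: TriMesh) -> np.ndarray:
    """Mean coordinate of the minimum-neighbor-count vertices.

    Raises :class:`NoBaseError` on a watertight mesh (no cut boundary).
    """
    if len(boundary_edges(mesh)) == 0:
        raise NoBaseError("mesh is closed: no dendrite-cut boundary to define a base")
    counts = vertex_neighbor_counts(mesh)
    referenced = counts > 0          # isolated vertices carry no geometry
    at_min = referenced & (counts == counts[referenced].min())
    return mesh.vertices[at_min].mean(axis=0)


def boundary_loops(mesh: TriMesh) -> list[np.ndarray]:
    """Connected open-boundary loops as arrays of vertex indices (unordered)."""
    be = boundary_edges(mesh)
    if len(be) == 0:
        return []
    parent = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in be:
        parent[find(int(a))] = find(int(b))
    groups: dict[int, list[int]] = {}
    for v in {int(x) for x in be.ravel()}:
        groups.setdefault(find(v), []).append(v)
    return [np.array(sorted(g)) for g in groups.values()]


def _directed_edges(faces: np.ndarray) -> np.ndarray:
    return np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])


def _is_consistently_wound(faces: np.ndarray) -> bool:
    """True when no directed edge appears twice (orientable, consistent winding)."""
    de = _directed_edges(faces)
    return len(np.unique(de, axis=0)) == len(de)


def cap_base(mesh: TriMesh, base_center=None) -> TriMesh:
    """Close the single base hole by fan triangulation to the base center.

    Returns a closed mesh with consistently oriented faces. Raises if the
    mesh has more than one boundary loop.
    """
    loops = boundary_loops(mesh)
    if len(loops) == 0:
        return mesh
    if len(loops) > 1:
        raise UndefinedFeatureError(
            f"volume: mesh has {len(loops)} boundary loops; expected a single base hole")
    sbc = np.asarray(base_center, dtype=float) if base_center is not None \
        else find_base_center(mesh)
    # directed boundary edges, in the direction their owning face uses them
    de = _directed_edges(mesh.faces)
    n = int(mesh.faces.max()) + 1
    keys = (np.minimum(de[:, 0], de[:, 1]).astype(np.int64) * n
            + np.maximum(de[:, 0], de[:, 1]))
    uk, inv, counts = np.unique(keys, return_inverse=True, return_counts=True)
    bd = de[counts[inv] == 1]
    verts = np.vstack([mesh.vertices, sbc[None, :]])
    apex = len(mesh.vertices)
    # reversed traversal keeps the cap winding consistent with the surface
    cap_faces = np.column_stack([bd[:, 1], bd[:, 0], np.full(len(bd), apex)])
    faces = np.vstack([mesh.faces, cap_faces])
    if not _is_consistently_wound(faces):
        tm = _trimesh.Trimesh(verts, faces, process=False)
        _trimesh.repair.fix_normals(tm)
        return TriMesh.from_trimesh(tm)
    return TriMesh(verts, faces)


def compute_geometry(mesh: TriMesh, base_center=None) -> SpineGeometry:
    return SpineGeometry.from_mesh(mesh, base_center=base_center)


# ---------------------------------------------------------------------------
# Features

def feature_length(geom: SpineGeometry) -> float:
    """Mean of the n = ceil(0.05·N) largest base distances (ties included).

    Ties at the cutoff are included with a 1e-9 relative tolerance so the
    subset is stable under rigid motions of the mesh (symmetric meshes have
    exactly tied distances that float arithmetic would otherwise split).
    """
    d = np.sort(geom.distances)[::-1]
    cutoff = d[geom.n_longest - 1]
    return float(d[d >= cutoff - 1e-9 * max(1.0, cutoff)].mean())


def feature_surface(mesh: TriMesh) -> float:
    a = mesh.vertices[mesh.faces[:, 0]]
    b = mesh.vertices[mesh.faces[:, 1]]
    c = mesh.vertices[mesh.faces[:, 2]]
    return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())


def feature_volume(mesh: TriMesh, geom: SpineGeometry | None = None,
                   closed: TriMesh | None = None) -> float:
    """Enclosed volume: |Σ signed tetrahedra| with apex at the gravity center.

    Open-base meshes are first capped by fan triangulation to the base
    center; the closed result is independent of the apex choice.
    """
    if closed is None:
        if geom is None and len(boundary_edges(mesh)) > 0:
            geom = compute_geometry(mesh)
        closed = cap_base(mesh, None if geom is None else geom.base_center)
    apex = closed.vertices.mean(axis=0) if geom is None else geom.gravity_center
    a = closed.vertices[closed.faces[:, 0]] - apex
    b = closed.vertices[closed.faces[:, 1]] - apex
    c = closed.vertices[closed.faces[:, 2]] - apex
    signed = np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0
    return float(abs(signed.sum()))


def feature_hull(mesh: TriMesh, volume: float | None = None) -> tuple[float, float]:
    """Convex hull volume HV and hull ratio HR = (HV − V)/V."""
    try:
        hv = float(ConvexHull(mesh.vertices).volume)
    except (QhullError, ValueError) as exc:
        raise UndefinedFeatureError(f"hull: convex hull not computable ({exc})") from exc
    v = feature_volume(mesh) if volume is None else volume
    if v <= 0:
        raise UndefinedFeatureError("hull ratio: enclosed volume is zero")
    return hv, (hv - v) / v


def feature_distance_stats(geom: SpineGeometry) -> tuple[float, float]:
    """AD (mean base distance) and CVD (population SD / AD)."""
    if geom.n_vertices < 2:
        raise UndefinedFeatureError("distance stats: need at least 2 vertices")
    ad = float(geom.distances.mean())
    if ad == 0:
        raise UndefinedFeatureError("CVD: all vertices coincide with the base center")
    return ad, float(geom.distances.std(ddof=0) / ad)


def feature_open_angle(geom: SpineGeometry) -> float:
    """Mean angle between the base→centroid axis and base→vertex vectors."""
    axis = geom.gravity_center - geom.base_center
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise UndefinedFeatureError("open angle: gravity center coincides with base center")
    axis = axis / norm
    keep = geom.distances > 1e-12
    if not np.any(keep):
        raise UndefinedFeatureError("open angle: no vertex distinct from the base center")
    unit = geom.displacements[keep] / geom.distances[keep, None]
    cosang = np.clip(unit @ axis, -1.0, 1.0)
    return float(np.arccos(cosang).mean())


def feature_curvatures(mesh: TriMesh, closed: TriMesh | None = None) -> tuple[float, float]:
    """Surface-normalized total mean curvature and Gaussian curvature.

    Both are evaluated on the closed (base-capped) surface: MC is the
    edge-dihedral integral mean curvature Σ ½·ℓ·θ (convex edges positive)
    divided by the closed surface area, and GC is the total angle defect
    (2π·N − Σ corner angles) divided by the same area.
    """
    if closed is None:
        closed = cap_base(mesh)
    verts, faces = closed.vertices, closed.faces

    # orient outward so convex edges come out positive
    a0 = verts[faces[:, 0]]
    b0 = verts[faces[:, 1]]
    c0 = verts[faces[:, 2]]
    if np.einsum("ij,ij->i", np.cross(a0, b0), c0).sum() < 0:
        faces = faces[:, ::-1]

    de = _directed_edges(faces)
    face_of = np.tile(np.arange(len(faces)), 3)
    nvk = int(faces.max()) + 1
    keys = (np.minimum(de[:, 0], de[:, 1]).astype(np.int64) * nvk
            + np.maximum(de[:, 0], de[:, 1]))
    order = np.argsort(keys, kind="stable")
    keys_s, face_s = keys[order], face_of[order]
    und_s = np.column_stack([keys_s // nvk, keys_s % nvk])
    runs = np.flatnonzero(keys_s[:-1] == keys_s[1:])
    if len(runs) > 1 and np.any(np.diff(runs) == 1):
        raise UndefinedFeatureError("curvature: mesh has non-manifold edges")
    i1, i2 = runs, runs + 1          # paired rows = interior edges

    tri = verts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    nn = np.linalg.norm(normals, axis=1)
    nn[nn == 0] = 1.0
    normals = normals / nn[:, None]

    f1, f2 = face_s[i1], face_s[i2]
    cosang = np.clip(np.einsum("ij,ij->i", normals[f1], normals[f2]), -1.0, 1.0)
    angles = np.arccos(cosang)
    lengths = np.linalg.norm(verts[und_s[i1, 0]] - verts[und_s[i1, 1]], axis=1)
    # convex edge: the opposite vertex of the second face lies below the
    # plane of the first
    opp2 = faces[f2].sum(axis=1) - und_s[i1].sum(axis=1)
    below = np.einsum("ij,ij->i", normals[f1], verts[opp2] - verts[und_s[i1, 0]])
    signs = np.where(below < 0, 1.0, -1.0)
    total_mc = float(0.5 * (lengths * angles * signs).sum())

    corner_angles = 0.0
    for p, q, r in ((tri[:, 0], tri[:, 1], tri[:, 2]),
                    (tri[:, 1], tri[:, 2], tri[:, 0]),
                    (tri[:, 2], tri[:, 0], tri[:, 1])):
        u, v = q - p, r - p
        nu = np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        nu[nu == 0] = 1.0
        corner_angles += np.arccos(np.clip(np.einsum("ij,ij->i", u, v) / nu, -1, 1)).sum()
    total_gc = float(2 * math.pi * len(verts) - corner_angles)

    area = feature_surface(closed)
    return total_mc / area, total_gc / area


def compute_features(mesh: TriMesh) -> FeatureVector:
    """All ten features of a repaired, base-detectable spine mesh."""
    geom = compute_geometry(mesh)
    closed = cap_base(mesh, geom.base_center)
    length = feature_length(geom)
    surface = feature_surface(mesh)
    volume = feature_volume(mesh, geom, closed=closed)
    hv, hr = feature_hull(mesh, volume)
    ad, cvd = feature_distance_stats(geom)
    oa = feature_open_angle(geom)
    mc, gc = feature_curvatures(mesh, closed=closed)
    return FeatureVector(L=length, S=surface, V=volume, HV=hv, HR=hr,
                         AD=ad, CVD=cvd, OA=oa, MC=mc, GC=gc)
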