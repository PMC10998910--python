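"""Triangle-mesh container, I/O and the mesh optimization/repair loop.

Spine surfaces are handled as plain indexed triangle meshes in micrometres.
Meshes arriving from marching cubes or from manual cutting tools routinely
carry degenerate (collinear) triangles, duplicated faces/vertices, isolated
vertices and occasional self-intersections; :func:`repair_mesh` runs a fixed
sequence of removal steps and re-checks mesh integrity, retrying once at a
reduced level of detail before giving up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.spatial import ConvexHull, QhullError, cKDTree

__all__ = [
    "TriMesh",
    "RepairReport",
    "IntegrityFlags",
    "MalformedMeshError",
    "RepairFailureError",
    "load_mesh",
    "save_mesh",
    "repair_mesh",
    "integrity",
    "vertex_neighbor_counts",
    "unique_edges",
    "boundary_edges",
]

_SUPPORTED_SUFFIXES = {".ply", ".obj", ".stl"}


class MalformedMeshError(ValueError):
    """Mesh violates the basic container invariants (N >= 4, f >= 1, valid indices)."""


class RepairFailureError(RuntimeError):
    """Mesh still fails the integrity assessment after the reduced-detail retry."""


@dataclass(frozen=True)
class TriMesh:
    """Indexed triangle mesh with vertices in µm.

    Parameters
    ----------
    vertices : (N, 3) float array
    faces : (f, 3) int array of vertex indices
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MalformedMeshError(f"vertices must be (N, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MalformedMeshError(f"faces must be (f, 3), got {f.shape}")
        if v.shape[0] < 4:
            raise MalformedMeshError(f"mesh needs at least 4 vertices, got {v.shape[0]}")
        if f.shape[0] < 1:
            raise MalformedMeshError("mesh needs at least 1 face")
        if f.min() < 0 or f.max() >= v.shape[0]:
            raise MalformedMeshError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: _trimesh.Trimesh) -> "TriMesh":
        return cls(np.asarray(tm.vertices, dtype=np.float64), np.asarray(tm.faces, dtype=np.int64))

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def box_diagonal(self) -> float:
        lo, hi = self.bounding_box()
        return float(np.linalg.norm(hi - lo))


@dataclass
class IntegrityFlags:
    is_watertight: bool
    is_manifold: bool
    hull_computable: bool


@dataclass
class RepairReport:
    removed_degenerate: int = 0
    removed_isolated_vertices: int = 0
    removed_self_intersections: int = 0
    removed_duplicate_faces: int = 0
    removed_obtuse: int = 0
    level_of_detail_used: str = "normal"
    passes: int = 1

    def total_removed(self) -> int:
        return (self.removed_degenerate + self.removed_isolated_vertices
                + self.removed_self_intersections + self.removed_duplicate_faces
                + self.removed_obtuse)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


# ---------------------------------------------------------------------------
# I/O

def load_mesh(path) -> TriMesh:
    """Load a PLY/OBJ/STL file, preserving the file's vertex order."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported mesh format {path.suffix!r}; expected PLY/OBJ/STL")
    if not path.exists():
        raise FileNotFoundError(path)
    tm = _trimesh.load(str(path), process=False, force="mesh")
    verts = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if verts.shape[0] < 4 or faces.shape[0] < 1:
        raise MalformedMeshError(
            f"{path.name}: {verts.shape[0]} vertices / {faces.shape[0]} faces is not a usable mesh")
    return TriMesh(verts, faces)


def save_mesh(mesh: TriMesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported mesh format {path.suffix!r}; expected PLY/OBJ/STL")
    mesh.to_trimesh().export(str(path))


# ---------------------------------------------------------------------------
# Topology helpers

def _edge_keys_and_n(faces: np.ndarray) -> tuple[np.ndarray, int]:
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    lo = np.minimum(e[:, 0], e[:, 1]).astype(np.int64)
    hi = np.maximum(e[:, 0], e[:, 1]).astype(np.int64)
    n = int(faces.max()) + 1
    return lo * n + hi, n


def unique_edges(mesh: TriMesh) -> np.ndarray:
    """Undirected unique edges as a (E, 2) sorted index array."""
    keys, n = _edge_keys_and_n(mesh.faces)
    uk = np.unique(keys)
    return np.column_stack([uk // n, uk % n])


def _edge_face_counts(faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keys, n = _edge_keys_and_n(faces)
    uk, counts = np.unique(keys, return_counts=True)
    return np.column_stack([uk // n, uk % n]), counts


def boundary_edges(mesh: TriMesh) -> np.ndarray:
    """Edges referenced by exactly one face (open boundary)."""
    edges, counts = _edge_face_counts(mesh.faces)
    return edges[counts == 1]


def vertex_neighbor_counts(mesh: TriMesh) -> np.ndarray:
    """Number of distinct vertices sharing an edge with each vertex."""
    edges = unique_edges(mesh)
    counts = np.zeros(mesh.n_vertices, dtype=np.int64)
    np.add.at(counts, edges[:, 0], 1)
    np.add.at(counts, edges[:, 1], 1)
    return counts


def integrity(mesh: TriMesh) -> IntegrityFlags:
    """Watertightness, edge-manifoldness and convex-hull feasibility."""
    _, counts = _edge_face_counts(mesh.faces)
    watertight = bool(np.all(counts == 2))
    manifold = bool(np.all(counts <= 2))
    try:
        hull = ConvexHull(mesh.vertices)
        hull_ok = hull.volume > 0
    except (QhullError, ValueError):
        hull_ok = False
    return IntegrityFlags(is_watertight=watertight, is_manifold=manifold, hull_computable=hull_ok)


# ---------------------------------------------------------------------------
# Repair steps

def _triangle_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def _max_angles_deg(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Largest interior angle of each triangle, in degrees."""
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    out = np.zeros(len(faces))
    for p, q, r in ((a, b, c), (b, c, a), (c, a, b)):
        u, v = q - p, r - p
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        denom = np.where(nu * nv == 0, 1.0, nu * nv)
        cosang = np.clip(np.einsum("ij,ij->i", u, v) / denom, -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
        ang = np.where(nu * nv == 0, 180.0, ang)
        out = np.maximum(out, ang)
    return out


def _drop_faces(faces: np.ndarray, keep: np.ndarray) -> np.ndarray:
    return faces[keep]


def _remove_isolated_vertices(verts, faces):
    used = np.zeros(len(verts), dtype=bool)
    used[faces.ravel()] = True
    n_removed = int((~used).sum())
    if n_removed == 0:
        return verts, faces, 0
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(used.sum())
    return verts[used], remap[faces], n_removed


def _duplicate_face_mask(faces: np.ndarray) -> np.ndarray:
    """True for faces that repeat an earlier face (same vertex set)."""
    key = np.sort(faces, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    keep = np.zeros(len(faces), dtype=bool)
    keep[first] = True
    return ~keep


def _merge_duplicate_vertices(verts, faces, tol=0.0):
    """Merge vertices with identical coordinates (exact by default)."""
    if tol > 0:
        key = np.round(verts / tol).astype(np.int64)
    else:
        key = verts
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)          # preserve first-appearance order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_faces = rank[inverse][faces]
    removed = len(verts) - len(first)
    return verts[np.sort(first)], new_faces, removed


def _tri_tri_intersect(t1: np.ndarray, t2: np.ndarray, eps: float) -> bool:
    """Triangle-triangle intersection with strict overlap.

    Pairs that merely touch (contact shorter than ``eps`` µm) and coplanar
    pairs are not flagged; coplanar duplicates are handled by the
    duplicate-face step instead.
    """
    def unit_normal(tri):
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        norm = np.linalg.norm(n)
        return None if norm == 0 else n / norm

    n1 = unit_normal(t1)
    n2 = unit_normal(t2)
    if n1 is None or n2 is None:
        return False
    dv2 = (t2 - t1[0]) @ n1          # signed distances (µm) of t2 to plane of t1
    if np.all(dv2 > eps) or np.all(dv2 < -eps):
        return False
    dv1 = (t1 - t2[0]) @ n2
    if np.all(dv1 > eps) or np.all(dv1 < -eps):
        return False
    if np.all(np.abs(dv1) <= eps) or np.all(np.abs(dv2) <= eps):
        return False                 # coplanar
    d = np.cross(n1, n2)
    dn = np.linalg.norm(d)
    if dn < 1e-12:
        return False                 # parallel, non-coplanar planes
    d = d / dn

    def interval(tri, dv):
        proj = tri @ d
        pos = dv > eps
        neg = dv < -eps
        pts = []
        for i in range(3):
            if not pos[i] and not neg[i]:
                pts.append(proj[i])                      # vertex on the line
            for j in range(i + 1, 3):
                if (pos[i] and neg[j]) or (neg[i] and pos[j]):
                    t = dv[i] / (dv[i] - dv[j])
                    pts.append(proj[i] + t * (proj[j] - proj[i]))
        if not pts:
            return None
        return min(pts), max(pts)

    i1 = interval(t1, dv1)
    i2 = interval(t2, dv2)
    if i1 is None or i2 is None:
        return False
    return (i1[1] > i2[0] + eps) and (i2[1] > i1[0] + eps)


def _self_intersecting_faces(verts: np.ndarray, faces: np.ndarray, eps: float) -> np.ndarray:
    """Indices of faces intersecting a non-adjacent face.

    Candidate pairs are pruned with a KD-tree on face centroids before the
    exact test; faces sharing a vertex are never flagged.
    """
    tris = verts[faces]
    centroids = tris.mean(axis=1)
    radii = np.linalg.norm(tris - centroids[:, None, :], axis=2).max(axis=1)
    rmax = radii.max() if len(radii) else 0.0
    if rmax == 0.0:
        return np.array([], dtype=np.int64)
    tree = cKDTree(centroids)
    pairs = tree.query_pairs(2.0 * rmax, output_type="ndarray")
    bad = set()
    for i, j in pairs:
        if set(faces[i]) & set(faces[j]):
            continue
        if np.linalg.norm(centroids[i] - centroids[j]) > radii[i] + radii[j]:
            continue
        if _tri_tri_intersect(tris[i], tris[j], eps):
            bad.add(int(i))
            bad.add(int(j))
    return np.array(sorted(bad), dtype=np.int64)


def _repair_pass(mesh: TriMesh, detail: str, diag_divisors, eps_intersect) -> tuple[TriMesh, RepairReport, bool]:
    report = RepairReport(level_of_detail_used=detail)
    verts, faces = mesh.vertices.copy(), mesh.faces.copy()

    # 1-2. bounding box -> target edge length from its diagonal
    diag = mesh.box_diagonal()
    target_edge = diag / diag_divisors[detail] if diag > 0 else 1.0
    area_tol = 1e-12 * max(target_edge, 1.0) ** 2

    # 3. degenerate (collinear) triangles
    keep = _triangle_areas(verts, faces) > area_tol
    report.removed_degenerate = int((~keep).sum())
    faces = _drop_faces(faces, keep)

    # 4. isolated vertices
    verts, faces, n = _remove_isolated_vertices(verts, faces)
    report.removed_isolated_vertices += n

    ok = faces.shape[0] >= 1 and verts.shape[0] >= 4
    if ok:
        # 5. self-intersecting faces
        bad = _self_intersecting_faces(verts, faces, eps_intersect)
        report.removed_self_intersections = len(bad)
        if len(bad):
            keep = np.ones(len(faces), dtype=bool)
            keep[bad] = False
            faces = _drop_faces(faces, keep)

        # 6. duplicated faces
        dup = _duplicate_face_mask(faces)
        report.removed_duplicate_faces += int(dup.sum())
        faces = _drop_faces(faces, ~dup)

        # 7. isolated vertices again
        verts, faces, n = _remove_isolated_vertices(verts, faces)
        report.removed_isolated_vertices += n

    ok = faces.shape[0] >= 1 and verts.shape[0] >= 4
    if ok:
        # 8. outer hull volume as an integrity probe
        try:
            hull_ok = ConvexHull(verts).volume > 0
        except (QhullError, ValueError):
            hull_ok = False

        # 9. obtuse triangles (interior angle > 179 degrees, strict)
        obtuse = _max_angles_deg(verts, faces) > 179.0
        report.removed_obtuse = int(obtuse.sum())
        faces = _drop_faces(faces, ~obtuse)

        # 10. duplicated faces and vertices
        dup = _duplicate_face_mask(faces)
        report.removed_duplicate_faces += int(dup.sum())
        faces = _drop_faces(faces, ~dup)
        verts, faces, n_dup_v = _merge_duplicate_vertices(verts, faces)
        # merging can collapse faces onto repeated indices; drop those
        if n_dup_v:
            degen = (faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2]) | (faces[:, 0] == faces[:, 2])
            report.removed_degenerate += int(degen.sum())
            faces = _drop_faces(faces, ~degen)
        verts, faces, n = _remove_isolated_vertices(verts, faces)
        report.removed_isolated_vertices += n
        ok = faces.shape[0] >= 1 and verts.shape[0] >= 4 and hull_ok

    # 11. integrity assessment
    if ok:
        out = TriMesh(verts, faces)
        flags = integrity(out)
        ok = flags.is_manifold and flags.hull_computable
        return out, report, ok
    return mesh, report, False


def repair_mesh(mesh: TriMesh, detail: str = "normal", *,
                diag_divisors: dict | None = None,
                eps_intersect: float = 1e-9) -> tuple[TriMesh, RepairReport]:
    """Run the mesh optimization loop and return the repaired mesh plus a report.

    Steps: bounding box -> target edge length from the box diagonal -> remove
    collinear triangles -> remove isolated vertices -> remove self-intersecting
    faces -> remove duplicated faces -> remove isolated vertices again -> outer
    hull probe -> remove triangles with an interior angle > 179 deg -> remove
    duplicated faces and vertices -> integrity assessment. If integrity fails
    at ``detail='normal'`` the loop restarts once at reduced detail.

    Integrity here means: edge-manifold (no edge shared by more than two faces)
    and a computable positive-volume convex hull. Watertightness is *not*
    required, because spine meshes are legitimately open at the dendrite cut.
    """
    if detail not in ("normal", "reduced"):
        raise ValueError("detail must be 'normal' or 'reduced'")
    divisors = {"normal": 100.0, "reduced": 50.0}
    if diag_divisors:
        divisors.update(diag_divisors)

    out, report, ok = _repair_pass(mesh, detail, divisors, eps_intersect)
    if ok:
        return out, report
    if detail == "normal":
        out, report2, ok = _repair_pass(mesh, "reduced", divisors, eps_intersect)
        report2.passes = 2
        if ok:
            return out, report2
    raise RepairFailureError("mesh failed the integrity assessment after the reduced-detail retry")
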