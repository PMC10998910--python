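"""The ten feature formulas against closed forms, oracles and invariances."""

import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation

from spinemorph.mesh import TriMesh, boundary_edges
from spinemorph.morphometry import (FeatureVector, NoBaseError, SpineGeometry,
                                    UndefinedFeatureError, cap_base,
                                    compute_features, compute_geometry,
                                    feature_curvatures, feature_distance_stats,
                                    feature_hull, feature_length,
                                    feature_open_angle, feature_surface,
                                    feature_volume, find_base_center)
from spinemorph.synthetic import SpineParams, make_spine_mesh


def _geom(distances, base=None, gravity=None):
    """Hand-built geometry for distance-only features."""
    d = np.asarray(distances, dtype=float)
    disp = np.column_stack([d, np.zeros_like(d), np.zeros_like(d)])
    return SpineGeometry(base_center=np.zeros(3) if base is None else base,
                         gravity_center=np.array([1.0, 0, 0]) if gravity is None else gravity,
                         displacements=disp, distances=d, n_vertices=len(d),
                         n_faces=1, n_longest=max(1, math.ceil(0.05 * len(d))))


class TestBaseCenter:
    def test_open_cylinder_base_at_origin(self, open_cylinder):
        sbc = find_base_center(open_cylinder)
        np.testing.assert_allclose(sbc[:2], [0, 0], atol=1e-6)

    def test_closed_mesh_has_no_base(self, icosphere_factory):
        with pytest.raises(NoBaseError):
            find_base_center(icosphere_factory())

    def test_matches_brute_force_minimum_neighbor_oracle(self, icosphere_factory):
        mesh = icosphere_factory(subdivisions=2)
        opened = TriMesh(mesh.vertices, mesh.faces[mesh.vertices[mesh.faces].mean(1)[:, 2] < 0.85])
        sbc = find_base_center(opened)
        # independent adjacency enumeration
        nbrs = [set() for _ in range(opened.n_vertices)]
        for a, b, c in opened.faces:
            nbrs[a] |= {b, c}
            nbrs[b] |= {a, c}
            nbrs[c] |= {a, b}
        counts = np.array([len(s) for s in nbrs])
        counts[counts == 0] = counts.max() + 1   # unreferenced vertices don't vote
        oracle = opened.vertices[counts == counts.min()].mean(axis=0)
        np.testing.assert_allclose(sbc, oracle, atol=1e-12)
        # the minimum-neighbor vertices sit on the cut boundary
        boundary_vertices = set(np.unique(boundary_edges(opened)))
        assert set(np.flatnonzero(counts == counts.min())) <= boundary_vertices

    def test_ring_cut_base_matches_boundary_centroid(self):
        # clean latitude cut: boundary ring symmetric about the axis
        mesh, _ = make_spine_mesh(SpineParams("mushroom", 0.5, 0.2, 1.0,
                                              mesh_resolution=2))
        sbc = find_base_center(mesh)
        ring = np.unique(boundary_edges(mesh))
        oracle = mesh.vertices[ring].mean(axis=0)
        assert np.linalg.norm(sbc - oracle) <= 0.02 * (np.linalg.norm(oracle) + 1.0)


class TestLength:
    def test_constant_distances(self):
        assert feature_length(_geom([2.0] * 40)) == pytest.approx(2.0)

    def test_five_percent_of_twenty_is_top_one(self):
        assert feature_length(_geom(np.arange(1.0, 21.0))) == pytest.approx(20.0)

    def test_matches_sort_and_average_oracle(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.1, 5.0, size=137)
        n = math.ceil(0.05 * len(d))
        oracle = np.sort(d)[::-1][:n].mean()
        assert feature_length(_geom(d)) == pytest.approx(oracle)


class TestSurfaceVolume:
    def test_unit_cube(self, unit_cube):
        assert feature_surface(unit_cube) == pytest.approx(6.0)
        assert feature_volume(unit_cube) == pytest.approx(1.0)

    def test_regular_tetrahedron(self, regular_tetrahedron):
        assert feature_surface(regular_tetrahedron) == pytest.approx(math.sqrt(3), rel=1e-9)
        assert feature_volume(regular_tetrahedron) == pytest.approx(1 / (6 * math.sqrt(2)), rel=1e-9)

    def test_icosphere_against_analytic_sphere(self, icosphere_factory):
        mesh = icosphere_factory(radius=1.0, subdivisions=3)
        assert feature_surface(mesh) == pytest.approx(4 * math.pi, rel=0.01)
        assert feature_volume(mesh) == pytest.approx(4 * math.pi / 3, rel=0.02)

    def test_open_base_capping(self, open_cylinder):
        # tube radius 1, length 2, cone cap height 0.5: V = pi*2 + pi/3*0.5
        v = feature_volume(open_cylinder)
        expected = math.pi * 2 + math.pi * 0.5 / 3
        assert v == pytest.approx(expected, rel=0.05)

    def test_multiple_boundary_loops_rejected(self, open_cylinder):
        # removing the apex fan opens a second hole
        faces = open_cylinder.faces[:-16]
        with pytest.raises(UndefinedFeatureError, match="boundary loops"):
            feature_volume(TriMesh(open_cylinder.vertices, faces))


class TestHull:
    def test_cube_is_its_own_hull(self, unit_cube):
        hv, hr = feature_hull(unit_cube)
        assert hv == pytest.approx(1.0)
        assert hr == pytest.approx(0.0, abs=1e-9)

    def test_icosphere_nearly_convex(self, icosphere_factory):
        _, hr = feature_hull(icosphere_factory(subdivisions=3))
        assert 0 <= hr <= 0.02

    def test_l_prism_matches_direct_hull(self):
        # two unit cubes sharing a face, one offset: a concave L solid
        import trimesh
        a = trimesh.creation.box(extents=(1, 1, 1))
        b = trimesh.creation.box(extents=(1, 1, 1))
        b.apply_translation([1.0, 0.5, 0.0])
        combo = trimesh.util.concatenate([a, b])
        mesh = TriMesh(np.asarray(combo.vertices), np.asarray(combo.faces))
        hv, hr = feature_hull(mesh, volume=2.0)
        oracle = ConvexHull(np.asarray(combo.vertices)).volume
        assert hv == pytest.approx(oracle, rel=1e-9)
        assert hr == pytest.approx((oracle - 2.0) / 2.0, rel=1e-9)

    def test_coplanar_vertices_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        mesh = TriMesh(verts, np.array([[0, 1, 2], [1, 3, 2]]))
        with pytest.raises(UndefinedFeatureError):
            feature_hull(mesh, volume=1.0)


class TestDistanceStats:
    def test_constant_distances(self):
        ad, cvd = feature_distance_stats(_geom([1.5] * 10))
        assert ad == pytest.approx(1.5)
        assert cvd == pytest.approx(0.0)

    def test_two_point_closed_form(self):
        ad, cvd = feature_distance_stats(_geom([1.0, 3.0] * 5))
        assert ad == pytest.approx(2.0)
        assert cvd == pytest.approx(0.5)

    def test_matches_numpy_oracle(self):
        rng = np.random.default_rng(11)
        d = rng.uniform(0.5, 4.0, 200)
        ad, cvd = feature_distance_stats(_geom(d))
        assert ad == pytest.approx(d.mean())
        assert cvd == pytest.approx(d.std() / d.mean())

    def test_degenerate_all_at_base(self):
        with pytest.raises(UndefinedFeatureError):
            feature_distance_stats(_geom([0.0, 0.0]))


class TestOpenAngle:
    def test_vertices_on_axis(self):
        g = _geom([1.0, 2.0, 3.0], gravity=np.array([1.0, 0, 0]))
        assert feature_open_angle(g) == pytest.approx(0.0, abs=1e-12)

    def test_vertices_perpendicular_to_axis(self):
        disp = np.array([[0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
        g = SpineGeometry(base_center=np.zeros(3), gravity_center=np.array([1.0, 0, 0]),
                          displacements=disp, distances=np.ones(4),
                          n_vertices=4, n_faces=1, n_longest=1)
        assert feature_open_angle(g) == pytest.approx(math.pi / 2)

    def test_matches_per_vertex_oracle(self, open_cylinder):
        geom = compute_geometry(open_cylinder)
        axis = geom.gravity_center - geom.base_center
        axis = axis / np.linalg.norm(axis)
        angles = []
        for disp, dist in zip(geom.displacements, geom.distances):
            if dist > 1e-12:
                angles.append(math.acos(float(np.clip(disp @ axis / dist, -1, 1))))
        assert feature_open_angle(geom) == pytest.approx(np.mean(angles))

    def test_degenerate_axis(self):
        g = _geom([1.0, 1.0], gravity=np.zeros(3))
        with pytest.raises(UndefinedFeatureError):
            feature_open_angle(g)


class TestCurvatures:
    @pytest.mark.parametrize("shape", ["cube", "tetra", "icosphere"])
    def test_gauss_bonnet_on_closed_genus_zero(self, shape, unit_cube,
                                               regular_tetrahedron, icosphere_factory):
        mesh = {"cube": unit_cube, "tetra": regular_tetrahedron,
                "icosphere": icosphere_factory(subdivisions=2)}[shape]
        mc, gc = feature_curvatures(mesh)
        assert gc * feature_surface(mesh) == pytest.approx(4 * math.pi, abs=1e-6)

    def test_sphere_curvatures_scale_as_inverse_radius(self, icosphere_factory):
        for r in (1.0, 2.0):
            mesh = icosphere_factory(radius=r, subdivisions=3)
            mc, gc = feature_curvatures(mesh)
            assert gc == pytest.approx(1 / r**2, rel=0.02)
            assert mc == pytest.approx(1 / r, rel=0.10)

    def test_nonmanifold_edge_rejected(self, regular_tetrahedron):
        verts = np.vstack([regular_tetrahedron.vertices, [[2.0, 2.0, 2.0]]])
        faces = np.vstack([regular_tetrahedron.faces, [[0, 1, 4]]])
        with pytest.raises(UndefinedFeatureError, match="manifold"):
            feature_curvatures(TriMesh(verts, faces))


class TestComputeFeatures:
    def test_mushroom_volume_matches_analytic_solid(self):
        params = SpineParams("mushroom", head_radius=0.5, neck_radius=0.1,
                             neck_length=1.5, mesh_resolution=3)
        mesh, truth = make_spine_mesh(params)
        fv = compute_features(mesh)
        assert fv.V == pytest.approx(truth["volume"], rel=0.05)
        assert fv.S == pytest.approx(truth["surface"], rel=0.05)

    def test_stubby_opens_wider_than_thin(self):
        stubby, _ = make_spine_mesh(SpineParams("stubby", 1.0, 1.0, 0.0))
        thin, _ = make_spine_mesh(SpineParams("thin", 0.2, 0.13, 1.5))
        assert compute_features(stubby).OA > compute_features(thin).OA

    def test_equidistant_mesh_has_zero_cvd_and_length_equals_ad(self):
        # hemisphere: every vertex lies on the sphere centered at the base center
        mesh, _ = make_spine_mesh(SpineParams("stubby", 1.0, 1.0, 0.0, mesh_resolution=3))
        fv = compute_features(mesh)
        assert fv.CVD == pytest.approx(0.0, abs=1e-9)
        assert fv.L == pytest.approx(fv.AD, rel=1e-9)

    def test_closed_mesh_propagates_no_base_error(self, icosphere_factory):
        with pytest.raises(NoBaseError):
            compute_features(icosphere_factory())


@pytest.fixture(scope="module")
def spine():
    mesh, _ = make_spine_mesh(SpineParams("mushroom", 0.5, 0.15, 1.2,
                                          tilt=0.4, mesh_resolution=2))
    return mesh


class TestInvariances:

    def test_scale_equivariance(self, spine):
        c = 2.7
        base = compute_features(spine)
        scaled = compute_features(TriMesh(spine.vertices * c, spine.faces))
        assert scaled.L == pytest.approx(c * base.L, rel=1e-6)
        assert scaled.AD == pytest.approx(c * base.AD, rel=1e-6)
        assert scaled.S == pytest.approx(c**2 * base.S, rel=1e-6)
        assert scaled.V == pytest.approx(c**3 * base.V, rel=1e-6)
        assert scaled.HV == pytest.approx(c**3 * base.HV, rel=1e-6)
        assert scaled.HR == pytest.approx(base.HR, rel=1e-6)
        assert scaled.CVD == pytest.approx(base.CVD, rel=1e-6)
        assert scaled.OA == pytest.approx(base.OA, rel=1e-6)
        assert scaled.MC == pytest.approx(base.MC / c, rel=1e-6)
        assert scaled.GC == pytest.approx(base.GC / c**2, rel=1e-6)

    def test_rigid_motion_invariance(self, spine):
        rot = Rotation.from_euler("zyx", [0.3, -1.1, 0.7]).as_matrix()
        moved = TriMesh(spine.vertices @ rot.T + np.array([5.0, -3.0, 2.0]), spine.faces)
        a = compute_features(spine).as_dict()
        b = compute_features(moved).as_dict()
        for name in a:
            assert b[name] == pytest.approx(a[name], rel=1e-6), name

    def test_hull_contains_solid(self, spine, unit_cube, open_cylinder):
        for mesh in (spine, unit_cube, open_cylinder):
            _, hr = feature_hull(mesh)
            assert hr >= -1e-9
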