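import math

import numpy as np
import pytest

import molprint as mp
from molprint import mesh_ops, voxel
from molprint.errors import (
    EmptyResultError,
    PrintabilityError,
    RepairError,
    UnitError,
    WallThicknessWarning,
)

import helpers

from conftest import TET_FACES, TET_VERTS


def two_tets_sharing_edge() -> mp.TriMesh:
    """Two closed tetrahedra whose only shared simplex is the edge 0-1."""
    v = np.vstack([TET_VERTS, [[1.0, 1.0, 1.0], [2.0, 1.0, 1.0]]])
    f = np.vstack([TET_FACES, [[0, 1, 4], [0, 4, 5], [0, 5, 1], [1, 5, 4]]])
    return mp.TriMesh(v, f)


class TestValidateMesh:
    def test_tetrahedron_is_watertight_genus_zero(self, tetrahedron):
        r = mp.validate_mesh(tetrahedron)
        assert r.watertight
        assert r.euler_characteristic == 2
        assert r.component_count == 1
        assert r.signed_volume == pytest.approx(1.0 / 6.0)

    def test_single_triangle_is_open(self):
        r = mp.validate_mesh(mp.TriMesh(TET_VERTS[:3], [[0, 1, 2]]))
        assert not r.watertight
        assert r.boundary_edge_count == 3
        assert r.euler_characteristic == 1

    def test_shared_edge_is_nonmanifold(self):
        r = mp.validate_mesh(two_tets_sharing_edge())
        assert r.nonmanifold_edge_count == 1
        assert not r.watertight

    def test_inverted_winding_gives_negative_volume(self, tetrahedron):
        r = mp.validate_mesh(tetrahedron.flipped())
        assert r.signed_volume == pytest.approx(-1.0 / 6.0)

    @pytest.mark.parametrize("fixture", ["tet", "triangle", "shared", "box", "sphere"])
    def test_agrees_with_brute_force_edge_oracle(self, fixture, box, icosphere):
        mesh = {
            "tet": mp.TriMesh(TET_VERTS, TET_FACES),
            "triangle": mp.TriMesh(TET_VERTS[:3], [[0, 1, 2]]),
            "shared": two_tets_sharing_edge(),
            "box": box(),
            "sphere": icosphere(1.0, subdivisions=1),
        }[fixture]
        r = mp.validate_mesh(mesh, check_self_intersections=False)
        oracle = helpers.edge_incidence_oracle(mesh.faces)
        assert r.boundary_edge_count == oracle["boundary"]
        assert r.nonmanifold_edge_count == oracle["nonmanifold"]
        V = len(np.unique(mesh.faces))
        assert r.euler_characteristic == V - oracle["edges"] + mesh.n_faces


class TestSelfIntersection:
    def test_interpenetrating_boxes(self, box):
        m = mp.concatenate([box((2, 2, 2)), box((2, 2, 2), center=(1.0, 0.7, 0.3))])
        assert mesh_ops.self_intersects(m)

    def test_disjoint_and_smooth_meshes_clean(self, box, icosphere):
        m = mp.concatenate([box((2, 2, 2)), box((2, 2, 2), center=(5, 0, 0))])
        assert not mesh_ops.self_intersects(m)
        assert not mesh_ops.self_intersects(icosphere(1.0))


class TestRepairMesh:
    def test_closes_missing_face(self, tetrahedron):
        open_tet = mp.TriMesh(tetrahedron.vertices, tetrahedron.faces[:3])
        fixed = mp.repair_mesh(open_tet)
        r = mp.validate_mesh(fixed)
        assert r.watertight
        assert abs(fixed.signed_volume()) == pytest.approx(1.0 / 6.0, abs=1e-9)

    def test_reorients_inverted_normals(self, tetrahedron):
        fixed = mp.repair_mesh(tetrahedron.flipped())
        assert fixed.signed_volume() == pytest.approx(1.0 / 6.0, abs=1e-9)

    def test_keep_largest_selects_big_component(self, box):
        both = mp.concatenate([box((2, 2, 2)), box((1, 1, 1), center=(5, 0, 0))])
        kept = mp.repair_mesh(both, policy="keep-largest")
        assert mp.validate_mesh(kept).component_count == 1
        assert kept.signed_volume() == pytest.approx(8.0, abs=1e-9)

    def test_idempotent(self, tetrahedron):
        once = mp.repair_mesh(mp.TriMesh(tetrahedron.vertices, tetrahedron.faces[:3]))
        twice = mp.repair_mesh(once)
        assert np.array_equal(once.faces, twice.faces)
        np.testing.assert_allclose(once.vertices, twice.vertices, atol=1e-12)
        assert twice.signed_volume() == pytest.approx(once.signed_volume(), abs=1e-9)

    def test_merges_duplicate_vertices(self, tetrahedron):
        # unweld into a triangle soup, then repair must restore closure
        soup_tri = tetrahedron.vertices[tetrahedron.faces].reshape(-1, 3)
        soup = mp.TriMesh(soup_tri, np.arange(12).reshape(-1, 3))
        assert mp.validate_mesh(soup).boundary_edge_count == 12
        fixed = mp.repair_mesh(soup)
        assert mp.validate_mesh(fixed).watertight
        assert fixed.signed_volume() == pytest.approx(1.0 / 6.0, abs=1e-9)

    def test_hole_cap_raises_with_residual_report(self, icosphere):
        sph = icosphere(5.0, subdivisions=3)
        # carve a large hole: drop every face whose centroid has z > 3
        cz = sph.vertices[sph.faces].mean(axis=1)[:, 2]
        holed = mp.TriMesh(sph.vertices, sph.faces[cz < 3.0])
        with pytest.raises(RepairError) as err:
            mp.repair_mesh(holed, hole_edge_cap=10)
        assert err.value.report.boundary_edge_count > 10


class TestHollowMesh:
    def test_spherical_shell_volume(self, icosphere):
        m = icosphere(10.0, subdivisions=4)
        shell = mp.hollow_mesh(m, wall=2.0)
        expected = 4.0 / 3.0 * math.pi * (10.0**3 - 8.0**3)
        assert shell.signed_volume() == pytest.approx(expected, rel=0.05)
        rep = mp.validate_mesh(shell, check_self_intersections=False)
        assert rep.watertight
        assert rep.component_count == 2  # nested outer + cavity

    def test_wall_exceeding_inradius_returns_solid(self, icosphere):
        m = icosphere(1.0, subdivisions=3)
        with pytest.warns(WallThicknessWarning):
            out = mp.hollow_mesh(m, wall=5.0)
        assert out is m

    def test_hollowing_removes_material(self, icosphere):
        m = icosphere(10.0, subdivisions=3)
        assert mp.hollow_mesh(m, wall=2.0).signed_volume() < m.signed_volume()

    def test_input_validation(self, tetrahedron):
        with pytest.raises(ValueError):
            mp.hollow_mesh(tetrahedron, wall=0.0)
        open_mesh = mp.TriMesh(tetrahedron.vertices, tetrahedron.faces[:3])
        with pytest.raises(PrintabilityError):
            mp.hollow_mesh(open_mesh, wall=0.1)


class TestBooleanSubtract:
    def test_disjoint_subtrahend_is_noop(self, box):
        cube = box((10, 10, 10))
        far = box((10, 10, 10), center=(100, 0, 0))
        assert mp.boolean_subtract(cube, far).signed_volume() == pytest.approx(1000.0, rel=0.02)

    def test_self_subtraction_is_empty(self, box):
        cube = box((10, 10, 10))
        with pytest.raises(EmptyResultError):
            mp.boolean_subtract(cube, cube)

    def test_cube_minus_through_cylinder(self, box, cylinder):
        cube = box((10, 10, 10))
        cyl = cylinder(radius=1.0, height=14.0, sections=96)
        expected = 1000.0 - 10.0 * math.pi
        v_default = mp.boolean_subtract(cube, cyl).signed_volume()
        assert v_default == pytest.approx(expected, rel=0.02)
        # fixed-seed point-membership Monte-Carlo oracle
        half = 5.0

        def inside(p):
            in_cube = np.all(np.abs(p) <= half, axis=1)
            in_cyl = p[:, 0] ** 2 + p[:, 1] ** 2 <= 1.0
            return in_cube & ~in_cyl

        mc = helpers.monte_carlo_volume(inside, [(-half,) * 3, (half,) * 3], 200_000, seed=42)
        assert v_default == pytest.approx(mc, rel=0.02)

    def test_refining_pitch_converges(self, box, cylinder):
        """Halving the voxel pitch moves the volume toward the analytic value
        (tested from a deliberately coarse pitch where discretization
        dominates the error)."""
        cube = box((10, 10, 10))
        cyl = cylinder(radius=1.0, height=14.0, sections=96)
        expected = 1000.0 - 10.0 * math.pi
        diag = float(np.linalg.norm(cube.extents))
        errs = [
            abs(mp.boolean_subtract(cube, cyl, pitch=diag / n).signed_volume() - expected)
            for n in (8, 16, 32, 64)
        ]
        assert errs[0] > errs[1] > errs[2] > errs[3]
        assert errs[3] < 0.01 * expected

    def test_inclusion_exclusion(self, box):
        cube = box((10, 10, 10))
        other = box((10, 10, 10), center=(5.0, 2.5, 0.0))
        pitch = voxel.default_pitch(cube)
        v_sub = mp.boolean_subtract(cube, other, pitch).signed_volume()
        v_int = mp.boolean_intersect(cube, other, pitch).signed_volume()
        assert v_sub + v_int == pytest.approx(cube.signed_volume(), rel=0.01)

    def test_unit_mismatch_and_open_operand(self, box, tetrahedron):
        cube = box((10, 10, 10))
        cube_mm = mp.TriMesh(cube.vertices, cube.faces, mp.MM)
        with pytest.raises(UnitError):
            mp.boolean_subtract(cube, cube_mm)
        open_mesh = mp.TriMesh(tetrahedron.vertices, tetrahedron.faces[:3])
        with pytest.raises(PrintabilityError):
            mp.boolean_subtract(cube, open_mesh)


class TestThinFeatureCheck:
    profile = mp.PrinterProfile("fdm", "FDM", (200, 200, 200), min_wall=1.0, min_rod_diameter=2.0)

    def test_thick_cube_clean(self, box):
        assert mp.thin_feature_check(box((20, 20, 20)), self.profile) == []

    def test_horizontal_thin_rod_flagged(self, cylinder):
        rod = cylinder(radius=0.4, height=10.0, sections=32)
        horizontal = rod.transformed(rotation=[[0, 0, 1], [0, 1, 0], [-1, 0, 0]])
        kinds = {w.kind for w in mp.thin_feature_check(horizontal, self.profile)}
        assert "thin_rod_perpendicular" in kinds

    def test_vertical_thin_rod_not_flagged_as_perpendicular(self, cylinder):
        rod = cylinder(radius=0.4, height=10.0, sections=32)
        kinds = {w.kind for w in mp.thin_feature_check(rod, self.profile)}
        assert "thin_rod_perpendicular" not in kinds

    def test_warning_invariant(self, cylinder):
        rod = cylinder(radius=0.4, height=10.0, sections=32)
        for w in mp.thin_feature_check(rod, self.profile):
            assert w.measured < w.limit
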