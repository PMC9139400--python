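import math

import numpy as np
import pytest

import molprint as mp
from molprint import representations
from molprint.errors import GeometryError, LevelSetError, OpenSurfaceWarning

import helpers


def sphere_volume(r: float) -> float:
    return 4.0 / 3.0 * math.pi * r**3


class TestGaussianDensity:
    def test_unity_on_vdw_sphere(self, single_atom):
        """An isolated atom's density is exactly 1 at distance r."""
        g = mp.gaussian_density(single_atom, mp.GaussianSurfaceParams(grid_spacing=0.1))
        # sample the analytic formula directly at a known grid point
        p = mp.GaussianSurfaceParams(blobbiness=-3.0)
        d = np.exp(p.blobbiness * ((1.7**2) / (1.7**2) - 1.0))
        assert d == pytest.approx(1.0, abs=1e-12)

    def test_center_value_is_exp_minus_b(self, single_atom):
        g = mp.gaussian_density(
            single_atom, mp.GaussianSurfaceParams(blobbiness=-3.0, grid_spacing=0.1)
        )
        assert g.values.max() == pytest.approx(math.exp(3.0), rel=1e-6)

    def test_density_is_additive(self):
        a1 = mp.AtomRecord(1, "C", "C", (0, 0, 0), radius=1.7)
        a2 = mp.AtomRecord(2, "C", "C", (0, 0, 0), radius=1.7)
        p = mp.GaussianSurfaceParams(grid_spacing=0.25)
        g1 = mp.gaussian_density(mp.MolecularStructure([a1]), p)
        g2 = mp.gaussian_density(mp.MolecularStructure([a1, a2]), p)
        np.testing.assert_allclose(g2.values, 2.0 * g1.values, rtol=1e-12)

    def test_small_padding_warns(self, single_atom):
        with pytest.warns(OpenSurfaceWarning):
            mp.gaussian_density(
                single_atom, mp.GaussianSurfaceParams(padding=0.5, grid_spacing=0.5)
            )


class TestIsosurface:
    def test_single_atom_reproduces_vdw_sphere(self, single_atom):
        p = mp.GaussianSurfaceParams(grid_spacing=0.25)
        mesh = mp.isosurface(mp.gaussian_density(single_atom, p), 1.0)
        assert mesh.signed_volume() == pytest.approx(sphere_volume(1.7), rel=0.03)
        assert mp.validate_mesh(mesh).watertight

    def test_isovalue_out_of_range(self, single_atom):
        g = mp.gaussian_density(single_atom, mp.GaussianSurfaceParams(grid_spacing=0.5))
        with pytest.raises(LevelSetError):
            mp.isosurface(g, 2.0 * float(g.values.max()))

    def test_refinement_converges_to_analytic_sphere(self, single_atom):
        errs = []
        for h in (0.5, 0.25, 0.125):
            mesh = mp.isosurface(
                mp.gaussian_density(single_atom, mp.GaussianSurfaceParams(grid_spacing=h)),
                1.0,
            )
            errs.append(abs(mesh.signed_volume() - sphere_volume(1.7)))
        assert errs[0] > errs[1] > errs[2]

    def test_rigid_motion_invariance(self, alpha_helix):
        """Enclosed surface volume is grid-placement independent to ~2%."""
        s = mp.assign_radii(alpha_helix)
        v0 = mp.gaussian_surface(s).signed_volume()
        rng = np.random.default_rng(11)
        # random rotation via QR of a Gaussian matrix
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        v1 = mp.gaussian_surface(
            s.transformed(rotation=q, translation=(1.3, -0.7, 2.1))
        ).signed_volume()
        assert v1 == pytest.approx(v0, rel=0.02)


class TestCpkMesh:
    def test_single_atom_volume(self, single_atom):
        m = mp.cpk_mesh(single_atom, spacing=0.2)
        assert m.signed_volume() == pytest.approx(sphere_volume(1.7), rel=0.05)
        assert mp.validate_mesh(m).component_count == 1

    @pytest.mark.parametrize("distance,expected", [(10.0, 2), (2.0, 1)])
    def test_component_count_follows_overlap(self, distance, expected):
        s = mp.MolecularStructure(
            [
                mp.AtomRecord(1, "C", "C", (0, 0, 0), radius=1.7),
                mp.AtomRecord(2, "C", "C", (distance, 0, 0), radius=1.7),
            ]
        )
        m = mp.cpk_mesh(s, spacing=0.2)
        assert mp.validate_mesh(m, check_self_intersections=False).component_count == expected

    def test_component_count_matches_graph_oracle(self):
        """Mesh components equal the sphere-overlap graph components.

        Configurations are drawn away from exact tangency: a pair whose gap
        is below the voxel size is topologically ambiguous at that grid
        resolution, so fixtures keep every |gap| above 2x the spacing.
        """
        spacing = 0.25
        rng = np.random.default_rng(5)
        done = 0
        while done < 3:
            n = int(rng.integers(3, 9))
            coords = rng.uniform(0, 8, size=(n, 3))
            radii = rng.uniform(1.0, 1.8, size=n)
            gaps = [
                abs(np.linalg.norm(coords[i] - coords[j]) - (radii[i] + radii[j]))
                for i in range(n)
                for j in range(i + 1, n)
            ]
            if min(gaps) < 2 * spacing:
                continue
            s = mp.MolecularStructure(
                [
                    mp.AtomRecord(i + 1, "C", "C", coords[i], radius=float(radii[i]))
                    for i in range(n)
                ]
            )
            expected = helpers.overlap_components_oracle(coords, radii)
            m = mp.cpk_mesh(s, spacing=spacing)
            got = mp.validate_mesh(m, check_self_intersections=False).component_count
            assert got == expected
            done += 1

    def test_vertex_colors_from_nearest_atom(self):
        s = mp.assign_colors(
            mp.assign_radii(
                mp.MolecularStructure(
                    [
                        mp.AtomRecord(1, "O", "O", (0, 0, 0)),
                        mp.AtomRecord(2, "N", "N", (10, 0, 0)),
                    ]
                )
            )
        )
        m = mp.cpk_mesh(s, spacing=0.25)
        left = m.vertex_colors[m.vertices[:, 0] < 5]
        right = m.vertex_colors[m.vertices[:, 0] > 5]
        assert np.allclose(left, (1, 0, 0)) and np.allclose(right, (0, 0, 1))


class TestBackboneTube:
    def test_capped_cylinder_volume(self):
        s = mp.MolecularStructure(
            [
                mp.AtomRecord(1, "CA", "C", (0, 0, 0)),
                mp.AtomRecord(2, "CA", "C", (5.0, 0, 0)),
                mp.AtomRecord(3, "CA", "C", (10.0, 0, 0)),
            ]
        )
        m = mp.backbone_tube(s, tube_radius=1.0)
        expected = math.pi * 10.0 + sphere_volume(1.0)
        assert m.signed_volume() == pytest.approx(expected, rel=0.05)
        assert mp.validate_mesh(m).watertight

    def test_helix_trace_single_watertight_component(self, alpha_helix):
        m = mp.backbone_tube(alpha_helix, tube_radius=1.5)
        rep = mp.validate_mesh(m, check_self_intersections=False)
        assert rep.watertight
        assert rep.component_count == 1

    def test_errors(self, alpha_helix, single_atom):
        with pytest.raises(ValueError):
            mp.backbone_tube(alpha_helix, tube_radius=0.0)
        with pytest.raises(GeometryError):
            mp.backbone_tube(single_atom, tube_radius=1.0)


class TestAddStruts:
    def straight_trace(self):
        return np.linspace([0, 0, 0], [20, 0, 0], 10)

    def hairpin_trace(self):
        down = [[x, 0.0, 0.0] for x in range(8)]
        turn = [[8.0, 1.5, 0.0]]
        back = [[x, 3.0, 0.0] for x in range(7, -1, -1)]
        return np.array(down + turn + back)

    def test_straight_trace_no_struts_identity(self):
        trace = self.straight_trace()
        tube = representations._sweep_tube(trace, 1.0)
        res = mp.add_struts(tube, trace, max_span=2.0, strut_radius=0.5)
        assert res.strut_count == 0
        assert res.mesh is tube  # bitwise identity, no voxel round-trip

    def test_hairpin_gains_struts_and_volume(self):
        trace = self.hairpin_trace()
        tube = representations._sweep_tube(trace, 0.8)
        res = mp.add_struts(tube, trace, max_span=3.5, strut_radius=0.5)
        # oracle: enumerate qualifying pairs by hand
        expected_pairs = sum(
            1
            for i in range(len(trace))
            for j in range(i + 3, len(trace))
            if np.linalg.norm(trace[j] - trace[i]) < 3.5
        )
        assert res.strut_count == expected_pairs >= 1
        assert res.mesh.signed_volume() > tube.signed_volume()
        assert mp.validate_mesh(res.mesh, check_self_intersections=False).watertight

    def test_strut_radius_must_be_positive(self):
        trace = self.straight_trace()
        tube = representations._sweep_tube(trace, 1.0)
        with pytest.raises(ValueError):
            mp.add_struts(tube, trace, max_span=2.0, strut_radius=0.0)
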