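"""Parametric geometry construction, opening extension and voxelization."""

import numpy as np
import pytest
import trimesh

from stentflow import geometry as geom


def sphere_geometry(radius=2.0, subdivisions=4):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return geom.SurfaceGeometry(np.asarray(m.vertices), np.asarray(m.faces), [], {})


class TestMakeSidewallAneurysm:
    def test_openings_and_analytic_plane(self):
        g = geom.make_sidewall_aneurysm(4, 8, 4, 40)
        assert [o.label for o in g.openings] == ["inlet", "outlet_0"]
        assert all(o.diameter == 4 for o in g.openings)
        plane = g.metadata["ostium_plane"]
        # neck plane is tangent to the parent lumen, normal pointing into the sac
        assert plane["point"][2] == pytest.approx(2.0)
        sac_center = g.metadata["sac_center"]
        assert (sac_center - plane["point"]) @ plane["normal"] > 0

    def test_sac_volume_matches_sphere_minus_neck_cap(self):
        g = geom.make_sidewall_aneurysm(4, 8, 4, 40)
        grid = geom.voxelize(g, 0.2)
        plane = g.metadata["ostium_plane"]
        mask = geom.sac_mask(grid, plane["point"], plane["normal"])
        vol = mask.sum() * 0.2**3
        Rs, rn = 4.0, 2.0
        cap_h = Rs - np.sqrt(Rs**2 - rn**2)
        expected = 4 / 3 * np.pi * Rs**3 - np.pi * cap_h**2 * (3 * Rs - cap_h) / 3
        assert vol == pytest.approx(expected, rel=0.05)

    @pytest.mark.parametrize(
        "args",
        [(4, 8, 9, 40), (0, 8, 4, 40), (4, -1, 2, 40), (4, 8, 4, 0), (4, 8, 0, 40)],
    )
    def test_invalid_parameters_raise(self, args):
        with pytest.raises(geom.GeometryError):
            geom.make_sidewall_aneurysm(*args)

    def test_degenerate_no_sac_is_a_straight_tube(self):
        g = geom.make_sidewall_aneurysm(4, 0, 0, 40)
        assert "ostium_plane" not in g.metadata
        grid = geom.voxelize(g, 0.3)
        expected = np.pi * 2**2 * 40
        assert grid.fluid_volume() == pytest.approx(expected, rel=0.05)

    def test_curved_parent(self):
        g = geom.make_sidewall_aneurysm(4, 8, 4, 30, bend_radius=25)
        grid = geom.voxelize(g, 0.3)
        # arc tube conserves volume vs straight tube of equal length + sac
        gs = geom.make_sidewall_aneurysm(4, 8, 4, 30)
        gs_grid = geom.voxelize(gs, 0.3)
        assert grid.fluid_volume() == pytest.approx(gs_grid.fluid_volume(), rel=0.03)


class TestExtendOpenings:
    def test_extension_length_is_diameters_times_local_diameter(self):
        g = geom.make_sidewall_aneurysm(4, 8, 4, 40)
        ge = geom.extend_openings(g, 5)
        assert ge.inlet.centroid[0] == pytest.approx(-20.0)
        assert ge.opening("outlet_0").centroid[0] == pytest.approx(60.0)

    def test_zero_diameters_is_identity(self):
        g = geom.make_sidewall_aneurysm(4, 8, 4, 40)
        assert geom.extend_openings(g, 0) is g

    def test_per_opening_extrusion_lengths(self):
        # mesh-surgery path: two caps with different diameters
        cyl = trimesh.creation.cylinder(radius=1.5, height=12.0, sections=32)
        g = geom.SurfaceGeometry(
            np.asarray(cyl.vertices), np.asarray(cyl.faces),
            [geom.Opening("inlet", [0, 0, -6], [0, 0, -1], 3.0),
             geom.Opening("outlet_0", [0, 0, 6], [0, 0, 1], 2.0)], {},
        )
        ge = geom.extend_openings(g, 5)
        assert ge.inlet.centroid[2] == pytest.approx(-6 - 15)
        assert ge.opening("outlet_0").centroid[2] == pytest.approx(6 + 10)
        m = trimesh.Trimesh(ge.vertices, ge.triangles, process=False)
        assert m.is_watertight

    def test_extension_preserves_cross_section_area(self):
        g = geom.make_sidewall_aneurysm(4, 0, 0, 20)
        ge = geom.extend_openings(g, 3)
        grid = geom.voxelize(ge, 0.3)
        lab = grid.labels
        areas = [(lab[i] > 0).sum() for i in range(2, lab.shape[0] - 2, 10)]
        assert max(areas) - min(areas) <= 0.06 * np.mean(areas)

    def test_unlabeled_opening_errors(self):
        g = geom.make_sidewall_aneurysm(4, 8, 4, 40)
        g2 = geom.SurfaceGeometry(g.vertices, g.triangles, [], g.metadata)
        with pytest.raises(geom.GeometryError):
            geom.extend_openings(g2, 5)


class TestVoxelize:
    def test_sphere_volume_oracle(self):
        g = sphere_geometry()
        grid = geom.voxelize(g, 0.1)
        assert grid.fluid_volume() == pytest.approx(4 / 3 * np.pi * 8, rel=0.05)

    def test_volume_converges_first_order(self):
        g = sphere_geometry()
        exact = 4 / 3 * np.pi * 8
        errs = [abs(geom.voxelize(g, h).fluid_volume() - exact) / exact
                for h in (0.4, 0.2, 0.1)]
        assert errs[0] > errs[1] > errs[2]

    def test_determinism(self):
        g = geom.make_sidewall_aneurysm(4, 0, 0, 20)
        a = geom.voxelize(g, 0.3)
        b = geom.voxelize(g, 0.3)
        assert np.array_equal(a.labels, b.labels)

    def test_invalid_spacing(self):
        g = sphere_geometry(subdivisions=2)
        with pytest.raises(geom.GeometryError):
            geom.voxelize(g, 0.0)

    def test_non_watertight_mesh_rejected(self):
        m = trimesh.creation.icosphere(subdivisions=2, radius=2.0)
        faces = np.asarray(m.faces)[:-5]  # puncture the surface
        g = geom.SurfaceGeometry(np.asarray(m.vertices), faces, [], {})
        with pytest.raises(geom.GeometryError):
            geom.voxelize(g, 0.2)

    def test_coarse_grid_breaking_connectivity_errors(self):
        g = geom.make_sidewall_aneurysm(2.0, 0, 0, 20)
        with pytest.raises(geom.GeometryError):
            geom.voxelize(g, 2.5)  # voxels wider than the lumen

    def test_caps_are_labeled_not_fluid(self):
        g = geom.make_sidewall_aneurysm(4, 0, 0, 20)
        grid = geom.voxelize(g, 0.3)
        assert (grid.labels == geom.INLET).sum() > 0
        assert (grid.labels == geom.OUTLET0).sum() > 0
        # exactly one voxel layer each
        inlet_x = np.unique(np.argwhere(grid.labels == geom.INLET)[:, 0])
        assert len(inlet_x) == 1


def test_stl_round_trip(tmp_path):
    g = geom.make_sidewall_aneurysm(4, 8, 4, 20)
    path = str(tmp_path / "case.stl")
    g.save(path)
    g2 = geom.SurfaceGeometry.load(path)
    assert [o.label for o in g2.openings] == ["inlet", "outlet_0"]
    assert np.allclose(g2.metadata["ostium_plane"]["point"], [10, 0, 2])
    assert len(g2.vertices) > 0


def test_voxel_grid_vtk_export(tmp_path):
    g = geom.make_sidewall_aneurysm(4, 0, 0, 10)
    grid = geom.voxelize(g, 0.4)
    out = tmp_path / "grid.vtk"
    grid.save_vtk(str(out))
    head = out.read_text().splitlines()
    assert head[0].startswith("# vtk DataFile")
    assert any(line.startswith("DIMENSIONS") for line in head[:8])
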