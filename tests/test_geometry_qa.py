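import numpy as np
import pytest

from phantomkit import _meshops, geometry_qa
from phantomkit.geometry_qa import (LayerSpec, OpenSurfaceError,
                                    check_watertight, detect_self_intersections,
                                    extract_shell_layer, region_mass,
                                    scale_to_target_mass, surface_volume,
                                    tetrahedralize, voxel_region_to_surface,
                                    voxelize)
from phantomkit.phantom_io import (PhantomValidationError, PolygonPhantom,
                                   Region, VoxelPhantom)

from conftest import two_region_phantom


class TestSurfaceVolume:
    def test_unit_cube(self, unit_cube_region):
        assert surface_volume(unit_cube_region) == pytest.approx(1.0)

    def test_icosphere_within_half_percent(self, sphere_region):
        vol = surface_volume(sphere_region)
        assert vol == pytest.approx(4 * np.pi / 3, rel=0.005)

    def test_refinement_converges(self):
        errs = []
        for sub in (2, 3, 4):
            v, f = _meshops.icosphere(sub, 1.0)
            errs.append(abs(_meshops.signed_volume(v, f) - 4 * np.pi / 3))
        assert errs[0] > errs[1] > errs[2]

    def test_inverted_cube_flagged(self, unit_cube_region):
        inv = Region(1, "inv", unit_cube_region.vertices,
                     unit_cube_region.faces[:, [0, 2, 1]])
        flag = {}
        assert surface_volume(inv, flag) == pytest.approx(1.0)
        assert flag["inverted_orientation"]

    def test_open_surface_errors(self, unit_cube_region):
        open_r = Region(1, "open", unit_cube_region.vertices,
                        unit_cube_region.faces[:-1])
        with pytest.raises(OpenSurfaceError, match="QA|report"):
            surface_volume(open_r)


class TestRegionMass:
    def test_water_cc(self):
        assert region_mass(1.0, 1.0) == pytest.approx(0.001)

    def test_inverse(self):
        assert region_mass(15000 / 1.05, 1.05) == pytest.approx(15.0)

    @pytest.mark.parametrize("vol,rho", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_non_positive_errors(self, vol, rho):
        with pytest.raises(ValueError):
            region_mass(vol, rho)


class TestWatertight:
    def test_intact_cube(self, unit_cube_region):
        e = check_watertight(unit_cube_region)
        assert e.closed and e.boundary_edge_count == 0

    def test_cube_missing_face(self, unit_cube_region):
        holed = Region(1, "holed", unit_cube_region.vertices,
                       unit_cube_region.faces[:-1])
        # oracle: enumerate edges of the dropped triangle that lose their
        # partner face
        dropped = unit_cube_region.faces[-1]
        all_edges = {}
        for tri in unit_cube_region.faces[:-1]:
            for k in range(3):
                e = tuple(sorted((tri[k], tri[(k + 1) % 3])))
                all_edges[e] = all_edges.get(e, 0) + 1
        expected_boundary = sum(1 for c in all_edges.values() if c == 1)
        entry = check_watertight(holed)
        assert not entry.closed
        assert entry.boundary_edge_count == expected_boundary == 3

    def test_shared_face_non_manifold(self):
        v1, f1 = _meshops.box_mesh((0, 0, 0), (1, 1, 1))
        v2, f2 = _meshops.box_mesh((1, 0, 0), (2, 1, 1))
        verts = np.vstack([v1, v2])
        faces = np.vstack([f1, f2 + 8])
        # weld coincident vertices on the shared x=1 plane
        key = {}
        remap = np.arange(len(verts))
        for i, p in enumerate(verts):
            k = tuple(np.round(p, 9))
            if k in key:
                remap[i] = key[k]
            else:
                key[k] = i
        welded = remap[faces]
        entry = check_watertight(Region(1, "weld", verts, welded))
        assert entry.non_manifold_edge_count > 0


class TestSelfIntersections:
    def test_clean_sphere(self, sphere_region):
        assert detect_self_intersections(sphere_region) == []

    def test_interpenetrating_tets(self):
        t1 = _meshops.regular_tetrahedron(1.0)
        t2 = t1 + np.array([0.15, 0.1, 0.05])
        faces = np.array([[0, 1, 2], [0, 3, 1], [1, 3, 2], [0, 2, 3]])
        verts = np.vstack([t1, t2])
        region = Region(1, "pair", verts, np.vstack([faces, faces + 4]))
        assert len(detect_self_intersections(region)) >= 1

    def test_disjoint_translated_copies(self):
        t1 = _meshops.regular_tetrahedron(1.0)
        t2 = t1 + np.array([5.0, 0.0, 0.0])
        faces = np.array([[0, 1, 2], [0, 3, 1], [1, 3, 2], [0, 2, 3]])
        region = Region(1, "pair", np.vstack([t1, t2]),
                        np.vstack([faces, faces + 4]))
        assert detect_self_intersections(region) == []


class TestScaling:
    def test_cube_root_law(self, sphere_region):
        # sphere of mass 1 g scaled to 8 g => factor 2
        rho = 0.001 / surface_volume(sphere_region) * 1000.0
        scaled, s = scale_to_target_mass(sphere_region, rho, 0.008)
        assert s == pytest.approx(2.0, rel=1e-9)

    def test_identity(self, unit_cube_region):
        m = region_mass(1.0, 1.05)
        scaled, s = scale_to_target_mass(unit_cube_region, 1.05, m)
        assert s == pytest.approx(1.0, rel=1e-12)
        np.testing.assert_allclose(scaled.vertices, unit_cube_region.vertices)

    def test_mass_recovered_to_1e9(self, sphere_region):
        scaled, _ = scale_to_target_mass(sphere_region, 1.05, 0.015)
        mass = region_mass(surface_volume(scaled), 1.05)
        assert mass == pytest.approx(0.015, rel=1e-9)

    def test_eyeball_target(self, sphere_region):
        # adult male eyeball target mass
        scaled, _ = scale_to_target_mass(sphere_region, 1.05, 0.015)
        assert region_mass(surface_volume(scaled), 1.05) == \
            pytest.approx(0.015, rel=1e-9)

    def test_errors(self, unit_cube_region):
        with pytest.raises(ValueError):
            scale_to_target_mass(unit_cube_region, 1.0, -1.0)
        open_r = Region(1, "open", unit_cube_region.vertices,
                        unit_cube_region.faces[:-1])
        with pytest.raises(OpenSurfaceError):
            scale_to_target_mass(open_r, 1.0, 1.0)


class TestShellLayer:
    def test_sphere_50_100_um(self):
        v, f = _meshops.icosphere(4, 10.0)
        layer = extract_shell_layer(Region(1, "s", v, f), LayerSpec(50, 100),
                                    check_intersections=False)
        vol = _meshops.signed_volume(layer.vertices, layer.faces)
        analytic = 4 * np.pi / 3 * (9.995 ** 3 - 9.990 ** 3)
        # mesh volume deficit of the subdiv-4 icosphere is ~0.2%
        assert vol == pytest.approx(analytic, rel=0.01)

    def test_equal_depths_error(self):
        with pytest.raises(ValueError):
            LayerSpec(100, 100)

    def test_full_thickness_skin_shell(self):
        # depth_lo = 0 yields the full-thickness skin (male default 1.28 mm)
        v, f = _meshops.icosphere(3, 10.0)
        layer = extract_shell_layer(Region(1, "skin", v, f),
                                    LayerSpec(0.0, 1280.0),
                                    check_intersections=False)
        entry = check_watertight(layer)
        assert entry.closed
        vol = _meshops.signed_volume(layer.vertices, layer.faces)
        assert vol > 0

    def test_layer_nesting_partition(self):
        v, f = _meshops.icosphere(3, 5.0)
        r = Region(1, "s", v, f)
        kw = dict(check_intersections=False)
        v01 = _meshops.signed_volume(*_layer_vf(r, 0, 500, **kw))
        v12 = _meshops.signed_volume(*_layer_vf(r, 500, 1000, **kw))
        v02 = _meshops.signed_volume(*_layer_vf(r, 0, 1000, **kw))
        assert v01 + v12 == pytest.approx(v02, rel=0.01)

    def test_collapse_error(self):
        v, f = _meshops.icosphere(2, 0.05)  # 500 um sphere
        with pytest.raises(PhantomValidationError):
            extract_shell_layer(Region(1, "s", v, f), LayerSpec(0, 600),
                                check_intersections=False)


def _layer_vf(region, lo, hi, **kw):
    layer = extract_shell_layer(region, LayerSpec(lo, hi), **kw)
    return layer.vertices, layer.faces


class TestVoxelToSurface:
    def test_single_voxel(self):
        ids = np.zeros((3, 3, 3), dtype=int)
        ids[1, 1, 1] = 4
        ph = VoxelPhantom(ids, pitch=(1.0, 2.0, 0.5))
        region = voxel_region_to_surface(ph, 4)
        vol = surface_volume(region)
        assert vol == pytest.approx(ph.voxel_volume_cm3, rel=0.01)

    def test_voxel_cube(self):
        ids = np.zeros((14, 14, 14), dtype=int)
        ids[2:12, 2:12, 2:12] = 1
        ph = VoxelPhantom(ids, pitch=(1.0, 1.0, 1.0))
        region = voxel_region_to_surface(ph, 1)
        assert surface_volume(region) == pytest.approx(
            1000 * ph.voxel_volume_cm3, rel=0.05)

    def test_absent_region(self):
        ph = VoxelPhantom(np.zeros((2, 2, 2), dtype=int))
        with pytest.raises(ValueError):
            voxel_region_to_surface(ph, 3)


class TestTetrahedralize:
    def test_unit_cube(self, unit_cube_region):
        tet = tetrahedralize(PolygonPhantom([unit_cube_region]))
        assert tet.region_volume(1) == pytest.approx(1.0, rel=0.005)

    def test_nested_regions(self):
        ph = two_region_phantom()
        tet = tetrahedralize(ph)
        inner_vol = surface_volume(ph.region(2))
        outer_vol = surface_volume(ph.region(1))
        assert tet.region_volume(2) == pytest.approx(inner_vol, rel=0.005)
        assert tet.region_volume(1) == pytest.approx(outer_vol - inner_vol,
                                                     rel=0.005)

    def test_open_surface_rejected(self, unit_cube_region):
        bad = Region(1, "open", unit_cube_region.vertices,
                     unit_cube_region.faces[:-1])
        with pytest.raises(OpenSurfaceError):
            tetrahedralize(PolygonPhantom([bad]))


class TestVoxelize:
    def test_sphere_volume(self):
        v, f = _meshops.icosphere(4, 5.0)
        ph = PolygonPhantom([Region(7, "s", v, f)])
        vox = voxelize(ph, 1.0)
        assert vox.region_volume(7) == pytest.approx(4 * np.pi / 3 * 125,
                                                     rel=0.02)

    def test_pitch_larger_than_phantom(self, unit_cube_region):
        vox = voxelize(PolygonPhantom([unit_cube_region]), 100.0)
        assert max(vox.dims) <= 3

    def test_non_positive_pitch(self, unit_cube_region):
        with pytest.raises(ValueError):
            voxelize(PolygonPhantom([unit_cube_region]), 0.0)

    def test_convergence_under_refinement(self):
        v, f = _meshops.icosphere(3, 4.0)
        ph = PolygonPhantom([Region(1, "s", v, f)])
        mesh_vol = surface_volume(ph.region(1))
        errs = [abs(voxelize(ph, p).region_volume(1) - mesh_vol)
                for p in (8.0, 4.0, 2.0)]
        assert errs[0] > errs[1] > errs[2]

    def test_innermost_wins(self):
        ph = two_region_phantom()
        vox = voxelize(ph, 2.0)
        assert (vox.organ_ids == 2).sum() > 0
        assert (vox.organ_ids == 1).sum() > 0

    def test_tet_phantom_input(self, unit_cube_region):
        tet = tetrahedralize(PolygonPhantom([unit_cube_region]))
        vox = voxelize(tet, 1.0)
        assert vox.region_volume(1) == pytest.approx(1.0, rel=0.1)


class TestQAPhantomReport:
    def test_clean_fixtures_pass(self):
        ph = two_region_phantom()
        report = geometry_qa.qa_phantom(ph)
        assert report.all_clean()

    def test_defect_fixtures_detected(self, unit_cube_region):
        holed = Region(1, "holed", unit_cube_region.vertices,
                       unit_cube_region.faces[:-1])
        report = geometry_qa.qa_phantom(PolygonPhantom([holed]))
        assert not report.all_clean()
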