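"""Synthetic vessel meshing, surface utilities, validity checks."""
import numpy as np
import pytest

from marrowmech import (SurfaceMesh, VesselSpec, find_self_intersections,
                        make_sinusoid_domain, make_tube_mesh, make_vessel_mesh,
                        offset_surface_inward, perturb_centerline,
                        smooth_surface)
from marrowmech.errors import InvalidSpecError, MeshError, SelfIntersectionError
from marrowmech.geometry import (TET_FACES, annulus_volume, cylinder_volume,
                                 tet_volumes)


def _boundary_faces(mesh):
    """All boundary triangles of a tet mesh as sorted vertex triples."""
    faces = mesh.tets[:, TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    return faces[counts[inv] == 1]


class TestVesselSpec:
    def test_study_defaults(self):
        artery = VesselSpec("artery")
        assert artery.length == 200.0
        assert artery.wall_thickness == pytest.approx(14.3)
        arteriole = VesselSpec("arteriole")
        assert arteriole.length == 200.0
        assert arteriole.wall_thickness == pytest.approx(5.0)
        sinusoid = VesselSpec("sinusoid")
        assert sinusoid.length == 300.0
        assert sinusoid.wall_thickness == 0.0

    def test_sinusoid_wall_forced_to_zero(self):
        assert VesselSpec("sinusoid", wall_thickness=7.0).wall_thickness == 0.0

    def test_unknown_class_rejected(self):
        with pytest.raises(InvalidSpecError):
            VesselSpec("vein")

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(InvalidSpecError):
            VesselSpec("artery", length=-1.0)
        with pytest.raises(InvalidSpecError):
            VesselSpec("artery", wall_thickness=0.0)
        with pytest.raises(InvalidSpecError):
            VesselSpec("sinusoid", marrow_outer_radius=10.0)


class TestTubeMesh:
    def test_regions_and_sets(self, artery_mesh):
        assert artery_mesh.regions == ("blood", "wall")
        for name in ("end_A", "end_B", "inner_lumen", "outer_wall",
                     "lumen_core"):
            assert name in artery_mesh.surface_sets
        assert "end_A" in artery_mesh.node_sets

    def test_all_tets_positive_volume(self, artery_mesh):
        assert tet_volumes(artery_mesh.nodes, artery_mesh.tets).min() > 0

    def test_wall_volume_converges_to_annulus(self):
        mesh = make_tube_mesh(VesselSpec("artery", edge_length=4.0))
        exact = annulus_volume(15.0, 29.3, 200.0)
        assert mesh.region_volume("wall") == pytest.approx(exact, rel=0.02)

    def test_blood_fills_lumen_except_core_channel(self):
        mesh = make_tube_mesh(VesselSpec("artery", edge_length=4.0))
        exact = cylinder_volume(15.0, 200.0)
        # the hollow axis channel removes ~1-2% of the lumen volume
        assert mesh.region_volume("blood") == pytest.approx(exact, rel=0.05)
        assert mesh.region_volume("blood") < exact

    def test_named_sets_tile_the_boundary(self, artery_mesh):
        boundary = _boundary_faces(artery_mesh)
        named = []
        for name, facets in artery_mesh.surface_sets.items():
            if name == "inner_lumen":  # interface set, not a boundary set
                continue
            named.append(artery_mesh.facet_triangles(name))
        named = np.concatenate(named)
        assert len(named) == len(boundary)
        a = set(map(tuple, np.sort(named, axis=1)))
        b = set(map(tuple, np.sort(boundary, axis=1)))
        assert a == b

    def test_outward_orientation_of_outer_wall(self, artery_mesh):
        areas, normals, centroids = artery_mesh.facet_areas_normals("outer_wall")
        radial = centroids[:, :2] / np.linalg.norm(centroids[:, :2], axis=1,
                                                   keepdims=True)
        assert np.all(np.einsum("ij,ij->i", normals[:, :2], radial) > 0)

    def test_outer_wall_area_matches_cylinder(self, artery_mesh):
        areas, _, _ = artery_mesh.facet_areas_normals("outer_wall")
        exact = 2.0 * np.pi * 29.3 * 200.0
        assert areas.sum() == pytest.approx(exact, rel=0.03)

    def test_node_count_formula(self):
        mesh = make_tube_mesh(VesselSpec("artery", resolution=(4, 12, 10)))
        assert len(mesh.nodes) == (10 + 1) * 12 * (4 + 1)

    def test_deterministic(self):
        m1 = make_tube_mesh(VesselSpec("arteriole", edge_length=6.0))
        m2 = make_tube_mesh(VesselSpec("arteriole", edge_length=6.0))
        assert np.array_equal(m1.nodes, m2.nodes)
        assert np.array_equal(m1.tets, m2.tets)


class TestSinusoidDomain:
    def test_regions(self, sinusoid_mesh):
        assert sinusoid_mesh.regions == ("blood", "marrow")
        assert "marrow_outer" in sinusoid_mesh.surface_sets

    def test_marrow_volume(self):
        mesh = make_sinusoid_domain(VesselSpec("sinusoid", edge_length=8.0))
        exact = annulus_volume(20.0, 100.0, 300.0)
        assert mesh.region_volume("marrow") == pytest.approx(exact, rel=0.03)

    def test_dispatch(self):
        mesh = make_vessel_mesh(VesselSpec("sinusoid", edge_length=15.0))
        assert "marrow" in mesh.regions


class TestPerturbCenterline:
    def test_amplitude_and_determinism(self, artery_mesh):
        wig = perturb_centerline(artery_mesh, amplitude=5.0, wavelength=50.0,
                                 seed=4)
        dx = wig.nodes - artery_mesh.nodes
        assert np.abs(dx[:, 2]).max() < 1e-12  # transverse only
        # the continuous field peaks at the amplitude; node stations sample
        # near (but not exactly at) the peak
        peak = np.abs(dx[:, :2]).max()
        assert 0.8 * 5.0 <= peak <= 5.0 + 1e-9
        wig2 = perturb_centerline(artery_mesh, amplitude=5.0, wavelength=50.0,
                                  seed=4)
        assert np.array_equal(wig.nodes, wig2.nodes)

    def test_connectivity_and_volumes_preserved(self, artery_mesh):
        wig = perturb_centerline(artery_mesh, amplitude=5.0, wavelength=50.0,
                                 seed=1)
        assert np.array_equal(wig.tets, artery_mesh.tets)
        assert tet_volumes(wig.nodes, wig.tets).min() > 0

    def test_spec_wiggle_equivalent(self):
        spec = VesselSpec("artery", edge_length=10.0,
                          centerline_wiggle_amplitude=4.0, seed=2)
        mesh = make_tube_mesh(spec)
        assert tet_volumes(mesh.nodes, mesh.tets).min() > 0


class TestSurfaceOps:
    def test_enclosed_volume_of_outer_surface(self, artery_mesh):
        surf = artery_mesh.surface("outer_wall")
        # closed by the end disks? outer_wall alone is an open tube: use
        # a generated closed surface instead
        assert surf.triangle_areas().sum() > 0

    def test_offset_inward_shrinks_cylinder(self, artery_mesh):
        surf = artery_mesh.surface("outer_wall")
        inner = offset_surface_inward(surf, 3.0)
        r_out = np.linalg.norm(surf.vertices[:, :2], axis=1).mean()
        r_in = np.linalg.norm(inner.vertices[:, :2], axis=1).mean()
        assert r_out - r_in == pytest.approx(3.0, rel=0.15)

    def test_offset_too_thick_raises(self, artery_mesh):
        surf = artery_mesh.surface("outer_wall")
        with pytest.raises(SelfIntersectionError):
            offset_surface_inward(surf, 40.0)

    def test_self_intersections_on_crossing_triangles(self):
        # two interpenetrating triangles
        verts = np.array([
            [0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [0.0, 2.0, 0.0],
            [0.5, 0.5, -1.0], [0.7, 0.5, 1.0], [0.5, 0.7, 1.0]])
        tris = np.array([[0, 1, 2], [3, 4, 5]])
        surf = SurfaceMesh(vertices=verts, triangles=tris, label="x")
        pairs = find_self_intersections(surf)
        assert len(pairs) >= 1

    def test_clean_surface_has_no_self_intersections(self, artery_mesh):
        surf = artery_mesh.surface("outer_wall")
        assert find_self_intersections(surf) == []

    def test_smoothing_reduces_roughness_keeps_volume(self):
        mesh = make_tube_mesh(VesselSpec("artery", edge_length=10.0,
                                         centerline_wiggle_amplitude=3.0,
                                         seed=3))
        surf = mesh.surface("outer_wall")
        smoothed = smooth_surface(surf, iterations=10)
        assert len(smoothed.triangles) == len(surf.triangles)
        # Taubin smoothing is volume-preserving to a few percent
        a0 = surf.triangle_areas().sum()
        a1 = smoothed.triangle_areas().sum()
        assert a1 == pytest.approx(a0, rel=0.05)

    def test_mesh_error_on_unknown_set(self, artery_mesh):
        with pytest.raises(MeshError):
            artery_mesh.facet_triangles("no_such_set")
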