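"""Quasi-static solver: pressure loads, Newton convergence, oracles."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from marrowmech import (LinearElastic, LoadCase, VesselSpec, FEModel,
                        apply_pressure_load, make_tube_mesh,
                        material_from_table, midspan_nodes, mmHg_to_MPa,
                        solve_static)
from marrowmech.errors import MeshError


class TestUnitConversion:
    def test_reference_pressures(self):
        assert mmHg_to_MPa(0.0) == 0.0
        assert mmHg_to_MPa(100.0) == pytest.approx(0.01333224)
        assert mmHg_to_MPa(50.0) == pytest.approx(0.00666612)


class TestPressureLoad:
    def test_closed_surface_zero_resultant(self, artery_mesh):
        # lateral wall + both end rings of the wall annulus close up with
        # the inner lumen; the full mesh boundary has zero net resultant
        total = np.zeros(3)
        area = 0.0
        for name in artery_mesh.surface_sets:
            if name == "inner_lumen":
                continue
            f = apply_pressure_load(artery_mesh, name, 1.0, follower=False)
            total += f.sum(axis=0)
            area += artery_mesh.facet_areas_normals(name)[0].sum()
        assert np.linalg.norm(total) < 1e-8 * area

    def test_resultant_on_end_disk(self, artery_mesh):
        p = 0.5
        f = apply_pressure_load(artery_mesh, "end_A", p, follower=False)
        area = artery_mesh.facet_areas_normals("end_A")[0].sum()
        # flat annular patch: |resultant| = p * A along the axis
        assert abs(f.sum(axis=0)[2]) == pytest.approx(p * area, rel=1e-12)
        assert np.linalg.norm(f.sum(axis=0)[:2]) < 1e-10 * p * area

    def test_inner_lumen_pushes_outward(self, artery_mesh):
        f = apply_pressure_load(artery_mesh, "inner_lumen", 1.0)
        tri = artery_mesh.facet_triangles("inner_lumen")
        nodes = np.unique(tri)
        radial = artery_mesh.nodes[nodes, :2]
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        fr = np.einsum("ij,ij->i", f[nodes, :2], radial)
        assert fr.sum() > 0  # net outward push on the wall

    def test_follower_rotation_equivariance(self, artery_mesh):
        R = Rotation.from_rotvec([0.4, -0.2, 0.7]).as_matrix()
        u_rot = artery_mesh.nodes @ R.T - artery_mesh.nodes
        f0 = apply_pressure_load(artery_mesh, "inner_lumen", 1.0,
                                 follower=True, u=None)
        f1 = apply_pressure_load(artery_mesh, "inner_lumen", 1.0,
                                 follower=True, u=u_rot)
        assert np.allclose(f1, f0 @ R.T, atol=1e-9 * np.abs(f0).max())

    def test_unknown_surface_rejected(self, artery_mesh):
        with pytest.raises(MeshError):
            apply_pressure_load(artery_mesh, "nope", 1.0)


class TestSolveStatic:
    def test_zero_load_zero_displacement(self, artery_mesh, artery_materials):
        state = solve_static(artery_mesh, artery_materials, LoadCase())
        assert state.converged
        assert state.n_iterations == 1
        assert np.all(state.u == 0.0)
        assert np.all(state.von_mises == 0.0)

    def test_converged_state_satisfies_tolerance(self, artery_static_50):
        assert artery_static_50.converged
        assert artery_static_50.residual_norm < 1e-6

    def test_stress_fields_symmetric(self, artery_static_50):
        c = artery_static_50.cauchy
        assert np.allclose(c, np.swapaxes(c, 1, 2), atol=1e-12)

    def test_lame_thick_wall_oracle(self):
        # linear-elastic cylinder a=15, b=29.3, E=1 MPa, nu=0.3, plane ends
        a, b, L, p = 15.0, 29.3, 8.0, 0.01
        mesh = make_tube_mesh(VesselSpec("artery", length=L, edge_length=3.0))
        mats = {"wall": LinearElastic(E=1.0, nu=0.3, density=1.1e-3),
                "blood": material_from_table("blood")}
        load = LoadCase(pulse_pressure=p / mmHg_to_MPa(1.0),
                        fixed={"end_A": "z", "end_B": "z"},
                        follower_pressure=False)
        state = solve_static(mesh, mats, load, n_steps=1,
                             drop_regions=("blood",))
        assert state.converged
        idx = np.where(mesh.region_mask("wall"))[0]
        cent = mesh.nodes[mesh.tets[idx]].mean(axis=1)
        r = np.linalg.norm(cent[:, :2], axis=1)
        ct, st = cent[:, 0] / r, cent[:, 1] / r
        sig = state.cauchy[idx]
        hoop = (st * st * sig[:, 0, 0] - 2 * st * ct * sig[:, 0, 1] +
                ct * ct * sig[:, 1, 1])
        k = p * a * a / (b * b - a * a)
        # ring-averaged radial profile vs the exact solution evaluated at
        # the mean centroid radius of each ring (linear tets carry
        # centroid stress, so compare at centroids, not at r=a)
        for lo, hi in [(a, a + 4), (a + 4, a + 9), (a + 9, b)]:
            sel = (r >= lo) & (r < hi)
            exact = (k * (1.0 + b * b / r[sel] ** 2)).mean()
            assert hoop[sel].mean() == pytest.approx(exact, rel=0.05)

    def test_patch_test_uniform_stress(self):
        # homogeneous stretch prescribed on every boundary node of a
        # single-material mesh must produce uniform interior stress
        mesh = make_tube_mesh(VesselSpec("arteriole", length=30.0,
                                         edge_length=6.0))
        mat = LinearElastic(E=1.0, nu=0.3, density=1e-3)
        mats = {"wall": mat, "blood": mat}
        grad = np.array([[1e-3, 2e-4, 0.0],
                         [0.0, -5e-4, 1e-4],
                         [3e-4, 0.0, 8e-4]])
        boundary_nodes = np.unique(np.concatenate(
            [mesh.facet_triangles(s).ravel() for s in mesh.surface_sets
             if s != "inner_lumen"]))
        u_b = mesh.nodes[boundary_nodes] @ grad.T
        dofs = (3 * boundary_nodes[:, None] + np.arange(3)).ravel()
        state = solve_static(mesh, mats, LoadCase(fixed={}), tol=1e-12,
                             n_steps=1,
                             extra_prescribed=(dofs, u_b.ravel()))
        assert state.converged
        spread = np.abs(state.cauchy - state.cauchy.mean(axis=0)).max()
        assert spread <= 1e-8 * np.abs(state.cauchy).max()

    def test_pressure_linearity_in_linear_regime(self):
        mesh = make_tube_mesh(VesselSpec("artery", length=40.0,
                                         edge_length=8.0))
        mats = {"wall": LinearElastic(E=1.0, nu=0.3, density=1.1e-3),
                "blood": material_from_table("blood")}
        states = {}
        for pp in (1.0, 2.0):  # mmHg: max strain well below 0.005
            states[pp] = solve_static(mesh, mats, LoadCase(pulse_pressure=pp),
                                      n_steps=1, drop_regions=("blood",))
        vm1, vm2 = states[1.0].von_mises, states[2.0].von_mises
        sel = vm1 > 0.2 * vm1.max()
        assert np.allclose(vm2[sel] / vm1[sel], 2.0, rtol=0.01)

    def test_bending_displacement_enforced(self, artery_mesh,
                                           artery_materials):
        d = 2.0
        state = solve_static(artery_mesh, artery_materials,
                             LoadCase(bending=d), n_steps=5)
        assert state.converged
        ring = midspan_nodes(artery_mesh)
        assert np.allclose(state.u[ring, 0], d, atol=1e-12)
        # both ends stay clamped
        for name in ("end_A", "end_B"):
            assert np.allclose(state.u[artery_mesh.node_sets[name]], 0.0)

    def test_bending_and_pulse_exclusive(self):
        with pytest.raises(ValueError):
            LoadCase(bending=1.0, end_pulse=(1.0, 1.0))

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError):
            LoadCase(pulse_pressure=-10.0)


class TestFEModelConsistency:
    def test_internal_forces_are_energy_gradient(self):
        mesh = make_tube_mesh(VesselSpec("arteriole", length=20.0,
                                         resolution=(8, 8, 2)))
        mats = {"wall": material_from_table("arteriole_wall"),
                "blood": material_from_table("blood")}
        model = FEModel(mesh, mats)
        rng = np.random.default_rng(8)
        u = 0.05 * rng.standard_normal((len(mesh.nodes), 3))
        f = model.internal_forces(u)
        h = 1e-6
        for dof in rng.choice(3 * len(mesh.nodes), size=12, replace=False):
            up, um = u.copy().ravel(), u.copy().ravel()
            up[dof] += h
            um[dof] -= h
            dW = (model.strain_energy(up.reshape(-1, 3)) -
                  model.strain_energy(um.reshape(-1, 3))) / (2 * h)
            assert f.ravel()[dof] == pytest.approx(dW, abs=1e-7 + 1e-4 * abs(dW))

    def test_stiffness_matches_force_difference(self):
        mesh = make_tube_mesh(VesselSpec("arteriole", length=20.0,
                                         resolution=(8, 8, 2)))
        mats = {"wall": material_from_table("arteriole_wall"),
                "blood": material_from_table("blood")}
        model = FEModel(mesh, mats)
        rng = np.random.default_rng(9)
        u = 0.02 * rng.standard_normal((len(mesh.nodes), 3))
        K = model.stiffness(u).toarray()
        assert np.allclose(K, K.T, atol=1e-6 * np.abs(K).max())
        h = 1e-5
        du = rng.standard_normal(3 * len(mesh.nodes))
        du /= np.linalg.norm(du)
        f1 = model.internal_forces((u.ravel() + h * du).reshape(-1, 3))
        f0 = model.internal_forces((u.ravel() - h * du).reshape(-1, 3))
        df_fd = (f1 - f0).ravel() / (2 * h)
        df_K = K @ du
        scale = np.abs(df_fd).max()
        assert np.allclose(df_K, df_fd, atol=5e-4 * scale)
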