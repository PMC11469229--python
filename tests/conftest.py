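"""Shared fixtures: coarse meshes and solves reused across test modules.

Session scope keeps the expensive finite-element work to one solve per
scenario for the whole run.
"""
import numpy as np
import pytest

from marrowmech import (LinearElastic, LoadCase, VesselSpec,
                        default_materials, make_tube_mesh,
                        make_sinusoid_domain, material_from_table,
                        run_explicit, solve_static)


@pytest.fixture(scope="session")
def artery_mesh():
    return make_tube_mesh(VesselSpec("artery", edge_length=10.0))


@pytest.fixture(scope="session")
def artery_materials(artery_mesh):
    return default_materials(artery_mesh, "artery")


@pytest.fixture(scope="session")
def arteriole_mesh():
    return make_tube_mesh(VesselSpec("arteriole", edge_length=5.0))


@pytest.fixture(scope="session")
def sinusoid_mesh():
    return make_sinusoid_domain(VesselSpec("sinusoid", edge_length=12.0))


@pytest.fixture(scope="session")
def artery_static_50(artery_mesh, artery_materials):
    """Artery inflated to a 50 mmHg pulse pressure (coarse mesh)."""
    state = solve_static(artery_mesh, artery_materials,
                         LoadCase(pulse_pressure=50.0), n_steps=2)
    assert state.converged
    return state


@pytest.fixture(scope="session")
def rod_setup():
    """Wall-only linear rod: E=10 MPa, nu=0, rho=1e-3 -> c = 100 µm/µs."""
    mesh = make_tube_mesh(VesselSpec("artery", length=400.0,
                                     edge_length=10.0))
    mats = {"wall": LinearElastic(E=10.0, nu=0.0, density=1e-3),
            "blood": material_from_table("blood")}
    return mesh, mats


@pytest.fixture(scope="session")
def rod_pulse_series(rod_setup):
    """Axial end pulse on the rod, sampled before the end-B reflection."""
    mesh, mats = rod_setup
    load = LoadCase(end_pulse=(0.05, 0.5), pulse_direction="z",
                    fixed={"end_B": "xyz"})
    return run_explicit(mesh, mats, load, duration=3.0,
                        output_times=(1.0, 1.5, 2.0, 2.5, 3.0),
                        drop_regions=("blood",))


@pytest.fixture(scope="session")
def artery_pulse_series(artery_mesh, artery_materials):
    """1 µm / 1 µs stretch pulse on the unpressurised artery, 5 µs."""
    load = LoadCase(end_pulse=(1.0, 1.0), fixed={"end_B": "xyz"})
    return run_explicit(artery_mesh, artery_materials, load, duration=5.0,
                        output_times=(0.5, 1.0, 2.0, 3.0, 4.0, 5.0))
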