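"""Quasi-static nonlinear FEA: pulse-pressure inflation and bending.

Load cases mirror the physiological scenarios: an intravascular pulse
pressure (the systolic-diastolic difference, 50 mmHg for walking and
100 mmHg for running) applied perpendicular to the endovascular surface
as a follower load, and a cortical-bone-bending displacement prescribed
transversely on the midspan node ring of a vessel whose ends are clamped.

The solver is total-Lagrangian Newton with uniform load stepping and
automatic bisection of a step that fails to converge.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, InvertedElementError, MeshError
from .fem import FEModel
from .geometry import VesselMesh
from .units import mmhg_to_mpa

__all__ = [
    "LoadCase",
    "FieldState",
    "mmHg_to_MPa",
    "apply_pressure_load",
    "solve_static",
    "midspan_nodes",
]

# public alias in the field's customary capitalisation
mmHg_to_MPa = mmhg_to_mpa


@dataclass
class LoadCase:
    """A single loading scenario.

    ``pulse_pressure`` is in mmHg (converted internally); ``bending`` is
    the transverse midspan displacement d in µm; ``end_pulse`` is an
    (amplitude µm, rise time µs) tuple for the dynamic solver.  ``fixed``
    maps node-set names to the constrained components, e.g.
    ``{"end_A": "xyz", "end_B": "z"}``.
    """

    pulse_pressure: float = 0.0
    bending: float = 0.0
    end_pulse: Optional[tuple[float, float]] = None
    fixed: dict = field(default_factory=lambda: {"end_A": "xyz", "end_B": "xyz"})
    follower_pressure: bool = True
    pressure_surface: str = "inner_lumen"
    #: the vibratory end pulse is transverse to the vessel axis by default
    #: (an axial pulse is selected with "z", e.g. for rod-wave benchmarks)
    pulse_direction: str = "x"
    bending_direction: str = "x"

    def __post_init__(self):
        if self.bending is None:
            self.bending = 0.0
        if self.pulse_pressure < 0:
            raise ValueError("pulse_pressure must be >= 0")
        if self.bending != 0.0 and self.end_pulse is not None:
            raise ValueError(
                "bending and end_pulse cannot be combined in one load case; "
                "pressure couplings go through couple_prestress")


@dataclass
class FieldState:
    """Converged (or last) static solution.

    ``cauchy`` and ``von_mises`` are indexed by *global* tet id (zero for
    elements outside the active regions) so surface facets can look up
    their parent element directly.  Stresses in MPa.
    """

    u: np.ndarray
    cauchy: np.ndarray
    von_mises: np.ndarray
    residual_norm: float
    converged: bool
    n_iterations: int = 0


_COMP = {"x": 0, "y": 1, "z": 2}


def midspan_nodes(mesh: VesselMesh) -> np.ndarray:
    """Nodes of the lattice station nearest z = L/2 (one element layer wide)."""
    z = mesh.nodes[:, 2]
    stations = np.unique(np.round(z, 9))
    mid = stations[np.argmin(np.abs(stations - 0.5 * (z.min() + z.max())))]
    return np.where(np.abs(z - mid) < 1e-6)[0]


def apply_pressure_load(mesh: VesselMesh, surface: str, p: float,
                        follower: bool = True,
                        u: Optional[np.ndarray] = None) -> np.ndarray:
    """Consistent nodal forces of a uniform pressure on a facet set.

    The traction is ``-p n`` with ``n`` the outward normal of the loaded
    region, i.e. the pressure pushes *into* the parent region — for the
    endovascular surface of a wall this is radially outward, matching a
    pulse pressure imposed perpendicular to the inner vascular surface.
    In follower mode normals and areas are recomputed on the deformed
    configuration ``x = X + u``.
    """
    if surface not in mesh.surface_sets:
        raise MeshError(f"unknown surface set {surface!r}")
    if len(mesh.surface_sets[surface]) == 0:
        raise MeshError(f"surface set {surface!r} is empty")
    coords = mesh.nodes
    if follower and u is not None:
        coords = mesh.nodes + u
    tri = mesh.facet_triangles(surface)
    x = coords[tri]
    av = 0.5 * np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])  # outward area vectors
    if np.any(np.linalg.norm(av, axis=1) <= 0.0):
        raise MeshError(f"zero-area facet in surface set {surface!r}")
    f_tri = -p * av
    forces = np.zeros((len(coords), 3))
    for corner in range(3):
        np.add.at(forces, tri[:, corner], f_tri / 3.0)
    return forces


def _dirichlet_dofs(model: FEModel, mesh: VesselMesh, load: LoadCase,
                    extra_prescribed=None):
    """Return (prescribed dof ids, unit values at full load)."""
    n = model.n_nodes
    dofs, vals = [], []

    def add(nodes, comps, value_by_comp):
        for c in comps:
            dofs.append(3 * np.asarray(nodes, dtype=np.int64) + _COMP[c])
            vals.append(np.full(len(nodes), value_by_comp.get(c, 0.0)))

    for set_name, comps in load.fixed.items():
        if set_name not in mesh.node_sets:
            raise MeshError(f"unknown node set {set_name!r} in fixed spec")
        add(mesh.node_sets[set_name], comps, {})
    if load.bending != 0.0:
        ring = midspan_nodes(mesh)
        add(ring, load.bending_direction, {load.bending_direction: load.bending})
    # nodes outside active regions carry no stiffness: pin them
    inactive = np.setdiff1d(np.arange(n), model.active_nodes, assume_unique=False)
    if len(inactive):
        add(inactive, "xyz", {})
    if extra_prescribed is not None:
        dofs.append(np.asarray(extra_prescribed[0], dtype=np.int64))
        vals.append(np.asarray(extra_prescribed[1], dtype=float))
    dofs = np.concatenate(dofs) if dofs else np.array([], dtype=np.int64)
    vals = np.concatenate(vals) if vals else np.array([])
    # deduplicate, keeping the first (constraint) entry
    uniq, first = np.unique(dofs, return_index=True)
    return uniq, vals[first]


def _global_stress_arrays(model: FEModel, u: np.ndarray):
    from .materials import von_mises as vm

    sigma_active = model.element_cauchy(u)
    n_tets = len(model.mesh.tets)
    cauchy = np.zeros((n_tets, 3, 3))
    cauchy[model.active_elements] = sigma_active
    vonmises = np.zeros(n_tets)
    vonmises[model.active_elements] = vm(sigma_active)
    return cauchy, vonmises


def solve_static(mesh: VesselMesh, materials: dict, load: LoadCase,
                 tol: float = 1e-9, max_iter: int = 30, n_steps: int = 10,
                 drop_regions=(), nodal_pressure: bool = True,
                 extra_prescribed=None, model: Optional[FEModel] = None,
                 max_bisections: int = 6) -> FieldState:
    """Solve a quasi-static load case by Newton iteration with load stepping.

    Convergence requires the free-dof residual norm to fall below
    ``tol * max(|f_ext|, |reactions|)`` (with a tiny absolute floor for
    unloaded cases).  A non-converging increment is bisected up to
    ``max_bisections`` times before a :class:`ConvergenceError` is raised.
    """
    if load.end_pulse is not None:
        raise ValueError("end_pulse load cases belong to the explicit solver")
    if model is None:
        model = FEModel(mesh, materials, drop_regions=drop_regions,
                        nodal_pressure=nodal_pressure)
    p_full = mmhg_to_mpa(load.pulse_pressure)
    presc_dofs, presc_vals = _dirichlet_dofs(model, mesh, load, extra_prescribed)
    ndof = 3 * model.n_nodes
    free = np.ones(ndof, dtype=bool)
    free[presc_dofs] = False
    free_idx = np.where(free)[0]

    u = np.zeros((model.n_nodes, 3))
    total_iters = 0
    lam_done = 0.0
    dlam = 1.0 / max(1, n_steps)
    bisections = 0
    last_res = np.inf

    if p_full == 0.0 and load.bending == 0.0 and (
            extra_prescribed is None or not len(np.atleast_1d(presc_vals)) or
            np.allclose(presc_vals, 0.0)):
        # unloaded: the zero state is the converged solution
        f = model.internal_forces(u)
        rn = float(np.linalg.norm(f.ravel()[free_idx]))
        cauchy, vonmises = _global_stress_arrays(model, u)
        return FieldState(u=u, cauchy=cauchy, von_mises=vonmises,
                          residual_norm=rn, converged=rn < 1e-10,
                          n_iterations=1)

    while lam_done < 1.0 - 1e-12:
        lam = min(1.0, lam_done + dlam)
        u_trial = u.copy()
        uflat = u_trial.reshape(-1)
        uflat[presc_dofs] = lam * presc_vals
        ok = False
        try:
            best = np.inf
            for it in range(max_iter):
                total_iters += 1
                f_int = model.internal_forces(u_trial)
                f_ext = np.zeros_like(f_int)
                if p_full != 0.0:
                    f_ext = apply_pressure_load(
                        mesh, load.pressure_surface, lam * p_full,
                        follower=load.follower_pressure, u=u_trial)
                r = (f_int - f_ext).reshape(-1)
                rnorm = float(np.linalg.norm(r[free_idx]))
                ref = max(float(np.linalg.norm(f_ext)),
                          float(np.linalg.norm(r[presc_dofs])), 1e-12)
                last_res = rnorm
                if rnorm <= tol * ref:
                    ok = True
                    break
                if rnorm > 1e4 * ref and rnorm > 10.0 * best:
                    break  # diverging; bisect
                best = min(best, rnorm)
                K = model.stiffness(u_trial)
                Kff = K[free_idx][:, free_idx]
                du = spla.spsolve(Kff.tocsc(), -r[free_idx])
                if not np.all(np.isfinite(du)):
                    break
                uflat[free_idx] += du
        except InvertedElementError:
            ok = False
        if ok:
            u = u_trial
            lam_done = lam
        else:
            bisections += 1
            dlam *= 0.5
            if bisections > max_bisections:
                raise ConvergenceError(
                    f"static solve failed at load fraction {lam:.4g} after "
                    f"{bisections} bisections (last residual {last_res:.3e})",
                    residual=last_res)

    cauchy, vonmises = _global_stress_arrays(model, u)
    return FieldState(u=u, cauchy=cauchy, von_mises=vonmises,
                      residual_norm=last_res, converged=True,
                      n_iterations=total_iters)
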