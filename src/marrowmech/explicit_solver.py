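"""Explicit central-difference dynamics for vibratory stretch pulses.

A single exercise-induced tensile pulse — 1 µm of end displacement applied
over 1 µs, then held — is propagated through the vessel with lumped-mass
central differences.  The time step obeys the CFL limit based on the
per-element dilatational wave speed; there is no damping unless requested.
Coupled scenarios start from a statically inflated configuration with the
pulse pressure held as a follower load throughout the transient.

The energy ledger (external work by reactions and pressure, kinetic and
strain energy) is tracked at every output time; in undamped runs its
drift is a direct global check on the integration.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (InvertedElementError, MaterialError, MeshError,
                     StabilityError)
from .fem import FEModel
from .geometry import VesselMesh
from .static_solver import LoadCase, FieldState, apply_pressure_load, solve_static
from .units import mmhg_to_mpa

__all__ = [
    "DynamicSeries",
    "stable_timestep",
    "run_explicit",
    "couple_prestress",
    "DEFAULT_OUTPUT_TIMES",
]

#: Default snapshot schedule (µs) for a 20 µs pulse-propagation run.
DEFAULT_OUTPUT_TIMES = (1.0, 2.0, 5.0, 10.0, 20.0)

_COMP = {"x": 0, "y": 1, "z": 2}


@dataclass
class DynamicSeries:
    """Snapshots of an explicit run.

    ``von_mises[k]`` is indexed by global tet id (MPa; zero outside active
    regions).  ``energy`` has one row per snapshot with columns
    ``time, external_work, kinetic, strain, drift``.
    """

    times: np.ndarray
    displacements: list
    velocities: list
    von_mises: list
    energy: pd.DataFrame
    dt: float
    static_state: Optional[FieldState] = None

    def peak_von_mises(self) -> np.ndarray:
        return np.array([vm.max() for vm in self.von_mises])


def stable_timestep(mesh: VesselMesh, materials: dict, safety: float = 0.5,
                    drop_regions=(), model: Optional[FEModel] = None) -> float:
    """CFL-stable time step: ``safety * min_e h_e / c_e`` (µs).

    ``h_e`` is the smallest element altitude and ``c_e`` the dilatational
    wave speed ``sqrt((kappa + 4 mu / 3) / rho)`` of the element material.
    """
    if model is None:
        model = FEModel(mesh, materials, drop_regions=drop_regions)
    h = model.characteristic_lengths()
    dt = np.inf
    for g in model.groups:
        mat = g.material
        if mat.density <= 0.0:
            raise MaterialError("density must be positive for explicit dynamics")
        c = np.sqrt(mat.p_wave_modulus / mat.density)
        dt = min(dt, float(h[g.idx].min()) / c)
    return safety * dt


def _pulse_profile(t, amplitude, rise_time, shape="half_cosine"):
    """Smooth ramp from 0 to ``amplitude`` over ``rise_time``, then hold."""
    t = np.minimum(np.asarray(t, dtype=float), rise_time)
    if shape == "linear":
        return amplitude * t / rise_time
    return 0.5 * amplitude * (1.0 - np.cos(np.pi * t / rise_time))


def run_explicit(mesh: VesselMesh, materials: dict, load: LoadCase,
                 duration: float, output_times: Sequence[float] = DEFAULT_OUTPUT_TIMES,
                 dt: Optional[float] = None, drop_regions=(),
                 model: Optional[FEModel] = None, initial_u: Optional[np.ndarray] = None,
                 damping: float = 0.0, safety: float = 0.5,
                 pulse_set: str = "end_A", pulse_shape: str = "half_cosine",
                 nodal_pressure: bool = True) -> DynamicSeries:
    """Integrate a load case explicitly and snapshot at ``output_times``.

    The end pulse displaces the ``pulse_set`` nodes along
    ``load.pulse_direction`` (transverse by default, half-cosine ramp)
    while clamping their other components;
    node sets named in ``load.fixed`` are held at their initial positions.
    Aborts with :class:`StabilityError` on NaN fields or kinetic-energy
    blow-up beyond 10x the external work.
    """
    if model is None:
        model = FEModel(mesh, materials, drop_regions=drop_regions,
                        nodal_pressure=nodal_pressure)
    if dt is None:
        dt = stable_timestep(mesh, materials, safety=safety, model=model)
    output_times = np.asarray(sorted(output_times), dtype=float)
    if output_times.size == 0 or output_times[-1] > duration + 1e-12:
        raise ValueError("output_times must be non-empty and within duration")
    n_steps = max(1, int(np.ceil(duration / dt - 1e-12)))
    dt = duration / n_steps
    snap_steps = set(np.unique(
        np.clip(np.round(output_times / dt), 1, n_steps).astype(int)).tolist())

    n = model.n_nodes
    u = np.zeros((n, 3)) if initial_u is None else np.array(initial_u, dtype=float)
    p_hold = mmhg_to_mpa(load.pulse_pressure)

    # --- constrained dofs -------------------------------------------------
    presc_dofs = []
    for set_name in load.fixed:
        if set_name not in mesh.node_sets:
            raise MeshError(f"unknown node set {set_name!r} in fixed spec")
        comps = load.fixed[set_name]
        nodes = mesh.node_sets[set_name]
        for c in comps:
            presc_dofs.append(3 * nodes + _COMP[c])
    pulse_dofs = np.array([], dtype=np.int64)
    if load.end_pulse is not None:
        amplitude, rise = load.end_pulse
        if rise <= 0:
            raise ValueError("pulse rise time must be positive")
        pnodes = mesh.node_sets[pulse_set]
        for c in "xyz":
            presc_dofs.append(3 * pnodes + _COMP[c])
        pulse_dofs = 3 * pnodes + _COMP[load.pulse_direction]
    inactive = np.setdiff1d(np.arange(n), model.active_nodes)
    if len(inactive):
        for c in range(3):
            presc_dofs.append(3 * inactive + c)
    presc_dofs = (np.unique(np.concatenate(presc_dofs))
                  if presc_dofs else np.array([], dtype=np.int64))
    base_vals = u.reshape(-1)[presc_dofs].copy()
    in_pulse = np.isin(presc_dofs, pulse_dofs)

    mass = model.mass.copy()
    free_nodes = np.zeros(n, dtype=bool)
    free_nodes[model.active_nodes] = True
    if np.any(mass[model.active_nodes] <= 0.0):
        raise MaterialError("zero nodal mass on active nodes")
    minv = np.zeros(n)
    minv[model.active_nodes] = 1.0 / mass[model.active_nodes]

    def prescribe(u_flat, t):
        vals = base_vals.copy()
        if load.end_pulse is not None:
            vals[in_pulse] += _pulse_profile(t, amplitude, rise, pulse_shape)
        u_flat[presc_dofs] = vals

    from .materials import von_mises as vm_of

    # --- time loop ---------------------------------------------------------
    u_prev = u.copy()
    prescribe(u_prev.reshape(-1), 0.0)
    prescribe(u.reshape(-1), 0.0)
    e0 = model.strain_energy(u)

    w_ext = 0.0
    R_prev = None
    fp_prev = None

    times_rec, u_rec, v_rec, vm_rec = [], [], [], []
    energy_rows = []
    m3 = mass[:, None]
    minv3 = minv[:, None]
    mass_c = np.repeat(mass, 3)[presc_dofs]

    # one trailing step so the state at t = duration is recorded with a
    # centred velocity (the pulse is simply held beyond the duration)
    for step in range(n_steps + 1):
        t = step * dt
        f_p = (apply_pressure_load(mesh, load.pressure_surface, p_hold,
                                   follower=load.follower_pressure, u=u)
               if p_hold != 0.0 else np.zeros((n, 3)))
        try:
            f_int = model.internal_forces(u)
        except InvertedElementError as exc:
            raise StabilityError(
                f"element inversion at t = {t:.4g} µs — the integration has "
                f"gone unstable (reduce the time step)") from exc
        a = (f_p - f_int) * minv3
        if damping > 0.0:
            a -= damping * (u - u_prev) / dt
        if step == 0:
            u_next = u + 0.5 * dt * dt * a  # v0 = 0 start
        else:
            u_next = 2.0 * u - u_prev + dt * dt * a
        prescribe(u_next.reshape(-1), t + dt)

        # reactions at constrained dofs: R = m a_presc + f_int - f_p
        a_presc = (u_next - 2.0 * u + u_prev).reshape(-1)[presc_dofs] / (dt * dt)
        R = mass_c * a_presc + (f_int - f_p).reshape(-1)[presc_dofs]
        if R_prev is not None:
            du_c = (u.reshape(-1)[presc_dofs] - u_prev_c)
            w_ext += float(0.5 * np.dot(R_prev + R, du_c))
            w_ext += float(0.5 * np.einsum("ij,ij->", fp_prev + f_p, u - u_prev))
        R_prev = R
        fp_prev = f_p
        u_prev_c = u.reshape(-1)[presc_dofs].copy()

        if not np.all(np.isfinite(u_next)):
            raise StabilityError(f"NaN/Inf displacement at t = {t + dt:.4g} µs")
        if step in snap_steps:
            v_half_prev = (u - u_prev) / dt if step > 0 else np.zeros_like(u)
            v_half_next = (u_next - u) / dt
            ke = 0.5 * float(np.einsum("ij,ij->", m3 * v_half_prev, v_half_next))
            se = model.strain_energy(u) - e0
            ref = max(abs(w_ext), abs(se), 1e-12)
            drift = abs(w_ext - (ke + se)) / ref
            if ke > 10.0 * ref + 1e-9:
                raise StabilityError(
                    f"kinetic energy {ke:.3e} exceeds 10x external work at "
                    f"t = {t:.4g} µs")
            times_rec.append(t)
            u_rec.append(u.copy())
            v_rec.append(0.5 * (v_half_prev + v_half_next))
            _, sigma = model.internal_forces(u, return_stress=True)
            vm_full = np.zeros(len(mesh.tets))
            vm_full[model.active_elements] = vm_of(sigma)
            vm_rec.append(vm_full)
            energy_rows.append(
                dict(time=t, external_work=w_ext, kinetic=ke, strain=se, drift=drift))
        u_prev, u = u, u_next

    energy = pd.DataFrame(energy_rows)
    return DynamicSeries(times=np.asarray(times_rec), displacements=u_rec,
                         velocities=v_rec, von_mises=vm_rec, energy=energy, dt=dt)


def couple_prestress(mesh: VesselMesh, materials: dict, pp_mmhg: float,
                     then: LoadCase, duration: float,
                     output_times: Sequence[float] = DEFAULT_OUTPUT_TIMES,
                     dt: Optional[float] = None, drop_regions=(),
                     static_tol: float = 1e-10,
                     static_kwargs: Optional[dict] = None,
                     **kwargs) -> DynamicSeries:
    """Explicit run initialised from a statically inflated configuration.

    The pulse pressure ``pp_mmhg`` is first equilibrated quasi-statically
    (both ends clamped), then the vibratory load case ``then`` runs with
    the pressure held as a follower load.  With ``pp_mmhg = 0`` the path is
    bit-identical to a cold :func:`run_explicit` start.
    """
    load_dyn = replace(then, pulse_pressure=pp_mmhg)
    model = FEModel(mesh, materials, drop_regions=drop_regions)
    if pp_mmhg == 0.0:
        return run_explicit(mesh, materials, load_dyn, duration, output_times,
                            dt=dt, model=model, **kwargs)
    fixed = dict(then.fixed)
    fixed.setdefault("end_A", "xyz")
    fixed.setdefault("end_B", "xyz")
    static_load = LoadCase(pulse_pressure=pp_mmhg, fixed=fixed,
                           follower_pressure=then.follower_pressure,
                           pressure_surface=then.pressure_surface)
    state = solve_static(mesh, materials, static_load, tol=static_tol,
                         model=model, **(static_kwargs or {}))
    series = run_explicit(mesh, materials, load_dyn, duration, output_times,
                          dt=dt, model=model, initial_u=state.u, **kwargs)
    series.static_state = state
    return series
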