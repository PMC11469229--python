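"""Shared finite-element core: kinematics, internal forces, tangent assembly.

Linear (constant-strain) tetrahedra in a total-Lagrangian setting.  The
near-incompressible Mooney-Rivlin wall (bulk/shear ~ 1000) would lock
badly with plain displacement tets, so the volumetric energy of
hyperelastic regions is evaluated on *nodal-patch-averaged* Jacobians
(the average-nodal-pressure tetrahedron of Bonet & Burton): with nodal
volumes ``V_n = sum_{e in patch(n)} V0_e / 4`` and nodal Jacobians
``J_n = sum (V0_e/4) J_e / V_n``, the volumetric energy is

    E_vol = sum_n V_n U(J_n),        U(J) = (1/D1) (J - 1)^2.

Internal forces are the exact gradient of the total energy (so the
explicit solver's energy ledger closes), and the static tangent includes
the exact non-local volumetric Hessian, keeping Newton quadratic.
The deviatoric part of the Mooney-Rivlin energy depends only on the
isochoric invariants and needs no projection.

Deformation gradients, stresses and tangents are evaluated in batch over
all elements with numpy einsum; the FD material tangent perturbs F in all
nine directions with central differences.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import InvertedElementError, MeshError
from .geometry import VesselMesh, tet_volumes
from .materials import (
    IgnoredMaterial,
    LinearElastic,
    MooneyRivlin5,
    mr_deviatoric_first_pk,
    mr_strain_energy,
    mr_volumetric_dUdJ,
    svk_first_pk,
    svk_strain_energy,
)

_FD_STEP = 1e-6


@dataclass
class _Group:
    """Elements sharing one material (indices into the *active* element arrays)."""

    material: object
    idx: np.ndarray
    kind: str              # "mr" | "svk"
    # average-nodal-pressure bookkeeping (mr groups only)
    anp: bool = False
    patch_nodes: np.ndarray | None = None   # unique node ids of the group
    node_pos: np.ndarray | None = None      # (n_e, 4) position of each tet node in patch_nodes
    Vn: np.ndarray | None = None            # reference nodal volumes


class FEModel:
    """Assembled representation of a vessel mesh with per-region materials.

    Parameters
    ----------
    mesh:
        The tetrahedral vessel mesh.
    materials:
        Mapping region tag -> material model.  Regions mapped to the
        IGNORED sentinel (or listed in ``drop_regions``) contribute neither
        stiffness nor mass.
    drop_regions:
        Region tags excluded from the model entirely.
    nodal_pressure:
        Apply the average-nodal-pressure projection to Mooney-Rivlin
        regions (default True).
    """

    def __init__(self, mesh: VesselMesh, materials: dict, drop_regions=(),
                 nodal_pressure: bool = True):
        self.mesh = mesh
        self.materials = dict(materials)
        drop = set(drop_regions)
        for region in mesh.regions:
            if region not in self.materials:
                raise MeshError(f"no material assigned to region {region!r}")
            if isinstance(self.materials[region], IgnoredMaterial):
                drop.add(region)
        keep = ~np.isin(mesh.region_of_tet, sorted(drop))
        self.active_elements = np.where(keep)[0]
        if len(self.active_elements) == 0:
            raise MeshError("no active elements remain")
        self.tets = mesh.tets[self.active_elements]
        X = mesh.nodes
        self.n_nodes = len(X)

        D = X[self.tets[:, 1:]] - X[self.tets[:, :1]]      # rows = edge vectors
        self.V0 = np.linalg.det(D) / 6.0
        if self.V0.min() <= 0.0:
            raise MeshError("active mesh contains non-positive volumes")
        Dinv = np.linalg.inv(D)
        G = np.empty((len(self.tets), 4, 3))
        G[:, 1:, :] = np.swapaxes(Dinv, 1, 2)
        G[:, 0, :] = -G[:, 1:, :].sum(axis=1)
        self.G = G

        # group elements by region material
        self.groups: list[_Group] = []
        regions_active = mesh.region_of_tet[self.active_elements]
        for region in sorted(set(regions_active.tolist())):
            mat = self.materials[region]
            idx = np.where(regions_active == region)[0]
            if isinstance(mat, MooneyRivlin5):
                g = _Group(material=mat, idx=idx, kind="mr", anp=nodal_pressure)
                if nodal_pressure:
                    self._init_anp(g)
                self.groups.append(g)
            elif isinstance(mat, LinearElastic):
                self.groups.append(_Group(material=mat, idx=idx, kind="svk"))
            else:  # pragma: no cover - guarded above
                raise MeshError(f"unsupported material for region {region!r}")

        self.active_nodes = np.unique(self.tets)
        # lumped (row-sum) nodal masses
        m = np.zeros(self.n_nodes)
        for g in self.groups:
            rho = g.material.density
            np.add.at(m, self.tets[g.idx].ravel(),
                      np.repeat(rho * self.V0[g.idx] / 4.0, 4))
        self.mass = m

    # -- average nodal pressure bookkeeping --------------------------------
    def _init_anp(self, g: _Group):
        tets = self.tets[g.idx]
        patch_nodes, node_pos = np.unique(tets, return_inverse=True)
        g.patch_nodes = patch_nodes
        g.node_pos = node_pos.reshape(tets.shape)
        Vn = np.zeros(len(patch_nodes))
        np.add.at(Vn, g.node_pos.ravel(), np.repeat(self.V0[g.idx] / 4.0, 4))
        g.Vn = Vn

    def _nodal_jacobians(self, g: _Group, J: np.ndarray) -> np.ndarray:
        """Volume-weighted nodal average of element Jacobians within a group."""
        acc = np.zeros(len(g.patch_nodes))
        np.add.at(acc, g.node_pos.ravel(), np.repeat(self.V0[g.idx] / 4.0 * J, 4))
        return acc / g.Vn

    # -- kinematics ----------------------------------------------------------
    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        """F per active element for a nodal displacement field u (N, 3)."""
        F = np.einsum("eai,eaj->eij", u[self.tets], self.G)
        F[:, 0, 0] += 1.0
        F[:, 1, 1] += 1.0
        F[:, 2, 2] += 1.0
        return F

    # -- constitutive dispatch ------------------------------------------------
    def _first_pk(self, g: _Group, Fg: np.ndarray, pe: np.ndarray | None):
        """First PK stress of a group; ``pe`` is the (projected) element pressure
        dU/dJ for mr groups, or None to use the local J."""
        if g.kind == "svk":
            return svk_first_pk(Fg, g.material)
        P = mr_deviatoric_first_pk(Fg, g.material)
        J = np.linalg.det(Fg)
        if np.any(J <= 0.0):
            raise InvertedElementError("inverted element in Mooney-Rivlin region")
        if pe is None:
            pe = mr_volumetric_dUdJ(J, g.material)
        FinvT = np.swapaxes(np.linalg.inv(Fg), 1, 2)
        return P + (pe * J)[:, None, None] * FinvT

    def _element_pressures(self, g: _Group, J: np.ndarray) -> np.ndarray:
        """ANP element pressure: mean of nodal dU/dJ over the tet's nodes."""
        Jn = self._nodal_jacobians(g, J)
        pn = mr_volumetric_dUdJ(Jn, g.material)
        return pn[g.node_pos].mean(axis=1)

    # -- energies, forces, stresses -------------------------------------------
    def strain_energy(self, u: np.ndarray) -> float:
        F = self.deformation_gradients(u)
        E = 0.0
        for g in self.groups:
            Fg = F[g.idx]
            if g.kind == "svk":
                E += float((self.V0[g.idx] * svk_strain_energy(Fg, g.material)).sum())
            else:
                Wdev = mr_strain_energy(Fg, g.material, include_volumetric=False)
                E += float((self.V0[g.idx] * Wdev).sum())
                J = np.linalg.det(Fg)
                if g.anp:
                    Jn = self._nodal_jacobians(g, J)
                    E += float((g.Vn * (Jn - 1.0) ** 2).sum() / g.material.D1)
                else:
                    E += float((self.V0[g.idx] * (J - 1.0) ** 2).sum() / g.material.D1)
        return E

    def internal_forces(self, u: np.ndarray, return_stress: bool = False):
        """Internal nodal force vector (N, 3); exact gradient of strain_energy.

        With ``return_stress`` also returns per-active-element Cauchy stress
        consistent with the (projected) pressures driving the forces.
        """
        F = self.deformation_gradients(u)
        f = np.zeros((self.n_nodes, 3))
        sigma = np.zeros_like(F) if return_stress else None
        for g in self.groups:
            Fg = F[g.idx]
            pe = None
            if g.kind == "mr" and g.anp:
                J = np.linalg.det(Fg)
                if np.any(J <= 0.0):
                    raise InvertedElementError("inverted element in Mooney-Rivlin region")
                pe = self._element_pressures(g, J)
            P = self._first_pk(g, Fg, pe)
            fe = np.einsum("e,eij,eaj->eai", self.V0[g.idx], P, self.G[g.idx])
            np.add.at(f, self.tets[g.idx].ravel(), fe.reshape(-1, 3))
            if return_stress:
                J = np.linalg.det(Fg)
                s = P @ np.swapaxes(Fg, 1, 2) / J[:, None, None]
                sigma[g.idx] = 0.5 * (s + np.swapaxes(s, 1, 2))
        if return_stress:
            return f, sigma
        return f

    def element_cauchy(self, u: np.ndarray) -> np.ndarray:
        """Cauchy stress per active element (symmetric)."""
        _, sigma = self.internal_forces(u, return_stress=True)
        return sigma

    # -- tangent stiffness -----------------------------------------------------
    def _material_tangent_fd(self, g: _Group, Fg: np.ndarray, pe):
        """dP/dF per element by central differences (pressure held fixed)."""
        n = len(Fg)
        A = np.empty((n, 3, 3, 3, 3))
        h = _FD_STEP
        for j in range(3):
            for l in range(3):
                Fp = Fg.copy()
                Fp[:, j, l] += h
                Fm = Fg.copy()
                Fm[:, j, l] -= h
                A[:, :, :, j, l] = (self._first_pk(g, Fp, pe)
                                    - self._first_pk(g, Fm, pe)) / (2.0 * h)
        return A

    def stiffness(self, u: np.ndarray) -> sp.csr_matrix:
        """Tangent stiffness (3N x 3N) at displacement u.

        Local part: FD material tangent per element.  For ANP groups, the
        element pressure is held fixed in the local part and the exact
        non-local volumetric Hessian ``sum_n (U''/V_n) g_n g_n^T`` is added.
        """
        F = self.deformation_gradients(u)
        rows, cols, vals = [], [], []
        for g in self.groups:
            Fg = F[g.idx]
            pe = None
            if g.kind == "mr" and g.anp:
                J = np.linalg.det(Fg)
                pe = self._element_pressures(g, J)
            A = self._material_tangent_fd(g, Fg, pe)
            # K[a i, b j] = V0 * dP_im/dF_jn * G[a, m] * G[b, n]
            Ke = np.einsum("e,eimjn,eam,ebn->eaibj",
                           self.V0[g.idx], A, self.G[g.idx], self.G[g.idx],
                           optimize=True)
            tg = self.tets[g.idx]
            dof = (3 * tg[:, :, None] + np.arange(3)[None, None, :]).reshape(len(tg), 12)
            r = np.repeat(dof, 12, axis=1).ravel()
            c = np.tile(dof, (1, 12)).ravel()
            rows.append(r)
            cols.append(c)
            vals.append(Ke.reshape(len(tg), 144).ravel())
            if g.kind == "mr" and g.anp:
                rn, cn, vn = self._anp_volumetric_hessian(g, Fg)
                rows.append(rn)
                cols.append(cn)
                vals.append(vn)
        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(3 * self.n_nodes, 3 * self.n_nodes),
        )
        return K.tocsr()

    def _anp_volumetric_hessian(self, g: _Group, Fg: np.ndarray):
        """Exact non-local volumetric Hessian of sum_n V_n U(J_n).

        ``g_n = dJ_n/du * V_n`` is supported on the 1-ring patch of node n;
        the Hessian contribution is ``(U''/V_n) g_n g_n^T`` (U' curvature of
        J_n itself is captured by the FD local part through the held
        element pressure acting on J's geometric second derivative).
        """
        mat = g.material
        J = np.linalg.det(Fg)
        Finv = np.linalg.inv(Fg)
        # dJ/du for element nodes: h[e, b, k] = J_e (G_e F_e^{-1})[b, k]
        h = J[:, None, None] * np.einsum("ebm,emk->ebk", self.G[g.idx], Finv)
        w = (self.V0[g.idx] / 4.0)[:, None, None] * h          # (n_e, 4, 3)
        tg = self.tets[g.idx]
        Upp = 2.0 / mat.D1  # U'' is constant for the quadratic penalty

        # per patch node: entries (global node, 3-vector) from each adjacent tet
        flat_nodes = g.node_pos.ravel()                        # patch-node index per entry
        entry_elem = np.repeat(np.arange(len(tg)), 4)
        entry_local = np.tile(np.arange(4), len(tg))
        order = np.argsort(flat_nodes, kind="stable")
        sorted_patch = flat_nodes[order]
        starts = np.searchsorted(sorted_patch, np.arange(len(g.patch_nodes)))
        ends = np.append(starts[1:], len(sorted_patch))

        rows, cols, vals = [], [], []
        for n in range(len(g.patch_nodes)):
            sel = order[starts[n]:ends[n]]
            e = entry_elem[sel]
            a = entry_local[sel]
            # accumulate g_n over unique global nodes of the patch
            nodes_rep = tg[e].ravel()
            contrib = w[e].reshape(-1, 3)
            uniq, inv = np.unique(nodes_rep, return_inverse=True)
            gn = np.zeros((len(uniq), 3))
            np.add.at(gn, inv, contrib)
            # keep only the rows fed by this node's own tets: g_n includes all
            # four nodes of each adjacent tet
            coeff = Upp / g.Vn[n]
            dofs = (3 * uniq[:, None] + np.arange(3)).ravel()
            gv = gn.ravel()
            block = coeff * np.outer(gv, gv)
            rows.append(np.repeat(dofs, len(dofs)))
            cols.append(np.tile(dofs, len(dofs)))
            vals.append(block.ravel())
        return (np.concatenate(rows), np.concatenate(cols), np.concatenate(vals))

    # -- element quality -------------------------------------------------------
    def characteristic_lengths(self) -> np.ndarray:
        """Per-element characteristic length: smallest altitude 3V / A_max."""
        x = self.mesh.nodes[self.tets]
        areas = []
        from .geometry import TET_FACES

        for f in TET_FACES:
            v = x[:, f, :]
            areas.append(0.5 * np.linalg.norm(
                np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1))
        amax = np.max(areas, axis=0)
        return 3.0 * self.V0 / amax
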