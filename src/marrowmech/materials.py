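"""Constitutive models for bone-marrow vessel tissue.

Arteriolar and arterial walls are smooth-muscle-rich and markedly
hyperelastic: their stiffness grows with deformation.  They are modelled
with the 5-parameter Mooney-Rivlin strain-energy density

    W = sum_{1 <= i+j <= 2} C_ij (I1b - 3)^i (I2b - 3)^j + (1/D1)(J - 1)^2

where ``I1b``, ``I2b`` are the isochoric (volume-preserving) invariants of
the right Cauchy-Green tensor and ``J = det F``.  Under exact
incompressibility (``lambda1 lambda2 lambda3 = 1``) the isochoric
invariants coincide with the plain ones and the penalty term vanishes, so
this compressible regularisation reduces to the classical incompressible
form.  Bone marrow is a soft linear-elastic solid (E = 10 kPa) and
intravascular blood carries mass but essentially no stiffness.

All stresses are in MPa, densities in the internal µm-µs-MPa unit system
(water = 1.0e-3; see :mod:`marrowmech.units`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

from .errors import InvertedElementError, MaterialError

__all__ = [
    "MooneyRivlin5",
    "LinearElastic",
    "IgnoredMaterial",
    "IGNORED",
    "MaterialModel",
    "Deformation",
    "mr_strain_energy",
    "mr_cauchy_stress",
    "mr_first_pk",
    "svk_first_pk",
    "svk_strain_energy",
    "linear_stress",
    "von_mises",
    "material_from_table",
    "ARTERY_WALL_COEFFICIENTS",
]

# Published calibration of the 5-parameter Mooney-Rivlin wall model (MPa).
ARTERY_WALL_COEFFICIENTS = {
    "C10": 0.115,
    "C01": -0.049,
    "C20": 1.403,
    "C11": -3.370,
    "C02": 2.201,
}

# Soft-tissue literature densities in internal units (1e6 kg/m^3).
DENSITY_WALL = 1.10e-3
DENSITY_BLOOD = 1.06e-3
DENSITY_MARROW = 1.00e-3

#: Default bulk-to-shear ratio for the near-incompressible wall; gives an
#: effective Poisson ratio of about 0.4995.
DEFAULT_BULK_TO_SHEAR = 1000.0


@dataclass(frozen=True)
class MooneyRivlin5:
    """5-parameter Mooney-Rivlin hyperelastic solid.

    ``C10 ... C02`` are in MPa.  ``D1`` (MPa^-1) controls the volumetric
    penalty ``(1/D1)(J-1)^2``; the linearised bulk modulus is ``2/D1``.
    When ``D1`` is omitted it is chosen so that bulk/shear = 1000.
    """

    C10: float
    C01: float
    C20: float
    C11: float
    C02: float
    D1: float | None = None
    density: float = DENSITY_WALL

    def __post_init__(self):
        if self.shear_modulus <= 0.0:
            raise MaterialError(
                f"initial shear modulus 2*(C10+C01) = {self.shear_modulus:g} must be > 0"
            )
        if self.D1 is None:
            kappa = DEFAULT_BULK_TO_SHEAR * self.shear_modulus
            object.__setattr__(self, "D1", 2.0 / kappa)
        if self.D1 <= 0.0:
            raise MaterialError(f"D1 = {self.D1:g} must be > 0")
        if self.density <= 0.0:
            raise MaterialError(f"density = {self.density:g} must be > 0")

    @property
    def shear_modulus(self) -> float:
        """Small-strain (initial) shear modulus mu0 = 2(C10 + C01), MPa."""
        return 2.0 * (self.C10 + self.C01)

    @property
    def bulk_modulus(self) -> float:
        """Linearised bulk modulus of the penalty term, kappa = 2/D1, MPa."""
        return 2.0 / self.D1

    @property
    def youngs_modulus(self) -> float:
        """Small-strain Young's modulus in the incompressible limit, 6(C10+C01)."""
        return 3.0 * self.shear_modulus

    @property
    def p_wave_modulus(self) -> float:
        """Dilatational (P-wave) modulus kappa + 4 mu / 3, MPa."""
        return self.bulk_modulus + 4.0 * self.shear_modulus / 3.0


@dataclass(frozen=True)
class LinearElastic:
    """Isotropic linear-elastic solid (St. Venant-Kirchhoff at finite strain)."""

    E: float
    nu: float
    density: float = DENSITY_MARROW

    def __post_init__(self):
        if self.E <= 0.0:
            raise MaterialError(f"Young's modulus E = {self.E:g} must be > 0")
        if not (-1.0 < self.nu < 0.5):
            raise MaterialError(f"Poisson ratio nu = {self.nu:g} must lie in (-1, 0.5)")
        if self.density <= 0.0:
            raise MaterialError(f"density = {self.density:g} must be > 0")

    @property
    def lame(self) -> tuple[float, float]:
        """Lame parameters (lambda, mu) in MPa."""
        lam = self.E * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))
        mu = self.E / (2.0 * (1.0 + self.nu))
        return lam, mu

    @property
    def shear_modulus(self) -> float:
        return self.lame[1]

    @property
    def bulk_modulus(self) -> float:
        lam, mu = self.lame
        return lam + 2.0 * mu / 3.0

    @property
    def p_wave_modulus(self) -> float:
        lam, mu = self.lame
        return lam + 2.0 * mu


class IgnoredMaterial:
    """Sentinel for tissue whose stiffness is neglected (sinusoid endothelium)."""

    def __repr__(self):  # pragma: no cover - trivial
        return "IGNORED"


IGNORED = IgnoredMaterial()

MaterialModel = Union[MooneyRivlin5, LinearElastic, IgnoredMaterial]


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

@dataclass
class Deformation:
    """Deformation state described by the gradient F (dimensionless).

    Accepts a single 3x3 matrix or a batch of shape (..., 3, 3).
    """

    F: np.ndarray

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape[-2:] != (3, 3):
            raise ValueError("F must have shape (..., 3, 3)")

    @property
    def J(self) -> np.ndarray:
        return np.linalg.det(self.F)

    @property
    def C(self) -> np.ndarray:
        """Right Cauchy-Green tensor F^T F."""
        return np.swapaxes(self.F, -1, -2) @ self.F

    @property
    def invariants(self) -> tuple[np.ndarray, np.ndarray]:
        """Plain invariants (I1, I2) of C (sums of squared principal stretches)."""
        C = self.C
        I1 = np.trace(C, axis1=-2, axis2=-1)
        trC2 = np.trace(C @ C, axis1=-2, axis2=-1)
        I2 = 0.5 * (I1**2 - trC2)
        return I1, I2

    @property
    def principal_stretches(self) -> np.ndarray:
        """Principal stretches lambda_i (descending), from the spectrum of C."""
        w = np.linalg.eigvalsh(self.C)
        return np.sqrt(w[..., ::-1])


def _as_F(deformation) -> np.ndarray:
    if isinstance(deformation, Deformation):
        return deformation.F
    F = np.asarray(deformation, dtype=float)
    if F.shape[-2:] != (3, 3):
        raise ValueError("deformation gradient must have shape (..., 3, 3)")
    return F


def _check_positive_J(J):
    if np.any(J <= 0.0):
        bad = np.min(J)
        raise InvertedElementError(f"det F must be positive (min J = {bad:g})")


def _isochoric_invariants(F):
    """Return (J, I1b, I2b, C) for a batch of deformation gradients."""
    J = np.linalg.det(F)
    _check_positive_J(J)
    C = np.swapaxes(F, -1, -2) @ F
    I1 = np.trace(C, axis1=-2, axis2=-1)
    trC2 = np.trace(C @ C, axis1=-2, axis2=-1)
    I2 = 0.5 * (I1**2 - trC2)
    I1b = J ** (-2.0 / 3.0) * I1
    I2b = J ** (-4.0 / 3.0) * I2
    return J, I1b, I2b, C


def _mr_dW(mat: MooneyRivlin5, I1b, I2b):
    """Partial derivatives of the deviatoric energy w.r.t. the isochoric invariants."""
    b1 = I1b - 3.0
    b2 = I2b - 3.0
    W1 = mat.C10 + 2.0 * mat.C20 * b1 + mat.C11 * b2
    W2 = mat.C01 + mat.C11 * b1 + 2.0 * mat.C02 * b2
    return W1, W2


# ---------------------------------------------------------------------------
# Mooney-Rivlin energy and stress
# ---------------------------------------------------------------------------

def mr_strain_energy(deformation, mat: MooneyRivlin5, *, include_volumetric: bool = True):
    """Strain-energy density W (MPa) of the 5-parameter Mooney-Rivlin model.

    ``W = 0`` in the reference configuration.  ``include_volumetric=False``
    returns only the deviatoric polynomial (useful under exact
    incompressibility where the penalty is identically zero).
    """
    F = _as_F(deformation)
    J, I1b, I2b, _ = _isochoric_invariants(F)
    b1 = I1b - 3.0
    b2 = I2b - 3.0
    W = (
        mat.C10 * b1
        + mat.C01 * b2
        + mat.C20 * b1**2
        + mat.C11 * b1 * b2
        + mat.C02 * b2**2
    )
    if include_volumetric:
        W = W + (1.0 / mat.D1) * (J - 1.0) ** 2
    return W if W.ndim else float(W)


def mr_deviatoric_first_pk(deformation, mat: MooneyRivlin5):
    """First Piola-Kirchhoff stress of the deviatoric (isochoric) energy only."""
    F = _as_F(deformation)
    J, I1b, I2b, C = _isochoric_invariants(F)
    W1, W2 = _mr_dW(mat, I1b, I2b)
    Finv = np.linalg.inv(F)
    FinvT = np.swapaxes(Finv, -1, -2)
    I1 = J ** (2.0 / 3.0) * I1b
    # d(I1b)/dF = 2 J^{-2/3} F - (2/3) I1b F^{-T}
    dI1b = 2.0 * J[..., None, None] ** (-2.0 / 3.0) * F - (2.0 / 3.0) * I1b[..., None, None] * FinvT
    # d(I2b)/dF = J^{-4/3} (2 I1 F - 2 F C) - (4/3) I2b F^{-T}
    dI2b = (
        J[..., None, None] ** (-4.0 / 3.0) * (2.0 * I1[..., None, None] * F - 2.0 * F @ C)
        - (4.0 / 3.0) * I2b[..., None, None] * FinvT
    )
    return W1[..., None, None] * dI1b + W2[..., None, None] * dI2b


def mr_volumetric_dUdJ(J, mat: MooneyRivlin5):
    """dU/dJ of the volumetric penalty U(J) = (1/D1)(J-1)^2."""
    return (2.0 / mat.D1) * (np.asarray(J, dtype=float) - 1.0)


def mr_first_pk(deformation, mat: MooneyRivlin5):
    """Total first Piola-Kirchhoff stress P = dW/dF (MPa)."""
    F = _as_F(deformation)
    J = np.linalg.det(F)
    _check_positive_J(J)
    Finv = np.linalg.inv(F)
    FinvT = np.swapaxes(Finv, -1, -2)
    P = mr_deviatoric_first_pk(F, mat)
    P = P + (mr_volumetric_dUdJ(J, mat) * J)[..., None, None] * FinvT
    return P


def mr_cauchy_stress(deformation, mat: MooneyRivlin5):
    """Cauchy stress tensor (MPa); symmetric, zero at F = identity.

    Obtained by pushing the strain-energy derivative forward:
    ``sigma = P F^T / J``.  The result is symmetrised to remove floating
    point asymmetry of order machine epsilon.
    """
    F = _as_F(deformation)
    J = np.linalg.det(F)
    _check_positive_J(J)
    P = mr_first_pk(F, mat)
    sigma = P @ np.swapaxes(F, -1, -2) / J[..., None, None]
    return 0.5 * (sigma + np.swapaxes(sigma, -1, -2))


# ---------------------------------------------------------------------------
# Linear elasticity
# ---------------------------------------------------------------------------

def linear_stress(strain, mat: LinearElastic):
    """Small-strain Hooke stress from a symmetric strain tensor.

    Inverts the compliance relations ``eps_i = (sigma_i - nu (sigma_j +
    sigma_k)) / E`` and adds the shear terms ``sigma_ij = E/(1+nu) eps_ij``.
    """
    if mat.nu == 0.5:
        raise MaterialError("nu = 0.5 exactly makes the compliance singular")
    eps = np.asarray(strain, dtype=float)
    if eps.shape[-2:] != (3, 3):
        raise ValueError("strain must have shape (..., 3, 3)")
    lam, mu = mat.lame
    tr = np.trace(eps, axis1=-2, axis2=-1)
    eye = np.eye(3)
    return lam * tr[..., None, None] * eye + 2.0 * mu * eps


def svk_strain_energy(deformation, mat: LinearElastic):
    """St. Venant-Kirchhoff energy density: the finite-strain extension of Hooke."""
    F = _as_F(deformation)
    E = 0.5 * (np.swapaxes(F, -1, -2) @ F - np.eye(3))
    lam, mu = mat.lame
    trE = np.trace(E, axis1=-2, axis2=-1)
    W = 0.5 * lam * trE**2 + mu * np.einsum("...ij,...ij->...", E, E)
    return W if W.ndim else float(W)


def svk_first_pk(deformation, mat: LinearElastic):
    """First Piola-Kirchhoff stress of the St. Venant-Kirchhoff model, P = F S."""
    F = _as_F(deformation)
    E = 0.5 * (np.swapaxes(F, -1, -2) @ F - np.eye(3))
    lam, mu = mat.lame
    trE = np.trace(E, axis1=-2, axis2=-1)
    S = lam * trE[..., None, None] * np.eye(3) + 2.0 * mu * E
    return F @ S


# ---------------------------------------------------------------------------
# Scalar reduction
# ---------------------------------------------------------------------------

def von_mises(stress):
    """Von Mises equivalent stress sqrt(3/2 dev(sigma):dev(sigma)).

    Rotation invariant, zero for hydrostatic states; equals ``|s|`` for a
    uniaxial stress ``s`` and ``sqrt(3) tau`` for pure shear ``tau``.
    """
    s = np.asarray(stress, dtype=float)
    if s.shape[-2:] != (3, 3):
        raise ValueError("stress must have shape (..., 3, 3)")
    tr = np.trace(s, axis1=-2, axis2=-1)
    dev = s - (tr / 3.0)[..., None, None] * np.eye(3)
    vm = np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))
    return vm if vm.ndim else float(vm)


# ---------------------------------------------------------------------------
# Table of tissue defaults
# ---------------------------------------------------------------------------

def material_from_table(component: str) -> MaterialModel:
    """Default material for a tissue tag.

    Tags: ``arteriole_wall``, ``artery_wall`` (5-parameter Mooney-Rivlin
    with the published wall coefficients), ``marrow`` (linear elastic,
    E = 10 kPa), ``blood`` (mass-only: near-zero stiffness with blood
    density), ``sinus_wall`` (ignored sentinel).
    """
    tag = component.strip().lower()
    if tag in ("arteriole_wall", "artery_wall", "wall"):
        return MooneyRivlin5(**ARTERY_WALL_COEFFICIENTS, density=DENSITY_WALL)
    if tag == "marrow":
        return LinearElastic(E=0.01, nu=0.45, density=DENSITY_MARROW)
    if tag == "blood":
        # "Mass only": a placeholder stiffness 1e-4 MPa keeps the element
        # block non-singular while contributing negligible resistance.
        return LinearElastic(E=1e-4, nu=0.3, density=DENSITY_BLOOD)
    if tag == "sinus_wall":
        return IGNORED
    raise MaterialError(f"unknown tissue tag {component!r}")


def with_overrides(mat: MaterialModel, **kwargs) -> MaterialModel:
    """Return a copy of a material with some coefficients replaced."""
    if isinstance(mat, IgnoredMaterial):
        if kwargs:
            raise MaterialError("cannot override coefficients of an ignored material")
        return mat
    return replace(mat, **kwargs)
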