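"""Constitutive models: nearly incompressible neo-Hookean graft and
isotropic linear-elastic cancellous bone.

The graft strain-energy density is

    Psi(F) = (1 / 2D) * ln(J)^2  +  C1 * (I1bar - 3)  +  F2(lambda)

with J = det F, I1bar = J^(-2/3) tr(F^T F) the first invariant of the
modified right Cauchy-Green tensor, and lambda the stretch along the
collagen-fibre direction.  Defaults C1 = 1.95 MPa and D = 0.00683 1/MPa
(bulk modulus k = 1/D ~ 146 MPa) give a soft, nearly incompressible
matrix.  A variant with the isochoric term C1*(I1bar^2 - 3) is available
behind ``squared_invariant`` for sensitivity checks; the transversely
isotropic fibre term is a standard toe-region exponential family,
disabled by default because its constants are application-supplied.

Cancellous bone is isotropic linear elastic, E = 389 MPa, nu = 0.3.
Stresses are MPa throughout; strains are dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InvertedConfigurationError, ValidationError

__all__ = [
    "LinearElasticParams",
    "NeoHookeanParams",
    "FiberTerm",
    "DeformationState",
    "strain_energy_density",
    "cauchy_stress_hyper",
    "small_strain_stress",
    "fiber_stretch",
    "pk2_stress",
    "material_tangent",
]


@dataclass(frozen=True)
class LinearElasticParams:
    """Isotropic linear elasticity for cancellous bone (MPa)."""

    E: float = 389.0
    nu: float = 0.3

    def __post_init__(self):
        if not self.E > 0.0:
            raise ValidationError("E must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValidationError("nu must lie in (-1, 0.5)")

    @property
    def lame_lambda(self) -> float:
        return self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))

    @property
    def lame_mu(self) -> float:
        return self.E / (2.0 * (1 + self.nu))


@dataclass(frozen=True)
class FiberTerm:
    """Toe-region fibre stress family for the transversely isotropic term.

    No compressive resistance below lambda = 1; exponential toe up to
    ``lam_star``; linear beyond, C1-continuous.  Energy:

        F2(lambda) = c3 * (exp(c4*(lambda-1)) - c4*(lambda-1) - 1) / c4^2

    for 1 < lambda < lam_star, with quadratic/linear continuation above.
    Constants are user-supplied; the term is disabled by default.
    """

    enabled: bool = False
    c3: float = 0.0        # MPa
    c4: float = 0.0        # dimensionless exponent
    lam_star: float = 1.1  # toe-to-linear transition stretch

    def energy(self, lam):
        lam = np.asarray(lam, dtype=float)
        if not self.enabled:
            return np.zeros_like(lam)
        out = np.zeros_like(lam)
        toe = (lam > 1.0) & (lam < self.lam_star)
        e = self.c4 * (lam - 1.0)
        out = np.where(
            toe, self.c3 * (np.exp(e) - e - 1.0) / self.c4**2, out
        )
        lin = lam >= self.lam_star
        es = self.c4 * (self.lam_star - 1.0)
        psi_s = self.c3 * (math.exp(es) - es - 1.0) / self.c4**2
        dpsi_s = self.c3 * (math.exp(es) - 1.0) / self.c4
        out = np.where(lin, psi_s + dpsi_s * (lam - self.lam_star)
                       + 0.0 * lam, out)
        return out

    def dpsi_dlam(self, lam):
        lam = np.asarray(lam, dtype=float)
        if not self.enabled:
            return np.zeros_like(lam)
        out = np.zeros_like(lam)
        toe = (lam > 1.0) & (lam < self.lam_star)
        e = self.c4 * (lam - 1.0)
        out = np.where(toe, self.c3 * (np.exp(e) - 1.0) / self.c4, out)
        es = self.c4 * (self.lam_star - 1.0)
        dpsi_s = self.c3 * (math.exp(es) - 1.0) / self.c4
        out = np.where(lam >= self.lam_star, dpsi_s, out)
        return out


@dataclass(frozen=True)
class NeoHookeanParams:
    """Graft constitutive constants: C1 (MPa), D (1/MPa), fibre direction."""

    C1: float = 1.95
    D: float = 0.00683
    fiber_direction: tuple = (0.0, 0.0, 1.0)
    fiber_term: FiberTerm = field(default_factory=FiberTerm)
    squared_invariant: bool = False   # literal C1*(I1bar^2 - 3) variant

    def __post_init__(self):
        if not self.C1 > 0.0:
            raise ValidationError("C1 must be positive")
        if not self.D > 0.0:
            raise ValidationError("D must be positive")
        a = np.asarray(self.fiber_direction, dtype=float)
        if abs(np.linalg.norm(a) - 1.0) > 1e-10:
            raise ValidationError("fiber_direction must be a unit vector")

    @property
    def k(self) -> float:
        """Bulk modulus, MPa (k * D = 1 identically)."""
        return 1.0 / self.D


@dataclass(frozen=True)
class DeformationState:
    """Kinematic quantities of a deformation gradient F."""

    F: np.ndarray
    J: float
    I1bar: float
    lam: float

    @classmethod
    def from_F(cls, F, fiber_direction=(0.0, 0.0, 1.0)) -> "DeformationState":
        F = np.asarray(F, dtype=float)
        J = float(np.linalg.det(F))
        if J <= 0.0:
            raise InvertedConfigurationError(f"det F = {J} <= 0")
        I1bar = J ** (-2.0 / 3.0) * float(np.trace(F.T @ F))
        lam = fiber_stretch(F, fiber_direction)
        return cls(F=F, J=J, I1bar=I1bar, lam=lam)


def fiber_stretch(F, direction) -> float:
    """Stretch of the fibre direction: lambda = |F a| for unit a."""
    a = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(a) - 1.0) > 1e-10:
        raise ValidationError("fibre direction must be a unit vector")
    return float(np.linalg.norm(np.asarray(F, float) @ a))


def strain_energy_density(F, params: NeoHookeanParams) -> float:
    """Psi(F) in MPa; zero at the reference state with fibres disabled."""
    st = DeformationState.from_F(F, params.fiber_direction)
    vol = math.log(st.J) ** 2 / (2.0 * params.D)
    if params.squared_invariant:
        iso = params.C1 * (st.I1bar**2 - 3.0)
    else:
        iso = params.C1 * (st.I1bar - 3.0)
    fib = float(params.fiber_term.energy(st.lam))
    return vol + iso + fib


# ------------------------------------------------- batched stress / tangent

def _inv_sym33(C):
    """Explicit inverse of batched symmetric 3x3 matrices (adjugate)."""
    det = np.linalg.det(C)
    inv = np.empty_like(C)
    c = C
    inv[..., 0, 0] = c[..., 1, 1] * c[..., 2, 2] - c[..., 1, 2] * c[..., 2, 1]
    inv[..., 0, 1] = c[..., 0, 2] * c[..., 2, 1] - c[..., 0, 1] * c[..., 2, 2]
    inv[..., 0, 2] = c[..., 0, 1] * c[..., 1, 2] - c[..., 0, 2] * c[..., 1, 1]
    inv[..., 1, 0] = inv[..., 0, 1]
    inv[..., 1, 1] = c[..., 0, 0] * c[..., 2, 2] - c[..., 0, 2] * c[..., 2, 0]
    inv[..., 1, 2] = c[..., 0, 2] * c[..., 1, 0] - c[..., 0, 0] * c[..., 1, 2]
    inv[..., 2, 0] = inv[..., 0, 2]
    inv[..., 2, 1] = inv[..., 1, 2]
    inv[..., 2, 2] = c[..., 0, 0] * c[..., 1, 1] - c[..., 0, 1] * c[..., 1, 0]
    return inv / det[..., None, None]


def pk2_stress(C, params: NeoHookeanParams, fiber_dirs=None) -> np.ndarray:
    """Second Piola-Kirchhoff stress S(C) for batched right Cauchy-Green
    tensors C of shape (..., 3, 3).

    ``fiber_dirs`` (broadcastable to (..., 3)) overrides the single fibre
    direction in ``params``; in the pipeline each graft element's fibre
    follows the extrusion path tangent.
    """
    C = np.asarray(C, dtype=float)
    detC = np.linalg.det(C)
    if np.any(detC <= 0.0):
        raise InvertedConfigurationError("det C <= 0 in stress evaluation")
    J = np.sqrt(detC)
    Cinv = _inv_sym33(C)
    trC = np.trace(C, axis1=-2, axis2=-1)
    I = np.broadcast_to(np.eye(3), C.shape)
    Jm23 = J ** (-2.0 / 3.0)
    dev = I - (trC / 3.0)[..., None, None] * Cinv
    if params.squared_invariant:
        I1bar = Jm23 * trC
        S_iso = 4.0 * params.C1 * (I1bar * Jm23)[..., None, None] * dev
    else:
        S_iso = 2.0 * params.C1 * Jm23[..., None, None] * dev
    S_vol = (np.log(J) / params.D)[..., None, None] * Cinv
    S = S_iso + S_vol
    if params.fiber_term.enabled:
        if fiber_dirs is None:
            a = np.asarray(params.fiber_direction, float)
        else:
            a = np.asarray(fiber_dirs, float)
        a = np.broadcast_to(a, C.shape[:-1])
        lam2 = np.einsum("...i,...ij,...j->...", a, C, a)
        lam = np.sqrt(lam2)
        coef = params.fiber_term.dpsi_dlam(lam) / lam
        S = S + coef[..., None, None] * np.einsum("...i,...j->...ij", a, a)
    return S


def material_tangent(C, params: NeoHookeanParams, fiber_dirs=None,
                     h: float = 1e-7):
    """dS/dE as a batched fourth-order tensor (..., 3, 3, 3, 3), by central
    differences of the analytic PK2 stress with respect to the Green strain
    (dC = 2 dE); uniform across material variants."""
    C = np.asarray(C, dtype=float)
    out = np.empty(C.shape + (3, 3))
    for (m, n) in [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]:
        dC = np.zeros((3, 3))
        dC[m, n] += h
        dC[n, m] += h          # symmetric perturbation: dE_mn = dE_nm = h/2
        Sp = pk2_stress(C + dC, params, fiber_dirs)
        Sm = pk2_stress(C - dC, params, fiber_dirs)
        dS_dE = (Sp - Sm) / (2.0 * h)    # dE contribution: dC = 2 dE
        out[..., m, n] = dS_dE
        out[..., n, m] = dS_dE
    return out


def cauchy_stress_hyper(F, params: NeoHookeanParams) -> np.ndarray:
    """Cauchy stress sigma = J^-1 F S F^T, MPa; symmetric, zero at F = I
    (fibres off)."""
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvertedConfigurationError(f"det F = {J} <= 0")
    S = pk2_stress(F.T @ F, params)
    sig = (F @ S @ F.T) / J
    return 0.5 * (sig + sig.T)


def cauchy_stress_batch(F, params: NeoHookeanParams,
                        fiber_dirs=None) -> np.ndarray:
    """Batched Cauchy stress for F of shape (..., 3, 3)."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    C = np.einsum("...ki,...kj->...ij", F, F)
    S = pk2_stress(C, params, fiber_dirs)
    sig = np.einsum("...ik,...kl,...jl->...ij", F, S, F) / J[..., None, None]
    return 0.5 * (sig + np.swapaxes(sig, -1, -2))


def small_strain_stress(strain, params: LinearElasticParams) -> np.ndarray:
    """Hooke's law sigma = lambda tr(eps) I + 2 mu eps (MPa)."""
    eps = np.asarray(strain, dtype=float)
    if not np.all(np.isfinite(eps)):
        raise DomainError("strain must be finite")
    if np.max(np.abs(eps - np.swapaxes(eps, -1, -2))) > 1e-10:
        raise ValidationError("strain tensor must be symmetric")
    lam, mu = params.lame_lambda, params.lame_mu
    tr = np.trace(eps, axis1=-2, axis2=-1)
    I = np.broadcast_to(np.eye(3), eps.shape)
    return lam * tr[..., None, None] * I + 2.0 * mu * eps
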