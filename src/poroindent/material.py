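"""Fibril-reinforced poroelastic (FRPE) constitutive model for articular cartilage.

The total stress at a material point splits into three constituents,

    sigma_t = sigma_nf + sigma_f - p I,

where ``sigma_nf`` is the stress of the porous hyperelastic non-fibrillar
matrix (the proteoglycan gel), ``sigma_f`` the tension-only stress of the
collagen fibril network, and ``p`` the pore-fluid pressure.

Five parameters are fitted per specimen:

======  ==========================================  =====================
name    meaning                                     units
======  ==========================================  =====================
Ef0     initial (strain-independent) fibril
        network modulus                             MPa
EfEps   strain-dependent fibril network modulus     MPa
Enf     non-fibrillar matrix modulus                MPa
k0      initial hydraulic permeability              1e-15 m^4 N^-1 s^-1
M       permeability strain-dependency exponent     --
======  ==========================================  =====================

Internally the package works in MPa / mm / s / N; permeability converts as
1e-15 m^4 N^-1 s^-1 == 1e-3 mm^4 N^-1 s^-1 (see :data:`K_USER_TO_INTERNAL`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .exceptions import DegenerateDeformationError

__all__ = [
    "FRPEParameters",
    "ConstitutiveConstants",
    "StrainState",
    "StressDecomposition",
    "fibril_stress",
    "nonfibrillar_stress",
    "permeability",
    "total_stress",
    "lame_parameters",
    "K_USER_TO_INTERNAL",
]

#: 1e-15 m^4 N^-1 s^-1 expressed in mm^4 N^-1 s^-1.
K_USER_TO_INTERNAL = 1.0e-3


@dataclass(frozen=True)
class FRPEParameters:
    """The five fitted FRPE constituent parameters.

    ``k0`` is stored in the conventional reporting unit 1e-15 m^4 N^-1 s^-1;
    use :attr:`k0_internal` inside the solver.
    """

    Ef0: float  # MPa
    EfEps: float  # MPa
    Enf: float  # MPa
    k0: float  # 1e-15 m^4/(N s)
    M: float  # dimensionless

    def __post_init__(self):
        if not all(np.isfinite(self.as_array())):
            raise ValueError("FRPE parameters must be finite")
        if self.Ef0 < 0 or self.EfEps < 0 or self.M < 0:
            raise ValueError("Ef0, EfEps and M must be non-negative")
        if self.Enf <= 0 or self.k0 <= 0:
            raise ValueError("Enf and k0 must be positive")

    @property
    def k0_internal(self) -> float:
        """Permeability in mm^4 N^-1 s^-1."""
        return self.k0 * K_USER_TO_INTERNAL

    def as_array(self) -> np.ndarray:
        """Parameter vector in the canonical order (Ef0, EfEps, Enf, k0, M)."""
        return np.array([self.Ef0, self.EfEps, self.Enf, self.k0, self.M])

    @classmethod
    def from_array(cls, x) -> "FRPEParameters":
        Ef0, EfEps, Enf, k0, M = (float(v) for v in x)
        return cls(Ef0=Ef0, EfEps=EfEps, Enf=Enf, k0=k0, M=M)

    @classmethod
    def names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))

    def replace(self, **kw) -> "FRPEParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class ConstitutiveConstants:
    """Fixed constitutive constants that are not fitted.

    nu_nf : Poisson's ratio of the drained non-fibrillar matrix.
    e0    : initial void ratio (fluid/solid volume ratio); the default 4.0
            corresponds to a typical cartilage fluid fraction of 0.8.
    """

    nu_nf: float = 0.42
    e0: float = 4.0

    def __post_init__(self):
        if not 0.0 <= self.nu_nf < 0.5:
            raise ValueError("nu_nf must lie in [0, 0.5)")
        if self.e0 <= 0:
            raise ValueError("e0 must be positive")


@dataclass(frozen=True)
class StrainState:
    """Axisymmetric deformation state at an integration point.

    Stores the non-trivial components of the deformation gradient in
    (r, z, theta) ordering; ``F_tt`` is the hoop stretch.  The void ratio
    follows from volume change of a biphasic mixture with intrinsically
    incompressible constituents: 1 + e = J (1 + e0).
    """

    F_rr: float = 1.0
    F_rz: float = 0.0
    F_zr: float = 0.0
    F_zz: float = 1.0
    F_tt: float = 1.0

    @property
    def F(self) -> np.ndarray:
        return np.array(
            [
                [self.F_rr, self.F_rz, 0.0],
                [self.F_zr, self.F_zz, 0.0],
                [0.0, 0.0, self.F_tt],
            ]
        )

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    def void_ratio(self, e0: float) -> float:
        J = self.J
        if J <= 0:
            raise DegenerateDeformationError(f"volumetric Jacobian {J} <= 0")
        return J * (1.0 + e0) - 1.0

    @classmethod
    def from_small_strain(cls, eps_rr=0.0, eps_zz=0.0, eps_tt=0.0, gamma_rz=0.0):
        """Build a state from infinitesimal strain components (engineering shear)."""
        return cls(
            F_rr=1.0 + eps_rr,
            F_rz=gamma_rz / 2.0,
            F_zr=gamma_rz / 2.0,
            F_zz=1.0 + eps_zz,
            F_tt=1.0 + eps_tt,
        )


@dataclass(frozen=True)
class StressDecomposition:
    """Constituent stresses at a point; ``sigma_t`` is always their exact sum."""

    sigma_nf: np.ndarray
    sigma_f: np.ndarray
    p: float
    sigma_t: np.ndarray = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "sigma_t", total_stress(self.sigma_nf, self.sigma_f, self.p)
        )


def fibril_stress(Ef0, EfEps, eps_f):
    """Tension-only strain-stiffening fibril network stress (MPa).

    sigma_f = (Ef0 + EfEps * eps_f) * eps_f   for eps_f > 0, else 0.

    ``eps_f`` is the nominal strain along the fibril direction.  The law is
    strictly increasing and convex in tension whenever EfEps > 0 and reduces
    to Hooke's law for EfEps = 0.  Accepts scalars or arrays.
    """
    Ef0 = np.asarray(Ef0, dtype=float)
    EfEps = np.asarray(EfEps, dtype=float)
    eps_f = np.asarray(eps_f, dtype=float)
    if not (np.all(np.isfinite(Ef0)) and np.all(np.isfinite(EfEps)) and np.all(np.isfinite(eps_f))):
        raise ValueError("fibril_stress: non-finite input")
    s = np.where(eps_f > 0.0, (Ef0 + EfEps * eps_f) * eps_f, 0.0)
    return s if s.ndim else float(s)


def lame_parameters(E, nu):
    """Lame constants (lambda, mu) from Young's modulus and Poisson's ratio."""
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu


def neo_hookean_cauchy(F, E, nu):
    """Cauchy stress of the compressible Neo-Hookean solid used for the
    non-fibrillar matrix.

    Strain energy  W = mu/2 (I1 - 3) - mu ln J + lambda/2 (ln J)^2, giving

        sigma = [ mu (B - I) + lambda ln(J) I ] / J.

    ``F`` may be (3, 3) or batched (..., 3, 3).
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise DegenerateDeformationError("non-positive Jacobian in Neo-Hookean stress")
    lam, mu = lame_parameters(E, nu)
    B = F @ np.swapaxes(F, -1, -2)
    I = np.eye(3)
    lnJ = np.log(J)[..., None, None]
    return (mu * (B - I) + lam * lnJ * I) / J[..., None, None]


def nonfibrillar_stress(Enf, nu_nf, strain: StrainState) -> np.ndarray:
    """Cauchy stress tensor (MPa) of the porous hyperelastic non-fibrillar matrix.

    Zero at the reference state; its infinitesimal tangent is isotropic
    linear elasticity with modulus ``Enf`` and ratio ``nu_nf``.
    """
    return neo_hookean_cauchy(strain.F, Enf, nu_nf)


def permeability(k0, M, e, e0):
    """Strain-dependent permeability  k = k0 * ((1 + e) / (1 + e0))^M.

    Returned in the same units as ``k0``.  Passes exactly through
    (e0, k0) and decreases under compaction when M > 0.
    """
    e = np.asarray(e, dtype=float)
    if np.any(e <= -1.0) or e0 <= -1.0:
        raise ValueError("void ratios must exceed -1")
    k = k0 * ((1.0 + e) / (1.0 + e0)) ** M
    return k if k.ndim else float(k)


def total_stress(sigma_nf, sigma_f, p):
    """Total stress  sigma_t = sigma_nf + sigma_f - p I  (component-wise exact)."""
    sigma_nf = np.asarray(sigma_nf, dtype=float)
    sigma_f = np.asarray(sigma_f, dtype=float)
    if sigma_nf.shape != sigma_f.shape or sigma_nf.shape[-2:] != (3, 3):
        raise ValueError(
            f"stress tensors must share shape (..., 3, 3); got {sigma_nf.shape} and {sigma_f.shape}"
        )
    return sigma_nf + sigma_f - np.asarray(p)[..., None, None] * np.eye(3)
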