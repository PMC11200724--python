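"""Myocardial constitutive laws.

Passive response: the Holzapfel--Ogden orthotropic hyperelastic strain
energy with an isotropic term, fiber and sheet fiber-stretch terms, and a
fiber--sheet shear coupling term.  The anisotropic ``I4`` terms are
tension-only: collagen-reinforced fiber families do not stiffen in
compression, so they contribute only when the squared stretch exceeds one.

Active response: a length-dependent time-varying-elastance fiber stress.
Tension rises and falls as ``(1 - cos omega)`` over one activation, scaled
by a calcium sigmoid whose half-activation level ``ECa50`` depends on the
effective sarcomere length -- this is how the Frank--Starling effect enters:
a more stretched fiber is more calcium-sensitive and develops more force.

Units follow the cardiac-mechanics convention used throughout the package:
stresses in MPa (= N/mm^2), lengths in mm (sarcomere lengths therefore come
out as e.g. 0.00185 mm = 1.85 um), times in s, concentrations in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "PassiveMaterialParams",
    "ActiveMaterialParams",
    "DeformationInvariants",
    "ActivationState",
    "ConstitutiveError",
    "passive_energy",
    "passive_stress",
    "passive_stress_matrix",
    "effective_sarcomere_length",
    "relaxation_duration",
    "activation_phase",
    "eca50",
    "active_fiber_stress",
]


class ConstitutiveError(ValueError):
    """Inadmissible deformation state or material configuration."""


@dataclass(frozen=True)
class PassiveMaterialParams:
    """Parameters of the passive orthotropic strain energy.

    ``a``-type parameters are stress-like (MPa); ``b``-type parameters are
    dimensionless exponential rates.  Suffix ``f`` = fiber, ``s`` = sheet,
    ``fs`` = fiber--sheet shear coupling.
    """

    a: float
    b: float
    a_f: float
    b_f: float
    a_s: float
    b_s: float
    a_fs: float
    b_fs: float
    tissue_label: str = "ventricle"

    def __post_init__(self) -> None:
        for name in ("a", "b", "a_f", "b_f", "a_s", "b_s", "a_fs", "b_fs"):
            if not getattr(self, name) > 0:
                raise ConstitutiveError(f"passive parameter {name!r} must be > 0")

    @classmethod
    def ventricle(cls) -> "PassiveMaterialParams":
        return cls(a=3.9e-4, b=3.7, a_f=1.9e-3, b_f=14.0, a_s=1.1e-3, b_s=11.0,
                   a_fs=3.6e-7, b_fs=7.8e-4, tissue_label="ventricle")

    @classmethod
    def atrium(cls) -> "PassiveMaterialParams":
        return cls(a=1.0e-3, b=3.1, a_f=4.7e-3, b_f=12.0, a_s=2.7e-3, b_s=9.1,
                   a_fs=9.0e-7, b_fs=6.7e-4, tissue_label="atrium")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ActiveMaterialParams:
    """Parameters of the time-varying-elastance active fiber stress.

    Tmax is the contractility scale (MPa): isometric tension at the longest
    sarcomere length and peak calcium.  Ca0/Ca0max are the peak intracellular
    calcium levels (mM).  B (1/mm) shapes the tension--length relation,
    l0 is the sarcomere length below which no force develops, lr the resting
    sarcomere length.  t0 is the time to peak tension; relaxation lasts
    ``m * l + b_relax`` at sarcomere length l.
    """

    Tmax: float
    Ca0: float
    Ca0max: float
    B: float
    l0: float
    lr: float
    t0: float
    m: float
    b_relax: float
    tissue_label: str = "ventricle"

    def __post_init__(self) -> None:
        if not self.Tmax > 0:
            raise ConstitutiveError("Tmax must be > 0")
        if not (self.lr > self.l0 > 0):
            raise ConstitutiveError("require lr > l0 > 0")
        if not self.t0 > 0:
            raise ConstitutiveError("t0 must be > 0")

    @classmethod
    def ventricle(cls, Tmax: float = 0.2) -> "ActiveMaterialParams":
        return cls(Tmax=Tmax, Ca0=4.35, Ca0max=4.35, B=4750.0, l0=0.00158,
                   lr=0.00185, t0=0.35, m=950.0, b_relax=-1.5,
                   tissue_label="ventricle")

    @classmethod
    def atrium(cls, Tmax: float = 0.1) -> "ActiveMaterialParams":
        return cls(Tmax=Tmax, Ca0=4.35, Ca0max=4.35, B=4750.0, l0=0.00158,
                   lr=0.00185, t0=0.05, m=1048.9, b_relax=-1.5,
                   tissue_label="atrium")

    def with_tmax(self, Tmax: float) -> "ActiveMaterialParams":
        d = asdict(self)
        d["Tmax"] = Tmax
        return ActiveMaterialParams(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DeformationInvariants:
    """Isochoric deformation invariants in the fiber-sheet-normal frame.

    I1: first invariant of the right Cauchy-Green tensor C.
    I4f / I4s: squared fiber / sheet stretch.
    I8fs: fiber-sheet shear coupling invariant.
    Eff: Lagrangian fiber strain, consistent with I4f via Eff=(I4f-1)/2.
    """

    I1: float
    I4f: float
    I4s: float
    I8fs: float

    @property
    def Eff(self) -> float:
        return 0.5 * (self.I4f - 1.0)

    @classmethod
    def identity(cls) -> "DeformationInvariants":
        return cls(I1=3.0, I4f=1.0, I4s=1.0, I8fs=0.0)


@dataclass(frozen=True)
class ActivationState:
    """Snapshot of the active-contraction state at one material point."""

    t: float
    l_eff: float
    tr: float
    omega: float
    ECa50: float
    sigma_active: float


# --------------------------------------------------------------------------
# passive law


def passive_energy(params: PassiveMaterialParams, inv: DeformationInvariants) -> float:
    """Deviatoric strain-energy density (MPa) of the passive orthotropic law.

    The fiber and sheet terms contribute only in tension (I4 > 1).
    """
    if not (inv.I4f > 0 and inv.I4s > 0):
        raise ConstitutiveError("I4f and I4s must be positive")
    a, b = params.a, params.b
    w = (a / (2.0 * b)) * np.exp(b * (inv.I1 - 3.0))
    if not np.isfinite(w):
        raise ConstitutiveError(f"isotropic term overflow at I1={inv.I1}")
    for label, ai, bi, i4 in (("fiber", params.a_f, params.b_f, inv.I4f),
                              ("sheet", params.a_s, params.b_s, inv.I4s)):
        if i4 > 1.0:
            with np.errstate(over="ignore"):
                term = (ai / (2.0 * bi)) * (np.exp(bi * (i4 - 1.0) ** 2) - 1.0)
            if not np.isfinite(term):
                raise ConstitutiveError(f"{label} term overflow at I4={i4}")
            w += term
    shear = (params.a_fs / (2.0 * params.b_fs)) * (
        np.exp(params.b_fs * inv.I8fs ** 2) - 1.0)
    if not np.isfinite(shear):
        raise ConstitutiveError(f"shear term overflow at I8fs={inv.I8fs}")
    return float(w + shear)


def _psi_derivatives(params: PassiveMaterialParams, I1, I4f, I4s, I8fs):
    """dPsi/dI1, dPsi/dI4f, dPsi/dI4s, dPsi/dI8fs (vectorized, tension-only)."""
    p1 = 0.5 * params.a * np.exp(params.b * (np.asarray(I1) - 3.0))
    e4f = np.asarray(I4f) - 1.0
    e4s = np.asarray(I4s) - 1.0
    p4f = np.where(e4f > 0.0, params.a_f * e4f, 0.0) * np.exp(
        params.b_f * np.where(e4f > 0.0, e4f, 0.0) ** 2)
    p4s = np.where(e4s > 0.0, params.a_s * e4s, 0.0) * np.exp(
        params.b_s * np.where(e4s > 0.0, e4s, 0.0) ** 2)
    p8 = params.a_fs * np.asarray(I8fs) * np.exp(params.b_fs * np.asarray(I8fs) ** 2)
    return p1, p4f, p4s, p8


def passive_stress_matrix(params: PassiveMaterialParams, C: np.ndarray) -> np.ndarray:
    """Second Piola-Kirchhoff stress in the fiber-sheet-normal frame.

    Parameters
    ----------
    C : (..., 3, 3) right Cauchy-Green tensor expressed in the local
        orthonormal fiber (0), sheet (1), normal (2) basis, with det C = 1
        (incompressibility is enforced kinematically by the caller).

    Returns
    -------
    (..., 3, 3) stress ``S = 2 dPsi/dC - p C^{-1}`` with the reaction
    pressure ``p`` fixed by the convention that the sheet-normal component
    S_nn vanishes.  Because det C = 1 along every admissible deformation of
    the reduced kinematics, the ``p C^{-1}`` term does no virtual work and
    the convention does not affect equilibrium; it does give S = 0 at the
    identity and makes the fiber component equal the isochoric energy
    gradient, which is what the finite-difference oracles check.
    """
    C = np.asarray(C, dtype=float)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    I4f = C[..., 0, 0]
    I4s = C[..., 1, 1]
    I8fs = C[..., 0, 1]
    if np.any(I4f <= 0) or np.any(I4s <= 0):
        raise ConstitutiveError("I4f and I4s must be positive")
    p1, p4f, p4s, p8 = _psi_derivatives(params, I1, I4f, I4s, I8fs)

    S = np.zeros_like(C)
    eye = np.eye(3)
    S += 2.0 * p1[..., None, None] * eye
    S[..., 0, 0] += 2.0 * p4f
    S[..., 1, 1] += 2.0 * p4s
    S[..., 0, 1] += p8
    S[..., 1, 0] += p8
    if not np.all(np.isfinite(S)):
        raise ConstitutiveError("non-finite passive stress (exponential overflow)")

    Cinv = np.linalg.inv(C)
    p = S[..., 2, 2] / Cinv[..., 2, 2]
    S = S - p[..., None, None] * Cinv
    return S


def passive_stress(params: PassiveMaterialParams, C: np.ndarray) -> np.ndarray:
    """Alias of :func:`passive_stress_matrix` for a single deformation state."""
    return passive_stress_matrix(params, C)


# --------------------------------------------------------------------------
# active law


def effective_sarcomere_length(Eff, lr: float):
    """Effective sarcomere length ``lr * sqrt(2 Eff + 1)`` (mm)."""
    arg = 2.0 * np.asarray(Eff, dtype=float) + 1.0
    if np.any(arg <= 0.0):
        raise ConstitutiveError("2*Eff + 1 must be positive")
    out = lr * np.sqrt(arg)
    return float(out) if np.ndim(Eff) == 0 else out


def relaxation_duration(l, m: float, b_relax: float):
    """Linear sarcomere-length dependence of relaxation time: ``m*l + b`` (s)."""
    tr = m * np.asarray(l, dtype=float) + b_relax
    if np.any(tr <= 0.0):
        raise ConstitutiveError("relaxation duration m*l + b must be positive")
    return float(tr) if np.ndim(l) == 0 else tr


def activation_phase(t, t0: float, tr):
    """Piecewise activation phase omega(t) in radians.

    Rises linearly from 0 to pi over [0, t0], continues from pi to 2*pi over
    the relaxation window [t0, t0 + tr] so that (1 - cos omega) returns to
    zero, and is 0 outside the active window.
    """
    t = np.asarray(t, dtype=float)
    tr = np.asarray(tr, dtype=float)
    if not t0 > 0:
        raise ConstitutiveError("t0 must be > 0")
    rising = np.pi * t / t0
    falling = np.pi * (t - t0 + tr) / np.where(tr > 0, tr, np.inf)
    omega = np.where(t < 0.0, 0.0,
                     np.where(t <= t0, rising,
                              np.where(t < t0 + tr, falling, 0.0)))
    return float(omega) if omega.ndim == 0 else omega


def eca50(params: ActiveMaterialParams, l_eff):
    """Length-dependent calcium sensitivity ``Ca0max / sqrt(exp(B(l-l0)) - 1)``.

    Diverges as l_eff -> l0 from above (no force develops at or below l0);
    callers treat l_eff <= l0 as the zero-force regime rather than an error.
    """
    l_eff = np.asarray(l_eff, dtype=float)
    denom_sq = np.expm1(params.B * (l_eff - params.l0))
    out = np.where(denom_sq > 0.0,
                   params.Ca0max / np.sqrt(np.where(denom_sq > 0, denom_sq, 1.0)),
                   np.inf)
    return float(out) if out.ndim == 0 else out


def active_fiber_stress(t, Eff, params: ActiveMaterialParams):
    """Active fiber stress (MPa) at time ``t`` since activation onset.

    sigma = (Tmax/2) * Ca0^2/(Ca0^2 + ECa50^2) * (1 - cos omega), bounded in
    [0, Tmax]; zero when the effective sarcomere length is at or below l0
    and outside the activation window [0, t0 + tr(l_eff)].
    """
    t = np.asarray(t, dtype=float)
    Eff = np.asarray(Eff, dtype=float)
    arg = 2.0 * Eff + 1.0
    l_eff = params.lr * np.sqrt(np.maximum(arg, 0.0))
    active_len = l_eff > params.l0  # zero-force regime below l0 (also arg <= 0)
    l_safe = np.where(active_len, l_eff, params.lr)
    tr = params.m * l_safe + params.b_relax  # > m*l0 + b by construction when active
    omega = activation_phase(t, params.t0, tr)
    ec = eca50(params, l_safe)
    ca2 = params.Ca0 ** 2
    sigma = 0.5 * params.Tmax * ca2 / (ca2 + ec ** 2) * (1.0 - np.cos(omega))
    sigma = np.where(active_len, sigma, 0.0)
    out = np.where((t >= 0.0), sigma, 0.0)
    return float(out) if out.ndim == 0 else out


def activation_state(t: float, Eff: float, params: ActiveMaterialParams) -> ActivationState:
    """Full diagnostic activation snapshot at one material point."""
    l_eff = effective_sarcomere_length(Eff, params.lr)
    if l_eff <= params.l0:
        return ActivationState(t=t, l_eff=l_eff, tr=np.nan, omega=0.0,
                               ECa50=np.inf, sigma_active=0.0)
    tr = relaxation_duration(l_eff, params.m, params.b_relax)
    return ActivationState(
        t=t, l_eff=l_eff, tr=tr,
        omega=float(activation_phase(t, params.t0, tr)),
        ECa50=float(eca50(params, l_eff)),
        sigma_active=float(active_fiber_stress(t, Eff, params)),
    )
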