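"""Quasi-static equilibrium of the reduced-order LV wall.

Equilibrium is stated as virtual work over the material-point quadrature:
internal work of the passive (orthotropic hyperelastic) plus active (fiber
direction) second Piola-Kirchhoff stresses against the strain variations of
the nine generalized coordinates, balanced by cavity-pressure work,
pericardial spring forces and the ascending-aorta root spring.

The reference configuration is the end-diastolic state: a constant
generalized prestress (the pressure work gradient at the reference EDP)
makes the reference geometry an exact equilibrium at the reference
end-diastolic pressure, mirroring how image-derived cardiac models treat
their in-vivo reference.  Incompressibility is kinematic (det F = 1 by
construction), so no volumetric penalty enters the equilibrium.

Units: generalized forces in N*mm (MPa*mm^3); pressures cross from mmHg to
MPa through ``MMHG_TO_MPA`` exactly once, here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinematics as kin
from .constitutive import (ActiveMaterialParams, PassiveMaterialParams,
                           active_fiber_stress, passive_stress_matrix)
from .kinematics import GeneralizedCoords, InadmissibleState, N_COORDS

__all__ = [
    "MMHG_TO_MPA",
    "SpringSet",
    "EquilibriumSolution",
    "SolverError",
    "deformation_map",
    "internal_virtual_work",
    "external_virtual_work",
    "EquilibriumSolver",
    "solve_equilibrium",
    "aortic_root_displacement",
    "pointwise_state",
]

#: pressure-stress unit bridge, used everywhere pressures meet stresses
MMHG_TO_MPA = 1.333e-4


class SolverError(RuntimeError):
    """Newton iteration failed to converge; carries the diagnostic state."""


@dataclass
class SpringSet:
    """Boundary springs: ascending-aorta root spring and pericardial set.

    ``k_aa`` is the AA spring stiffness (N/mm): 0.5 at baseline, 10 for the
    stiff-aorta scenarios.  Pericardial stiffnesses default to the values
    stored on the mesh (graded apex -> base).  ``root_rest_position`` is the
    rest length offset of the AA spring (mm of root displacement at which
    the spring is unloaded).
    """

    k_aa: float = 0.5
    pericardial_k: np.ndarray | None = None
    root_rest_position: float = 0.0
    #: pericardial stiffening in distension: outward normal displacement is
    #: resisted this many times more strongly than inward motion (the sac
    #: constrains acute dilation but folds compliantly inward); the
    #: transition is smoothed over ``outward_width`` mm to keep the
    #: equilibrium residual differentiable
    outward_factor: float = 8.0
    outward_width: float = 0.1

    def __post_init__(self) -> None:
        if not self.k_aa > 0:
            raise ValueError("k_aa must be > 0")

    def peri_k(self, mesh) -> np.ndarray:
        return self.pericardial_k if self.pericardial_k is not None else mesh.peri_k


@dataclass
class EquilibriumSolution:
    q: GeneralizedCoords
    residual_norm: float
    iterations: int
    pointwise_state: dict


# --------------------------------------------------------------------------
# kinematic and constitutive assembly


def deformation_map(mesh, q: GeneralizedCoords,
                    blend_width: float = kin.DEFAULT_BLEND_WIDTH) -> dict:
    """Per-point kinematics: stretches, fiber-frame invariants and Eff.

    The fiber frame is (fiber, sheet, normal) with the fiber at the local
    helix angle in the wall tangent plane, the sheet along the cross-fiber
    in-plane direction, and the sheet-normal transmural.  Keeping the stiff
    sheet family in-plane matters in a reduced model: a full continuum
    accommodates systolic wall thickening by sheet shear and slippage,
    which diagonal reduced kinematics cannot represent -- a transmural
    sheet axis would let the exponential sheet term penalize physiological
    thickening catastrophically.
    """
    lam_r, lam_c, lam_l = kin.point_stretches(mesh, q, blend_width)
    cf, sf = np.cos(mesh.helix), np.sin(mesh.helix)
    I4f = (cf * lam_c) ** 2 + (sf * lam_l) ** 2
    I4s = (sf * lam_c) ** 2 + (cf * lam_l) ** 2
    I1 = lam_r ** 2 + lam_c ** 2 + lam_l ** 2
    return {
        "lam_r": lam_r, "lam_c": lam_c, "lam_l": lam_l,
        "I1": I1, "I4f": I4f, "I4s": I4s,
        "I8fs": cf * sf * (lam_l ** 2 - lam_c ** 2),
        "Eff": 0.5 * (I4f - 1.0),
        "detF": lam_r * lam_c * lam_l,
    }


def _fiber_frame_C(mesh, lam_r, lam_c, lam_l):
    """Right Cauchy-Green tensor in the fiber/sheet/normal basis, (n,3,3)."""
    cf, sf = np.cos(mesh.helix), np.sin(mesh.helix)
    lc2, ll2, lr2 = lam_c ** 2, lam_l ** 2, lam_r ** 2
    n = lam_r.size
    C = np.zeros((n, 3, 3))
    C[:, 0, 0] = cf ** 2 * lc2 + sf ** 2 * ll2
    C[:, 1, 1] = sf ** 2 * lc2 + cf ** 2 * ll2
    C[:, 2, 2] = lr2
    C[:, 0, 1] = C[:, 1, 0] = cf * sf * (ll2 - lc2)
    return C


def internal_virtual_work(mesh, q: GeneralizedCoords, t: float,
                          passive: PassiveMaterialParams,
                          active: ActiveMaterialParams,
                          blend_width: float = kin.DEFAULT_BLEND_WIDTH,
                          active_scale: float = 1.0,
                          fiber_prestretch: float = 1.1) -> np.ndarray:
    """Generalized internal force (9,): quadrature of S : dE/dq.

    ``t`` is the time since ventricular activation onset (s).  The active
    fiber stress is evaluated at the absolute sarcomere strain: the mesh
    reference is the end-diastolic state, so the fiber stretch is premultiplied
    by ``fiber_prestretch`` (the ED fiber stretch relative to the unloaded
    configuration) before entering the force-length relation.
    """
    (lam_r, lam_c, lam_l), (dlam_r, dlam_c, dlam_l) = kin.point_stretches(
        mesh, q, blend_width, with_derivatives=True)
    C = _fiber_frame_C(mesh, lam_r, lam_c, lam_l)
    S = passive_stress_matrix(passive, C)

    Eff_abs = 0.5 * (fiber_prestretch ** 2 * C[:, 0, 0] - 1.0)
    sigma_a = active_scale * active_fiber_stress(t, Eff_abs, active)

    cf, sf = np.cos(mesh.helix), np.sin(mesh.helix)
    # dC entries (n, 9) through the stretch derivatives
    lc_d = 2.0 * lam_c[:, None] * dlam_c
    ll_d = 2.0 * lam_l[:, None] * dlam_l
    lr_d = 2.0 * lam_r[:, None] * dlam_r
    dC_ff = (cf ** 2)[:, None] * lc_d + (sf ** 2)[:, None] * ll_d
    dC_ss = (sf ** 2)[:, None] * lc_d + (cf ** 2)[:, None] * ll_d
    dC_nn = lr_d
    dC_fs = (cf * sf)[:, None] * (ll_d - lc_d)

    integrand = 0.5 * (
        (S[:, 0, 0] + sigma_a)[:, None] * dC_ff
        + S[:, 1, 1][:, None] * dC_ss
        + S[:, 2, 2][:, None] * dC_nn
        + 2.0 * S[:, 0, 1][:, None] * dC_fs
    )
    return (mesh.quad_volume[:, None] * integrand).sum(axis=0)


def _cavity_volume_gradient(mesh, q: GeneralizedCoords,
                            blend_width: float) -> np.ndarray:
    """Analytic dV/dq (mm^3 per unit coordinate)."""
    _, g = kin.deformed_cavity_volume_raw(mesh, q, blend_width,
                                          with_gradient=True)
    return g * mesh.vol_correction


def _spring_energy(mesh, q: GeneralizedCoords, springs: SpringSet,
                   blend_width: float) -> float:
    """Total boundary-spring energy (N*mm).

    Pericardial springs load only the displacement component along the
    reference outward surface normal: the pericardial sac resists radial
    excursion of the epicardium but lets it slide tangentially, and at the
    apex cap (where the normal is axial) it pins the apex.
    """
    disp = kin.deformed_site_positions(mesh, q, blend_width) \
        - kin.reference_site_positions(mesh)
    un = np.einsum("ij,ij->i", mesh.peri_normal, disp)
    u_peri = (springs.peri_k(mesh) * _outward_energy(
        un, springs.outward_factor, springs.outward_width)).sum()
    d_root = kin.aortic_root_displacement_q(mesh, q) - springs.root_rest_position
    return u_peri + 0.5 * springs.k_aa * d_root ** 2


def _outward_energy(un, factor, w):
    """Per-unit-stiffness energy of the distension-stiffening spring.

    The spring force is the monotone softplus blend
    ``F(u)/k = u + (factor-1) * w * (log(1+exp(u/w)) - log 2)``:
    slope 1 deep inward, ``factor`` in distension, force-free at the
    reference.  The energy is its exact antiderivative (dilogarithm).
    """
    from scipy.special import spence

    x = un / w
    # antiderivative of log(1+exp(x)): -Li2(-e^x) = -spence(1+e^x)
    sp = -spence(1.0 + np.exp(np.minimum(x, 60.0)))
    sp = np.where(x > 60.0, 0.5 * x ** 2 + np.pi ** 2 / 6.0, sp)
    sp0 = -spence(2.0)
    return 0.5 * un ** 2 + (factor - 1.0) * w ** 2 * (
        sp - sp0 - np.log(2.0) * x)


def _outward_force(un, factor, w):
    """d(_outward_energy)/d(un): monotone, smooth, zero at the reference."""
    soft = np.where(un / w > 60.0, un / w,
                    np.log1p(np.exp(np.minimum(un / w, 60.0))))
    return un + (factor - 1.0) * w * (soft - np.log(2.0))


def _spring_gradient(mesh, q: GeneralizedCoords, springs: SpringSet,
                     blend_width: float) -> np.ndarray:
    """Analytic gradient of the boundary-spring energy."""
    pos, dpos = kin.deformed_site_positions(mesh, q, blend_width,
                                            with_derivatives=True)
    disp = pos - kin.reference_site_positions(mesh)
    un = np.einsum("ij,ij->i", mesh.peri_normal, disp)
    dun = np.einsum("ij,ijq->iq", mesh.peri_normal, dpos)
    k = springs.peri_k(mesh)
    f = _outward_force(un, springs.outward_factor, springs.outward_width)
    g = ((k * f)[:, None] * dun).sum(axis=0)
    d_root = kin.aortic_root_displacement_q(mesh, q) - springs.root_rest_position
    g += springs.k_aa * d_root * kin.aortic_root_displacement_gradient(mesh)
    return g


def external_virtual_work(mesh, q: GeneralizedCoords, p_lv: float,
                          springs: SpringSet,
                          p_la: float = 0.0,
                          blend_width: float = kin.DEFAULT_BLEND_WIDTH) -> np.ndarray:
    """Generalized external force (9,): cavity pressure minus spring forces.

    ``p_lv`` in mmHg.  ``p_la`` is accepted for interface symmetry; the
    atrium is lumped into the circulation module and exerts no direct
    traction on the LV wall here.
    """
    g = MMHG_TO_MPA * p_lv * _cavity_volume_gradient(mesh, q, blend_width)
    g -= _spring_gradient(mesh, q, springs, blend_width)
    return g


def aortic_root_displacement(mesh, q: GeneralizedCoords) -> float:
    """Apex-ward displacement (mm) of the aortic-root attachment."""
    return kin.aortic_root_displacement_q(mesh, q)


# --------------------------------------------------------------------------
# Newton solver


class EquilibriumSolver:
    """Damped-Newton equilibrium solver with warm-started Jacobians.

    The characteristic force scale for convergence is the pressure-work
    gradient at the reference state under a 100 mmHg load; the residual
    must drop below ``tol`` times that scale, componentwise-normalized.
    """

    def __init__(self, mesh, passive: PassiveMaterialParams,
                 active: ActiveMaterialParams, springs: SpringSet,
                 edp_reference: float = 11.85,
                 blend_width: float = kin.DEFAULT_BLEND_WIDTH,
                 tol: float = 1e-8, max_iter: int = 40,
                 active_scale: float = 1.0, fiber_prestretch: float = 1.1):
        self.mesh = mesh
        self.passive = passive
        self.active = active
        self.springs = springs
        self.active_scale = active_scale
        self.fiber_prestretch = fiber_prestretch
        self.blend_width = blend_width
        self.tol = tol
        self.max_iter = max_iter
        self._J = None

        g_ref = _cavity_volume_gradient(mesh, GeneralizedCoords.identity(),
                                        blend_width)
        self.scale = np.maximum(np.abs(MMHG_TO_MPA * 100.0 * g_ref), 1.0)
        # constant generalized prestress: reference state balances at the
        # reference end-diastolic pressure
        self.prestress = MMHG_TO_MPA * edp_reference * g_ref
        self.edp_reference = edp_reference

    def residual(self, q: GeneralizedCoords, t: float, p_lv: float) -> np.ndarray:
        r = internal_virtual_work(self.mesh, q, t, self.passive, self.active,
                                  self.blend_width,
                                  active_scale=self.active_scale,
                                  fiber_prestretch=self.fiber_prestretch)
        r -= external_virtual_work(self.mesh, q, p_lv, self.springs,
                                   blend_width=self.blend_width)
        return r + self.prestress

    def _fallback(self, x: np.ndarray, t: float, p_lv: float):
        """Powell hybrid fallback when damped Newton stalls."""
        from scipy.optimize import root as scipy_root

        def fun(z):
            try:
                return self.residual(GeneralizedCoords.from_array(z), t,
                                     p_lv) / self.scale
            except InadmissibleState:
                return np.full(N_COORDS, 1e6)

        sol = scipy_root(fun, x, method="hybr", tol=1e-12)
        self._J = None
        r = self.residual(GeneralizedCoords.from_array(sol.x), t, p_lv)
        return sol.x, r, float(np.max(np.abs(r) / self.scale))

    def _jacobian(self, x: np.ndarray, t: float, p_lv: float,
                  h: float = 1e-6) -> np.ndarray:
        J = np.empty((N_COORDS, N_COORDS))
        for j in range(N_COORDS):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            rp = self.residual(GeneralizedCoords.from_array(xp), t, p_lv)
            rm = self.residual(GeneralizedCoords.from_array(xm), t, p_lv)
            J[:, j] = (rp - rm) / (2.0 * h)
        return J

    def solve(self, t: float, p_lv: float,
              q_guess: GeneralizedCoords | None = None,
              with_state: bool = False) -> EquilibriumSolution:
        x = (q_guess or GeneralizedCoords.identity()).to_array()
        r = self.residual(GeneralizedCoords.from_array(x), t, p_lv)
        norm = np.max(np.abs(r) / self.scale)
        it = 0
        refreshed = self._J is None
        # non-monotone damping: the scaled max-norm may rise transiently on
        # the way into Newton's quadratic phase, so steps are accepted
        # against the worst recent merit, with halving only as a fallback
        history = [norm]
        while norm > self.tol and it < self.max_iter:
            if self._J is None:
                self._J = self._jacobian(x, t, p_lv)
                refreshed = True
            try:
                dx = np.linalg.solve(self._J, -r)
            except np.linalg.LinAlgError:
                self._J = None
                continue
            # cap steps in the stretch-like coordinates for robustness
            cap = np.max(np.abs(dx[1:]) / 0.25)
            if cap > 1.0:
                dx /= cap
            ref_norm = max(history[-4:])
            alpha, best = 1.0, None
            for _ in range(10):
                x_try = x + alpha * dx
                try:
                    r_try = self.residual(GeneralizedCoords.from_array(x_try),
                                          t, p_lv)
                except InadmissibleState:
                    alpha *= 0.5
                    continue
                n_try = np.max(np.abs(r_try) / self.scale)
                # Newton norms can spike transiently before the quadratic
                # phase; accept generously, relying on the step cap and the
                # iteration bound for global control
                if n_try < ref_norm * (1e4 if alpha == 1.0 else 1.0) \
                        or n_try <= self.tol:
                    best = (x_try, r_try, n_try)
                    break
                alpha *= 0.5
            if best is None:
                if not refreshed:
                    self._J = None   # stale Jacobian: refresh and retry
                    refreshed = True
                    continue
                # Powell-dogleg fallback for stalls near stiffness
                # transitions of the boundary springs
                x_f, r_f, n_f = self._fallback(x, t, p_lv)
                if n_f <= self.tol:
                    x, r, norm = x_f, r_f, n_f
                    break
                raise SolverError(
                    f"equilibrium stalled at t={t:.4f}s p={p_lv:.2f}mmHg "
                    f"norm={norm:.3e} q={x}")
            x_new, r_new, n_new = best
            # Broyden rank-1 update keeps the frozen Jacobian useful
            # between full finite-difference refreshes
            dx_acc = x_new - x
            dr = r_new - r
            denom = float(dx_acc @ dx_acc)
            if denom > 0:
                self._J += np.outer(dr - self._J @ dx_acc, dx_acc) / denom
            x, r, norm = x_new, r_new, n_new
            history.append(norm)
            it += 1
            if it % 8 == 0:
                self._J = None   # periodic refresh keeps the quadratic tail
        if norm > self.tol:
            x_f, r_f, n_f = self._fallback(x, t, p_lv)
            if n_f <= self.tol:
                x, r, norm = x_f, r_f, n_f
            else:
                raise SolverError(
                    f"no convergence after {it} iterations at t={t:.4f}s "
                    f"p={p_lv:.2f}mmHg norm={norm:.3e} q={x}")
        q = GeneralizedCoords.from_array(x)
        state = pointwise_state(self.mesh, q, t, self.passive, self.active,
                                self.blend_width,
                                active_scale=self.active_scale,
                                fiber_prestretch=self.fiber_prestretch) \
            if with_state else {}
        return EquilibriumSolution(q=q, residual_norm=float(norm),
                                   iterations=it, pointwise_state=state)

    def cavity_volume(self, q: GeneralizedCoords) -> float:
        from .geometry import cavity_volume

        return cavity_volume(self.mesh, q)


def solve_equilibrium(mesh, t: float, p_lv: float, springs: SpringSet,
                      passive: PassiveMaterialParams,
                      active: ActiveMaterialParams,
                      q_guess: GeneralizedCoords | None = None,
                      **kwargs) -> EquilibriumSolution:
    """One-shot equilibrium solve (see :class:`EquilibriumSolver`)."""
    solver = EquilibriumSolver(mesh, passive, active, springs, **kwargs)
    return solver.solve(t, p_lv, q_guess, with_state=True)


def pointwise_state(mesh, q: GeneralizedCoords, t: float,
                    passive: PassiveMaterialParams,
                    active: ActiveMaterialParams,
                    blend_width: float = kin.DEFAULT_BLEND_WIDTH,
                    active_scale: float = 1.0,
                    fiber_prestretch: float = 1.1) -> dict:
    """Strains, invariants and fiber stresses at every material point.

    ``fiber_stress`` is the Cauchy-equivalent total fiber stress
    ``I4f * (S_ff_passive + sigma_active)`` -- the push-forward of the
    fiber-direction second Piola-Kirchhoff component under det F = 1.
    ``Eff`` is reported relative to the ED reference; the active stress is
    evaluated at the absolute sarcomere strain via ``fiber_prestretch``.
    """
    km = deformation_map(mesh, q, blend_width)
    C = _fiber_frame_C(mesh, km["lam_r"], km["lam_c"], km["lam_l"])
    S = passive_stress_matrix(passive, C)
    Eff_abs = 0.5 * (fiber_prestretch ** 2 * km["I4f"] - 1.0)
    sigma_a = active_scale * active_fiber_stress(t, Eff_abs, active)
    km = dict(km)
    km["S_ff_passive"] = S[:, 0, 0]
    km["sigma_active"] = np.asarray(sigma_a)
    km["fiber_stress"] = km["I4f"] * (S[:, 0, 0] + sigma_a)
    return km
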