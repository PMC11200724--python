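"""Reduced-order deformation ansatz of the LV wall.

The deformation state is a 9-component generalized-coordinate vector:

* ``d_avp`` -- rigid apex-base translation of the ventricle along the long
  axis (mm, positive apex-ward).  The apical pericardial springs keep it
  small; the physiological atrioventricular-plane displacement is carried
  by the longitudinal stretches and reported via the basal-ring motion.
* ``lambda_long`` -- four regional longitudinal stretches (septal,
  anterior, lateral, posterior), blended smoothly around the circumference.
* ``radial_scale`` -- three per-axial-level scale factors of the
  endocardial radius (apical, mid, basal), blended along the axis.
* ``ovality`` -- a cos(2 theta) ellipticity mode of the cross-section.

Through-wall kinematics treat each axial level as a locally cylindrical
incompressible thick shell with longitudinal stretch ``Lambda``: the
deformed radius of a material circle at reference radius R follows

    r'(R)^2 = (rho R_endo)^2 + (R^2 - R_endo^2) / Lambda,

which gives circumferential stretch ``lambda_c = r'/R``, radial stretch
``lambda_r = R / (Lambda r')`` and ``lambda_r lambda_c lambda_l = 1``
exactly (pointwise incompressibility by construction).  Wall thickening is
therefore determined by the cavity-radius scale and the longitudinal
stretch, and is larger at the endocardium -- the transmural strain gradient
seen in real ventricles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneralizedCoords",
    "N_COORDS",
    "circumferential_blend",
    "axial_blend",
    "point_stretches",
    "deformed_cavity_volume_raw",
    "deformed_site_positions",
    "basal_ring_displacement",
    "aortic_root_displacement_q",
]

N_COORDS = 9

#: default half-width (rad) of the linear blend between circumferential regions
DEFAULT_BLEND_WIDTH = 0.5

_REGION_CENTERS = np.array([0.0, 0.5 * np.pi, np.pi, 1.5 * np.pi])
_AXIAL_NODES = np.array([1.0 / 6.0, 0.5, 5.0 / 6.0])


@dataclass
class GeneralizedCoords:
    """Low-dimensional deformation state of the LV wall."""

    d_avp: float = 0.0
    lambda_long: np.ndarray = field(
        default_factory=lambda: np.ones(4))
    radial_scale: np.ndarray = field(
        default_factory=lambda: np.ones(3))
    ovality: float = 0.0

    @classmethod
    def identity(cls) -> "GeneralizedCoords":
        return cls()

    @classmethod
    def from_array(cls, x: np.ndarray) -> "GeneralizedCoords":
        x = np.asarray(x, dtype=float)
        return cls(d_avp=float(x[0]), lambda_long=x[1:5].copy(),
                   radial_scale=x[5:8].copy(), ovality=float(x[8]))

    def to_array(self) -> np.ndarray:
        return np.concatenate(([self.d_avp], self.lambda_long,
                               self.radial_scale, [self.ovality]))

    def is_admissible(self) -> bool:
        return bool(np.all(self.lambda_long > 0.05)
                    and np.all(self.radial_scale > 0.05)
                    and abs(self.ovality) < 0.9)


def circumferential_blend(theta: np.ndarray,
                          blend_width: float = DEFAULT_BLEND_WIDTH) -> np.ndarray:
    """C0 partition of unity over the four circumferential regions.

    Trapezoidal weights: flat inside a region, linear ramps of total width
    ``blend_width`` across region boundaries.
    """
    theta = np.asarray(theta, dtype=float)
    d = np.abs((theta[..., None] - _REGION_CENTERS + np.pi) % (2 * np.pi) - np.pi)
    half = np.pi / 4.0
    w = np.clip((half + 0.5 * blend_width - d) / blend_width, 0.0, 1.0)
    return w / w.sum(axis=-1, keepdims=True)


def axial_blend(zeta: np.ndarray) -> np.ndarray:
    """Piecewise-linear hat weights of the three axial levels at ``zeta``."""
    zeta = np.asarray(zeta, dtype=float)
    w = np.zeros(zeta.shape + (3,))
    z = np.clip(zeta, _AXIAL_NODES[0], _AXIAL_NODES[-1])
    for k in range(2):
        lo, hi = _AXIAL_NODES[k], _AXIAL_NODES[k + 1]
        m = (z >= lo) & (z <= hi)
        t = (z - lo) / (hi - lo)
        w[..., k] += np.where(m, 1.0 - t, 0.0)
        w[..., k + 1] += np.where(m, t, 0.0)
    # interior nodes are counted once from each side at the exact node value
    w /= w.sum(axis=-1, keepdims=True)
    return w


def point_stretches(mesh, q: GeneralizedCoords,
                    blend_width: float = DEFAULT_BLEND_WIDTH,
                    with_derivatives: bool = False):
    """Local (radial, circumferential, longitudinal) stretches at each point.

    Returns ``(lam_r, lam_c, lam_l)`` arrays, plus ``(dlam_r, dlam_c,
    dlam_l)`` of shape (n, 9) with respect to the generalized coordinates
    when ``with_derivatives`` is set.  Raises if the state is inadmissible
    (non-positive stretches anywhere).
    """
    N = circumferential_blend(mesh.theta, blend_width)     # (n, 4)
    M = axial_blend(mesh.zeta)                             # (n, 3)
    Lam = N @ q.lambda_long                                # (n,)
    s_z = M @ q.radial_scale
    c2 = np.cos(2.0 * mesh.theta)
    mod = 1.0 + q.ovality * c2
    rho = s_z * mod

    if np.any(Lam <= 0) or np.any(rho <= 0):
        raise InadmissibleState("non-positive stretch in deformation state")

    Re2 = mesh.R_endo_level ** 2
    R2 = mesh.R ** 2
    A = (rho ** 2) * Re2 + (R2 - Re2) / Lam
    if np.any(A <= 0):
        raise InadmissibleState("inverted wall (r'^2 <= 0)")
    rp = np.sqrt(A)

    lam_c = rp / mesh.R
    lam_l = Lam
    lam_r = 1.0 / (lam_c * lam_l)

    if not with_derivatives:
        return lam_r, lam_c, lam_l

    n = mesh.R.size
    dLam = np.zeros((n, N_COORDS))
    dLam[:, 1:5] = N
    drho = np.zeros((n, N_COORDS))
    drho[:, 5:8] = M * mod[:, None]
    drho[:, 8] = s_z * c2

    dA = (2.0 * rho * Re2)[:, None] * drho \
        - ((R2 - Re2) / Lam ** 2)[:, None] * dLam
    drp = dA / (2.0 * rp)[:, None]
    dlam_c = drp / mesh.R[:, None]
    dlam_l = dLam
    dlam_r = -lam_r[:, None] * (dlam_c / lam_c[:, None] + dlam_l / lam_l[:, None])
    return (lam_r, lam_c, lam_l), (dlam_r, dlam_c, dlam_l)


class InadmissibleState(ValueError):
    """Deformation state outside the admissible range (det F would be <= 0)."""


# --------------------------------------------------------------------------
# deformed configuration: surfaces, sites, attachments


def _deformed_endo_surface(mesh, q: GeneralizedCoords,
                           blend_width: float = DEFAULT_BLEND_WIDTH,
                           with_derivatives: bool = False):
    """Deformed endocardial surface points, shape (n_psi, n_theta, 3).

    With ``with_derivatives``, also returns the analytic position
    derivatives with respect to the generalized coordinates,
    shape (n_psi, n_theta, 3, 9).
    """
    th = mesh.surf_theta
    N = circumferential_blend(th, blend_width)
    Lam = N @ q.lambda_long                                # (n_theta,)
    z_apex = -mesh.c_endo
    zeta = np.clip((mesh.surf_z - z_apex) / mesh.length, 0.0, 1.0)
    M = axial_blend(zeta)
    s_z = M @ q.radial_scale                               # (n_psi,)
    c2 = np.cos(2.0 * th)
    mod = 1.0 + q.ovality * c2                             # (n_theta,)
    r = mesh.surf_R[:, None] * s_z[:, None] * mod[None, :]
    z = z_apex + (mesh.surf_z[:, None] - z_apex) * Lam[None, :] - q.d_avp
    ct, st = np.cos(th), np.sin(th)
    P = np.stack([r * ct[None, :], r * st[None, :], z], axis=-1)
    if not with_derivatives:
        return P

    n_psi, n_th = r.shape
    dP = np.zeros((n_psi, n_th, 3, N_COORDS))
    dP[:, :, 2, 0] = -1.0
    dz_fac = (mesh.surf_z - z_apex)[:, None]
    for j in range(4):
        dP[:, :, 2, 1 + j] = dz_fac * N[None, :, j]
    for k in range(3):
        dr = mesh.surf_R[:, None] * M[:, None, k] * mod[None, :]
        dP[:, :, 0, 5 + k] = dr * ct[None, :]
        dP[:, :, 1, 5 + k] = dr * st[None, :]
    dr_ov = mesh.surf_R[:, None] * s_z[:, None] * c2[None, :]
    dP[:, :, 0, 8] = dr_ov * ct[None, :]
    dP[:, :, 1, 8] = dr_ov * st[None, :]
    return P, dP


def _cross(a, b):
    """Row-wise cross product without np.cross's axis-juggling overhead."""
    c = np.empty_like(a)
    c[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    c[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    c[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return c


def _tri_volume_terms(T1, T2, T3, d1=None, d2=None, d3=None):
    """Sum of p1.(p2 x p3) over triangles, and its q-gradient if derivatives
    are supplied (each T (m,3), each d (m,3,9))."""
    c23 = _cross(T2, T3)
    v = float((T1 * c23).sum())
    if d1 is None:
        return v, None
    g = np.einsum("mi,miq->q", c23, d1)
    g += np.einsum("mi,miq->q", _cross(T3, T1), d2)
    g += np.einsum("mi,miq->q", _cross(T1, T2), d3)
    return v, g


def deformed_cavity_volume_raw(mesh, q: GeneralizedCoords,
                               blend_width: float = DEFAULT_BLEND_WIDTH,
                               with_gradient: bool = False):
    """Volume (mm^3) of the deformed endocardial surface.

    Divergence-theorem sum over the triangulated side wall plus a basal cap;
    callers apply ``mesh.vol_correction`` to remove the discretization bias.
    With ``with_gradient``, also returns the analytic dV/dq (9,).
    """
    if with_gradient:
        P, dP = _deformed_endo_surface(mesh, q, blend_width, True)
    else:
        P = _deformed_endo_surface(mesh, q, blend_width)
        dP = None

    def roll_th(X):
        return np.roll(X, -1, axis=1)

    Pn = roll_th(P)
    A, B, C, D = P[:-1], Pn[:-1], P[1:], Pn[1:]
    flat = lambda X: X.reshape(-1, *X.shape[2:])
    if dP is not None:
        dPn = roll_th(dP)
        dA, dB, dC, dD = dP[:-1], dPn[:-1], dP[1:], dPn[1:]
        v1, g1 = _tri_volume_terms(flat(A), flat(B), flat(D),
                                   flat(dA), flat(dB), flat(dD))
        v2, g2 = _tri_volume_terms(flat(A), flat(D), flat(C),
                                   flat(dA), flat(dD), flat(dC))
    else:
        v1, g1 = _tri_volume_terms(flat(A), flat(B), flat(D))
        v2, g2 = _tri_volume_terms(flat(A), flat(D), flat(C))

    ring = P[-1]
    cen = np.broadcast_to(ring.mean(axis=0), ring.shape)
    ring_n = np.roll(ring, -1, axis=0)
    if dP is not None:
        dring = dP[-1]
        dcen = np.broadcast_to(dring.mean(axis=0), dring.shape)
        v3, g3 = _tri_volume_terms(cen, ring, ring_n, dcen, dring,
                                   np.roll(dring, -1, axis=0))
        v = v1 + v2 + v3
        g = g1 + g2 + g3
        sgn = 1.0 if v >= 0 else -1.0
        return abs(v) / 6.0, sgn * g / 6.0
    v3, _ = _tri_volume_terms(cen, ring, ring_n)
    return abs(v1 + v2 + v3) / 6.0


def deformed_site_positions(mesh, q: GeneralizedCoords,
                            blend_width: float = DEFAULT_BLEND_WIDTH,
                            with_derivatives: bool = False):
    """Deformed positions (n_sites, 3) of the pericardial spring sites.

    Epicardial sites ride on the incompressible-thickness map: their radius
    follows the endocardial scale through the thick-shell relation, their
    height follows the regional longitudinal stretch.  With
    ``with_derivatives``, also returns d(position)/dq, (n_sites, 3, 9).
    """
    th, z, R, Re = mesh.peri_theta, mesh.peri_z, mesh.peri_R, mesh.peri_R_endo
    N = circumferential_blend(th, blend_width)
    Lam = N @ q.lambda_long
    z_apex = -mesh.c_endo
    zeta = np.clip((z - z_apex) / mesh.length, 0.0, 1.0)
    M = axial_blend(zeta)
    s_z = M @ q.radial_scale
    c2 = np.cos(2.0 * th)
    mod = 1.0 + q.ovality * c2
    rho = s_z * mod
    A = (rho * Re) ** 2 + (R ** 2 - Re ** 2) / Lam
    rp = np.sqrt(np.clip(A, 1e-12, None))
    zp = z_apex + (z - z_apex) * Lam - q.d_avp
    ct, st = np.cos(th), np.sin(th)
    pos = np.stack([rp * ct, rp * st, zp], axis=-1)
    if not with_derivatives:
        return pos

    n = th.size
    dpos = np.zeros((n, 3, N_COORDS))
    dpos[:, 2, 0] = -1.0
    dA = np.zeros((n, N_COORDS))
    for j in range(4):
        dA[:, 1 + j] = -(R ** 2 - Re ** 2) / Lam ** 2 * N[:, j]
        dpos[:, 2, 1 + j] = (z - z_apex) * N[:, j]
    for k in range(3):
        dA[:, 5 + k] = 2.0 * rho * Re ** 2 * M[:, k] * mod
    dA[:, 8] = 2.0 * rho * Re ** 2 * s_z * c2
    drp = dA / (2.0 * rp)[:, None]
    dpos[:, 0, :] += drp * ct[:, None]
    dpos[:, 1, :] += drp * st[:, None]
    return pos, dpos


def reference_site_positions(mesh) -> np.ndarray:
    return np.stack([mesh.peri_R * np.cos(mesh.peri_theta),
                     mesh.peri_R * np.sin(mesh.peri_theta),
                     mesh.peri_z], axis=-1)


def basal_ring_displacement(mesh, q: GeneralizedCoords) -> np.ndarray:
    """Apex-ward displacement (mm) of the basal ring at each region center."""
    N = circumferential_blend(_REGION_CENTERS)
    Lam = N @ q.lambda_long
    return q.d_avp + mesh.length * (1.0 - Lam)


def aortic_root_displacement_q(mesh, q: GeneralizedCoords) -> float:
    """Apex-ward displacement (mm) of the aortic-root attachment.

    The root rides on the basal ring: its displacement is the coupling-
    weighted combination of the regional basal-ring displacements, scaled
    by the root-motion ratio (the sino-tubular junction, sitting above the
    annular plane on the compliant root, travels only a fraction of the
    annular excursion).
    """
    from .geometry import CIRC_REGIONS

    u = basal_ring_displacement(mesh, q)
    w = np.array([mesh.root_weights[r] for r in CIRC_REGIONS])
    return float(mesh.root_motion_ratio * (w @ u))


def aortic_root_displacement_gradient(mesh) -> np.ndarray:
    """d(root displacement)/dq, a constant vector (9,)."""
    from .geometry import CIRC_REGIONS

    w = np.array([mesh.root_weights[r] for r in CIRC_REGIONS])
    N = circumferential_blend(_REGION_CENTERS)
    g = np.zeros(N_COORDS)
    g[0] = 1.0
    g[1:5] = -mesh.length * (w @ N)
    return mesh.root_motion_ratio * g
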