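"""Idealized left-ventricular geometry.

A truncated thick-walled prolate ellipsoid stands in for an anatomical LV
mesh: an endocardial ellipsoid of revolution is offset outward by a uniform
wall thickness and truncated by a flat basal plane.  Material points carry
a rule-based transmural fiber architecture (helix angle interpolated
linearly from endocardium to epicardium), a 4 circumferential x 3 axial
region partition, local orthonormal frames and quadrature volumes.

Boundary attachments: 49 pericardial spring sites distributed evenly over
the epicardium with stiffness graded from apex (high) to base (low), and an
aortic-root attachment on the basal ring whose spring force is distributed
over the four circumferential regions by configurable coupling weights
(septal-dominant by default, reflecting the aorto-mitral continuity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LVGeometryConfig",
    "MaterialPoint",
    "LVMesh",
    "GeometryError",
    "build_idealized_lv",
    "assign_fiber_field",
    "pericardial_sites",
    "cavity_volume",
    "truncated_ellipsoid_volume",
    "CIRC_REGIONS",
    "AXIAL_REGIONS",
]

CIRC_REGIONS = ("septal", "anterior", "lateral", "posterior")
AXIAL_REGIONS = ("apical", "mid", "basal")

#: circumferential region centers (rad); septal at theta = 0
REGION_CENTERS = {"septal": 0.0, "anterior": 0.5 * np.pi,
                  "lateral": np.pi, "posterior": 1.5 * np.pi}

DEFAULT_ROOT_WEIGHTS = {"septal": 0.4, "anterior": 0.3,
                        "posterior": 0.2, "lateral": 0.1}


class GeometryError(ValueError):
    """Infeasible geometry configuration or inadmissible deformed surface."""


@dataclass(frozen=True)
class LVGeometryConfig:
    """Configuration of the idealized LV.

    ed_cavity_volume is the end-diastolic cavity volume (mL) of the
    reference configuration.  wall_volume (mL) defaults to the shell
    obtained with a 10 mm uniform wall.  base_to_apex_length (mm) is the
    endocardial long-axis length; truncation_fraction sets where the basal
    plane cuts the ellipsoid (fraction of the long semi-axis above center).
    """

    ed_cavity_volume: float = 158.3
    wall_volume: float | None = None
    base_to_apex_length: float = 85.0
    truncation_fraction: float = 0.4
    wall_thickness: float = 10.0
    n_transmural: int = 3
    n_axial: int = 6
    n_circumferential: int = 12
    endo_helix_angle: float = 60.0
    epi_helix_angle: float = -60.0
    n_pericardial: int = 49
    k_pericardial_apex: float = 5.0
    k_pericardial_base: float = 2.0
    root_weights: dict = field(default_factory=lambda: dict(DEFAULT_ROOT_WEIGHTS))
    root_motion_ratio: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ed_cavity_volume <= 0:
            raise GeometryError("ed_cavity_volume must be positive")
        if self.n_axial < 3 or self.n_circumferential < 4 or self.n_transmural < 2:
            raise GeometryError("need >=3 axial, >=4 circumferential, >=2 transmural")
        if not (0 < self.truncation_fraction < 1):
            raise GeometryError("truncation_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class MaterialPoint:
    """View of one quadrature point of the wall."""

    reference_position: np.ndarray
    fiber_direction: np.ndarray
    sheet_direction: np.ndarray
    normal_direction: np.ndarray
    region: str
    layer: str
    quadrature_volume: float


def truncated_ellipsoid_volume(a: float, c: float, eta: float) -> float:
    """Volume enclosed by an ellipsoid of revolution (equatorial semi-axis
    ``a``, long semi-axis ``c``) truncated by the plane z = eta*c, eta in
    (-1, 1), keeping the part below the plane (apex side)."""
    return np.pi * a * a * c * (2.0 / 3.0 + eta - eta ** 3 / 3.0)


@dataclass
class LVMesh:
    """Material-point cloud with fiber frames, regions and attachments.

    Geometry scalars are in mm / mm^3; volumes exposed in mL where noted.
    The axial material coordinate ``zeta`` runs 0 (apex) -> 1 (base).
    """

    config: LVGeometryConfig
    # ellipsoid parameters (mm)
    a_endo: float
    c_endo: float
    t_wall: float
    z_base: float           # basal plane height (ellipsoid center at z=0)
    length: float           # endocardial apex -> base distance
    wall_volume_mm3: float
    ed_cavity_volume_mm3: float
    # per-point arrays
    theta: np.ndarray
    u: np.ndarray           # transmural coordinate, 0 endo -> 1 epi
    zeta: np.ndarray
    R: np.ndarray           # cylindrical radius of the reference position
    z: np.ndarray
    R_endo_level: np.ndarray  # endocardial radius at the point's height
    quad_volume: np.ndarray
    helix: np.ndarray       # fiber helix angle (rad)
    region_circ: np.ndarray  # int index into CIRC_REGIONS
    region_axial: np.ndarray  # int index into AXIAL_REGIONS
    e_r: np.ndarray         # (n,3) outward wall-normal
    e_c: np.ndarray         # (n,3) circumferential
    e_l: np.ndarray         # (n,3) meridional (toward base)
    # endocardial surface grid for cavity-volume integration
    surf_theta: np.ndarray
    surf_psi: np.ndarray
    surf_R: np.ndarray      # (n_psi,) endo radius per psi row
    surf_z: np.ndarray      # (n_psi,)
    vol_correction: float = 1.0
    # boundary attachments (filled by pericardial_sites)
    peri_theta: np.ndarray | None = None
    peri_zeta: np.ndarray | None = None
    peri_R: np.ndarray | None = None
    peri_z: np.ndarray | None = None
    peri_R_endo: np.ndarray | None = None
    peri_k: np.ndarray | None = None
    peri_normal: np.ndarray | None = None
    root_weights: dict | None = None
    root_motion_ratio: float = 0.8

    @property
    def n_points(self) -> int:
        return self.theta.size

    @property
    def layer(self) -> np.ndarray:
        return np.where(self.u < 0.5, "endo", "epi")

    def point(self, i: int) -> MaterialPoint:
        circ = CIRC_REGIONS[self.region_circ[i]]
        axial = AXIAL_REGIONS[self.region_axial[i]]
        al = self.helix[i]
        f = np.cos(al) * self.e_c[i] + np.sin(al) * self.e_l[i]
        # sheet along the cross-fiber in-plane direction; sheet-normal
        # transmural (see mechanics.deformation_map)
        s = -np.sin(al) * self.e_c[i] + np.cos(al) * self.e_l[i]
        n = self.e_r[i]
        pos = np.array([self.R[i] * np.cos(self.theta[i]),
                        self.R[i] * np.sin(self.theta[i]), self.z[i]])
        return MaterialPoint(reference_position=pos, fiber_direction=f,
                             sheet_direction=s, normal_direction=n,
                             region=f"{circ}-{axial}", layer=str(self.layer[i]),
                             quadrature_volume=float(self.quad_volume[i]))

    @property
    def pericardial_site_records(self) -> list[dict]:
        recs = []
        for i in range(self.peri_theta.size):
            recs.append({
                "position": np.array([self.peri_R[i] * np.cos(self.peri_theta[i]),
                                      self.peri_R[i] * np.sin(self.peri_theta[i]),
                                      self.peri_z[i]]),
                "stiffness": float(self.peri_k[i]),
            })
        return recs

    def to_dataframe(self):
        """Tabular export (positions, frames, labels, volumes) for inspection."""
        import pandas as pd

        x = self.R * np.cos(self.theta)
        y = self.R * np.sin(self.theta)
        al = self.helix
        f = (np.cos(al)[:, None] * self.e_c + np.sin(al)[:, None] * self.e_l)
        return pd.DataFrame({
            "x": x, "y": y, "z": self.z,
            "fiber_x": f[:, 0], "fiber_y": f[:, 1], "fiber_z": f[:, 2],
            "sheet_x": self.e_r[:, 0], "sheet_y": self.e_r[:, 1],
            "sheet_z": self.e_r[:, 2],
            "region_circ": np.asarray(CIRC_REGIONS)[self.region_circ],
            "region_axial": np.asarray(AXIAL_REGIONS)[self.region_axial],
            "layer": self.layer,
            "quad_volume_mm3": self.quad_volume,
        })


# --------------------------------------------------------------------------


def _solve_shape(cfg: LVGeometryConfig):
    """Endocardial semi-axes, wall thickness and basal plane from the config."""
    eta = cfg.truncation_fraction
    c_e = cfg.base_to_apex_length / (1.0 + eta)
    z_b = eta * c_e
    v_target = cfg.ed_cavity_volume * 1000.0  # mL -> mm^3
    a_e = np.sqrt(v_target / (np.pi * c_e * (2.0 / 3.0 + eta - eta ** 3 / 3.0)))

    def shell_volume(t):
        eta_epi = z_b / (c_e + t)
        v_epi = truncated_ellipsoid_volume(a_e + t, c_e + t, eta_epi)
        return v_epi - v_target

    if cfg.wall_volume is None:
        t = cfg.wall_thickness
        wall_mm3 = shell_volume(t)
    else:
        wall_mm3 = cfg.wall_volume * 1000.0
        try:
            t = brentq(lambda t: shell_volume(t) - wall_mm3, 1e-3, 60.0)
        except ValueError as exc:
            raise GeometryError("infeasible wall/cavity combination") from exc
    if a_e <= 0 or t <= 0:
        raise GeometryError("infeasible wall/cavity combination")
    return a_e, c_e, t, z_b, wall_mm3


def _frames(psi, theta, a, c):
    """Orthonormal (outward-normal, circumferential, meridional) triads."""
    e_c = np.stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)], axis=-1)
    ml = np.stack([a * np.cos(psi) * np.cos(theta),
                   a * np.cos(psi) * np.sin(theta),
                   c * np.sin(psi)], axis=-1)
    e_l = ml / np.linalg.norm(ml, axis=-1, keepdims=True)
    e_r = np.cross(e_c, e_l)
    return e_r, e_c, e_l


def build_idealized_lv(config: LVGeometryConfig | None = None) -> LVMesh:
    """Construct the idealized LV material-point cloud.

    Deterministic for a fixed ``config.seed`` (the seed rotates the
    circumferential sampling and the pericardial spiral; it does not change
    the continuum geometry).  The reference cavity volume matches
    ``config.ed_cavity_volume`` to well within 0.5%.
    """
    cfg = config or LVGeometryConfig()
    rng = np.random.default_rng(cfg.seed)
    a_e, c_e, t, z_b, wall_mm3 = _solve_shape(cfg)
    length = z_b + c_e

    n_s, n_c, n_t = cfg.n_axial, cfg.n_circumferential, cfg.n_transmural
    theta_off = rng.uniform(0.0, 2.0 * np.pi / n_c)

    s_grid = (np.arange(n_s) + 0.5) / n_s
    th_grid = 2.0 * np.pi * (np.arange(n_c) + 0.5) / n_c + theta_off
    u_grid = (np.arange(n_t) + 0.5) / n_t

    S, TH, U = np.meshgrid(s_grid, th_grid, u_grid, indexing="ij")
    S, TH, U = S.ravel(), TH.ravel(), U.ravel()

    a_u = a_e + U * t
    c_u = c_e + U * t
    psi_max = np.arccos(np.clip(-z_b / c_u, -1.0, 1.0))
    PSI = S * psi_max

    R = a_u * np.sin(PSI)
    Z = -c_u * np.cos(PSI)
    zeta = np.clip((Z + c_e) / length, 0.0, 1.0)

    # endocardial radius at each point's height (0 below the endo apex)
    R_e = np.where(Z >= -c_e,
                   a_e * np.sqrt(np.clip(1.0 - (Z / c_e) ** 2, 0.0, None)),
                   0.0)

    # quadrature volumes: |d position / d(s, theta, u)| by central differences
    def pos(s, th, u):
        au, cu = a_e + u * t, c_e + u * t
        pm = np.arccos(np.clip(-z_b / cu, -1.0, 1.0))
        ps = s * pm
        return np.stack([au * np.sin(ps) * np.cos(th),
                         au * np.sin(ps) * np.sin(th),
                         -cu * np.cos(ps)], axis=-1)

    h = 1e-5
    dps = (pos(S + h, TH, U) - pos(S - h, TH, U)) / (2 * h)
    dpt = (pos(S, TH + h, U) - pos(S, TH - h, U)) / (2 * h)
    dpu = (pos(S, TH, U + h) - pos(S, TH, U - h)) / (2 * h)
    jac = np.abs(np.einsum("ij,ij->i", dps, np.cross(dpt, dpu)))
    dV = jac * (1.0 / n_s) * (2.0 * np.pi / n_c) * (1.0 / n_t)
    dV *= wall_mm3 / dV.sum()   # exact normalization to the shell volume

    helix = np.deg2rad(cfg.endo_helix_angle
                       + U * (cfg.epi_helix_angle - cfg.endo_helix_angle))

    centers = np.array([REGION_CENTERS[r] for r in CIRC_REGIONS])
    dth = np.abs((TH[:, None] - centers[None, :] + np.pi) % (2 * np.pi) - np.pi)
    region_circ = np.argmin(dth, axis=1)
    region_axial = np.minimum((zeta * 3).astype(int), 2)

    e_r, e_c, e_l = _frames(PSI, TH, a_u, c_u)

    # endocardial surface grid (finer than the quadrature grid) for volume
    n_sp, n_sc = 36, 36
    psi_b_endo = np.arccos(np.clip(-z_b / c_e, -1.0, 1.0))
    surf_psi = np.linspace(0.0, psi_b_endo, n_sp)
    surf_theta = np.linspace(0.0, 2.0 * np.pi, n_sc, endpoint=False)
    surf_R = a_e * np.sin(surf_psi)
    surf_z = -c_e * np.cos(surf_psi)

    mesh = LVMesh(
        config=cfg, a_endo=a_e, c_endo=c_e, t_wall=t, z_base=z_b,
        length=length, wall_volume_mm3=wall_mm3,
        ed_cavity_volume_mm3=cfg.ed_cavity_volume * 1000.0,
        theta=TH, u=U, zeta=zeta, R=R, z=Z, R_endo_level=R_e,
        quad_volume=dV, helix=helix,
        region_circ=region_circ, region_axial=region_axial,
        e_r=e_r, e_c=e_c, e_l=e_l,
        surf_theta=surf_theta, surf_psi=surf_psi, surf_R=surf_R, surf_z=surf_z,
    )

    # discretization correction so the reference cavity volume is exact
    from .kinematics import GeneralizedCoords, deformed_cavity_volume_raw

    v_disc = deformed_cavity_volume_raw(mesh, GeneralizedCoords.identity())
    mesh.vol_correction = mesh.ed_cavity_volume_mm3 / v_disc

    mesh = pericardial_sites(mesh, n=cfg.n_pericardial,
                             k_apex=cfg.k_pericardial_apex,
                             k_base=cfg.k_pericardial_base, rng=rng)
    mesh.root_weights = dict(cfg.root_weights)
    mesh.root_motion_ratio = cfg.root_motion_ratio
    w = sum(mesh.root_weights.values())
    if w <= 0 or any(v < 0 for v in mesh.root_weights.values()):
        raise GeometryError("root coupling weights must be non-negative")
    mesh.root_weights = {k: v / w for k, v in mesh.root_weights.items()}
    return mesh


def assign_fiber_field(mesh: LVMesh, endo_angle: float, epi_angle: float) -> LVMesh:
    """Re-assign the rule-based helix-angle field (degrees, endo -> epi)."""
    if not (-90.0 < endo_angle < 90.0 and -90.0 < epi_angle < 90.0):
        raise GeometryError("helix angles must lie in (-90, 90) degrees")
    mesh.helix = np.deg2rad(endo_angle + mesh.u * (epi_angle - endo_angle))
    return mesh


def pericardial_sites(mesh: LVMesh, n: int = 49, k_apex: float = 1.0,
                      k_base: float = 0.05,
                      rng: np.random.Generator | None = None) -> LVMesh:
    """Place ``n`` pericardial spring sites evenly on the epicardium.

    A golden-angle spiral distributes the sites over the epicardial surface;
    stiffness interpolates linearly in the axial coordinate from ``k_apex``
    at the apex to ``k_base`` at the base (higher apical stiffness keeps the
    apex nearly stationary over the cycle).
    """
    if not (k_apex >= k_base > 0):
        raise GeometryError("require k_apex >= k_base > 0")
    rng = rng or np.random.default_rng(mesh.config.seed + 1)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n)
    zeta = (i + 0.5) / n
    theta = (i * golden + rng.uniform(0.0, 2.0 * np.pi)) % (2.0 * np.pi)

    c_epi = mesh.c_endo + mesh.t_wall
    a_epi = mesh.a_endo + mesh.t_wall
    z_apex_epi = -c_epi
    z = z_apex_epi + zeta * (mesh.z_base - z_apex_epi)
    R = a_epi * np.sqrt(np.clip(1.0 - (z / c_epi) ** 2, 0.0, None))
    R_e = np.where(z >= -mesh.c_endo,
                   mesh.a_endo * np.sqrt(np.clip(1.0 - (z / mesh.c_endo) ** 2,
                                                 0.0, None)),
                   0.0)
    k = k_apex + (k_base - k_apex) * zeta

    # outward surface normals of the epicardial ellipsoid at the sites;
    # pericardial springs act along these (normal contact, free tangential
    # sliding, as a pericardial sac permits)
    nx = R * np.cos(theta) / a_epi ** 2
    ny = R * np.sin(theta) / a_epi ** 2
    nz = z / c_epi ** 2
    n = np.stack([nx, ny, nz], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)

    mesh.peri_theta, mesh.peri_zeta, mesh.peri_R = theta, zeta, R
    mesh.peri_z, mesh.peri_R_endo, mesh.peri_k = z, R_e, k
    mesh.peri_normal = n
    return mesh


def cavity_volume(mesh: LVMesh, deformation) -> float:
    """Cavity volume (mL) under a generalized deformation state.

    Integrates the deformed endocardial surface (triangulated side wall,
    apex fan and basal cap) via the divergence theorem, with a constant
    discretization correction that makes the reference volume exact.
    """
    from .kinematics import deformed_cavity_volume_raw

    v = deformed_cavity_volume_raw(mesh, deformation) * mesh.vol_correction
    if v <= 0:
        raise GeometryError("deformed cavity surface is inverted")
    return v / 1000.0
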