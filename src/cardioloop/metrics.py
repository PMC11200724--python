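"""PV-loop metrics, regional strains, myofiber stress and comparison tables.

Conventions mirror the reporting of clinical/computational LV studies:

* ED = maximum LV volume of the converged cycle, ES = minimum.
* SV = EDV - ESV; MAP = time-averaged arterial pressure over the cycle;
  SW = SV * MAP.  Stroke work is computed and stored in mmHg*mL; the
  tabular output labels the column "Joule" following the convention of the
  source tables this layout replicates, although the magnitudes are
  mmHg*mL (8747.5 mmHg*mL is about 1.17 J) -- see docs/methods.md.
* Strains are engineering strains (L_es - L_ed)/L_ed between the end-
  diastolic and end-systolic states, sampled at 12 locations (4
  circumferential x 3 axial) at both the epicardium and endocardium;
  layers are averaged per site before family statistics.  Radial strain is
  positive for wall thickening; circumferential and longitudinal strains
  are negative for shortening.
* Myofiber stress is the volume-weighted mean of the total (passive +
  active) Cauchy-equivalent fiber stress at end-systole, in MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinematics as kin
from .geometry import AXIAL_REGIONS, CIRC_REGIONS

__all__ = [
    "PVLoopMetrics",
    "StrainReport",
    "StressReport",
    "MetricsBundle",
    "ComparisonTable",
    "pv_metrics",
    "loop_area",
    "strain_report",
    "myofiber_stress_report",
    "percent_change",
    "comparison_table",
    "bundle_from_result",
]


@dataclass(frozen=True)
class PVLoopMetrics:
    """End-point pressures/volumes and work of one converged cycle."""

    edp: float
    edv: float
    esp: float
    esv: float
    map: float
    loop_area: float = np.nan

    @property
    def sv(self) -> float:
        return self.edv - self.esv

    @property
    def sw(self) -> float:
        return self.sv * self.map

    @classmethod
    def from_values(cls, edp: float, edv: float, esp: float, esv: float,
                    sw: float | None = None,
                    map: float | None = None) -> "PVLoopMetrics":
        """Build from tabulated values; MAP recovered from SW if needed."""
        sv = edv - esv
        if map is None:
            if sw is None:
                raise ValueError("need map or sw")
            map = sw / sv
        return cls(edp=edp, edv=edv, esp=esp, esv=esv, map=map)

    def to_dict(self) -> dict:
        return {"EDP": self.edp, "EDV": self.edv, "ESP": self.esp,
                "ESV": self.esv, "SV": self.sv, "SW": self.sw}


@dataclass(frozen=True)
class StrainReport:
    """Family-level strain statistics and regional longitudinal strains."""

    radial: tuple          # (mean, sd) over 3 axial sites
    circumferential: tuple  # (mean, sd) over 3 axial sites
    longitudinal: tuple    # (mean, sd) over 4 circumferential sites
    regional_longitudinal: dict  # region -> strain

    def to_dict(self) -> dict:
        d = {"radial": self.radial[0], "circumferential": self.circumferential[0],
             "longitudinal": self.longitudinal[0]}
        d.update({f"longitudinal_{k}": v
                  for k, v in self.regional_longitudinal.items()})
        return d


@dataclass(frozen=True)
class StressReport:
    """Volume-averaged end-systolic myofiber stress (MPa)."""

    mean_myofiber_stress: float
    sd: float
    per_region: dict = field(default_factory=dict)
    pointwise: np.ndarray | None = None
    weights: np.ndarray | None = None


@dataclass
class MetricsBundle:
    pv: PVLoopMetrics | None = None
    strain: StrainReport | None = None
    stress: StressReport | None = None


# --------------------------------------------------------------------------


def pv_metrics(trace) -> PVLoopMetrics:
    """PV-loop summary of a converged cycle trace."""
    v = np.asarray(trace.v_lv, dtype=float)
    p = np.asarray(trace.p_lv, dtype=float)
    i_ed = int(np.argmax(v))
    i_es = int(np.argmin(v))
    if not np.all(np.isfinite(v)) or not np.all(np.isfinite(p)):
        raise ValueError("non-finite trace")
    return PVLoopMetrics(edp=float(p[i_ed]), edv=float(v[i_ed]),
                         esp=float(p[i_es]), esv=float(v[i_es]),
                         map=float(np.mean(trace.p_art)),
                         loop_area=loop_area(trace))


def loop_area(trace) -> float:
    """Signed shoelace area of the (V, P) cycle, in mmHg*mL.

    Positive for the counterclockwise traversal of a working loop
    (ejection at high pressure, filling at low pressure).
    """
    v = np.asarray(trace.v_lv, dtype=float)
    p = np.asarray(trace.p_lv, dtype=float)
    vn = np.roll(v, -1)
    pn = np.roll(p, -1)
    return float(0.5 * np.sum(v * pn - vn * p))


def _site_means(mesh, values: np.ndarray) -> np.ndarray:
    """(4 circ, 3 axial) site means; epi/endo layers averaged per site."""
    out = np.full((len(CIRC_REGIONS), len(AXIAL_REGIONS)), np.nan)
    endo = mesh.u < 0.5
    for i in range(len(CIRC_REGIONS)):
        for j in range(len(AXIAL_REGIONS)):
            m = (mesh.region_circ == i) & (mesh.region_axial == j)
            if not np.any(m):
                raise ValueError("empty sampling site; refine the mesh")
            layer_vals = []
            for lay in (endo, ~endo):
                sel = m & lay
                if np.any(sel):
                    layer_vals.append(values[sel].mean())
            out[i, j] = float(np.mean(layer_vals))
    return out


def strain_report(ed_state, es_state, mesh,
                  blend_width: float = kin.DEFAULT_BLEND_WIDTH) -> StrainReport:
    """Engineering strains between the ED and ES deformation states.

    ``ed_state``/``es_state`` are GeneralizedCoords of the same converged
    cycle.  Strain along each anatomical direction is the relative length
    change of a material segment: lambda_es/lambda_ed - 1.
    """
    lam_ed = kin.point_stretches(mesh, ed_state, blend_width)
    lam_es = kin.point_stretches(mesh, es_state, blend_width)
    eps = {}
    for name, a, b in (("radial", lam_es[0], lam_ed[0]),
                       ("circumferential", lam_es[1], lam_ed[1]),
                       ("longitudinal", lam_es[2], lam_ed[2])):
        if np.any(b <= 0):
            raise ValueError("degenerate ED segment length")
        eps[name] = a / b - 1.0

    sites = {k: _site_means(mesh, v) for k, v in eps.items()}
    # radial & circumferential: one value per axial level (3 locations)
    rad = sites["radial"].mean(axis=0)
    cir = sites["circumferential"].mean(axis=0)
    # longitudinal: one value per circumferential region (4 locations)
    lon = sites["longitudinal"].mean(axis=1)
    region_long = {CIRC_REGIONS[i]: float(lon[i]) for i in range(4)}

    def stat(x):
        return (float(np.mean(x)), float(np.std(x, ddof=1)))

    return StrainReport(radial=stat(rad), circumferential=stat(cir),
                        longitudinal=stat(lon),
                        regional_longitudinal=region_long)


def myofiber_stress_report(es_state: dict, mesh) -> StressReport:
    """Volume-weighted myofiber-stress statistics at end-systole.

    ``es_state`` is a pointwise-state dict (see mechanics.pointwise_state)
    holding ``fiber_stress`` per material point.
    """
    sig = np.asarray(es_state["fiber_stress"], dtype=float)
    w = mesh.quad_volume / mesh.quad_volume.sum()
    mean = float(w @ sig)
    sd = float(np.sqrt(w @ (sig - mean) ** 2))
    per_region = {}
    for i, name in enumerate(CIRC_REGIONS):
        m = mesh.region_circ == i
        per_region[name] = float(mesh.quad_volume[m] @ sig[m]
                                 / mesh.quad_volume[m].sum())
    return StressReport(mean_myofiber_stress=mean, sd=sd,
                        per_region=per_region, pointwise=sig,
                        weights=mesh.quad_volume.copy())


def percent_change(reference: float, comparison: float) -> float:
    """Percent change of ``comparison`` relative to ``reference``."""
    if reference == 0:
        return np.nan
    return 100.0 * (comparison - reference) / reference


# --------------------------------------------------------------------------
# comparison tables


@dataclass
class ComparisonTable:
    """Reference-vs-comparison difference and percent-change tables."""

    pv: pd.DataFrame
    strain: pd.DataFrame
    regional: pd.DataFrame
    stress: pd.DataFrame


def _rowset(ref: dict, cmp: dict, columns) -> pd.DataFrame:
    ref_v = np.array([ref[c] for c in columns], dtype=float)
    cmp_v = np.array([cmp[c] for c in columns], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (cmp_v - ref_v) / ref_v
    return pd.DataFrame([ref_v, cmp_v, cmp_v - ref_v, pct],
                        index=["reference", "comparison", "difference",
                               "percent_change"],
                        columns=list(columns))


def comparison_table(ref_bundle: MetricsBundle,
                     cmp_bundle: MetricsBundle) -> ComparisonTable:
    """Full difference/percent tables between two metric bundles.

    The stress table reports both the percent change of the volume-averaged
    means and, when pointwise fields are available, the volume-weighted
    mean of the pointwise percent changes (the two differ; both are
    reported, neither is privileged).
    """
    for b in (ref_bundle, cmp_bundle):
        if b.pv is None or b.strain is None:
            raise ValueError("bundles must provide pv and strain metrics")
    pv_cols = ("EDP", "EDV", "ESP", "ESV", "SV", "SW")
    pv = _rowset(ref_bundle.pv.to_dict(), cmp_bundle.pv.to_dict(), pv_cols)
    pv.attrs["units"] = {"EDP": "mmHg", "EDV": "mL", "ESP": "mmHg",
                         "ESV": "mL", "SV": "mL", "SW": "Joule"}

    fam_cols = ("radial", "circumferential", "longitudinal")
    strain = _rowset(
        {c: getattr(ref_bundle.strain, c)[0] for c in fam_cols},
        {c: getattr(cmp_bundle.strain, c)[0] for c in fam_cols}, fam_cols)

    reg = _rowset(ref_bundle.strain.regional_longitudinal,
                  cmp_bundle.strain.regional_longitudinal, CIRC_REGIONS)

    stress = pd.DataFrame()
    if ref_bundle.stress is not None and cmp_bundle.stress is not None:
        r, c = ref_bundle.stress, cmp_bundle.stress
        stress = _rowset({"mean_myofiber_stress": r.mean_myofiber_stress},
                         {"mean_myofiber_stress": c.mean_myofiber_stress},
                         ("mean_myofiber_stress",))
        if r.pointwise is not None and c.pointwise is not None \
                and r.pointwise.shape == c.pointwise.shape:
            w = r.weights / r.weights.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                pw = 100.0 * (c.pointwise - r.pointwise) / np.abs(r.pointwise)
            ok = np.isfinite(pw)
            stress.loc["pointwise_percent_change_mean",
                       "mean_myofiber_stress"] = float(
                (w[ok] * pw[ok]).sum() / w[ok].sum())
    return ComparisonTable(pv=pv, strain=strain, regional=reg, stress=stress)


def bundle_from_result(result) -> MetricsBundle:
    """Metrics bundle (PV, strain, stress) of a finished scenario run."""
    trace = result.trace
    pv = pv_metrics(trace)
    strain = strain_report(trace.q_ed, trace.q_es, result.mesh,
                           result.model.config.blend_width)
    es_state = result.model.pointwise_state(trace.q_es,
                                            trace.t[trace.i_es])
    stress = myofiber_stress_report(es_state, result.mesh)
    return MetricsBundle(pv=pv, strain=strain, stress=stress)
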