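"""Cardiac-cycle orchestration: mechanics-circulation coupling, limit
cycles, and the three ventricular-aortic coupling scenarios.

Coupling scheme (monolithic per step): at each time step the LV pressure is
the root of a scalar volume-match residual -- the cavity volume of the
mechanical equilibrium at that pressure must equal the LV volume implied by
the valve flows at the same pressure.  The scalar root is found by a
safeguarded secant/bisection iteration inside a sign-change bracket; the
embedded equilibrium solves are warm-started from the previous step, so
most steps cost a handful of Newton iterations.  The LV volume carried
forward is the flow-balance value, which keeps total blood volume
conserved to machine precision.

Scenarios (aliases A/B/C):

* ``baseline``          -- AA root spring 0.5 N/mm, ventricular Tmax 0.2 MPa
* ``stiff_aa``          -- root spring 10 N/mm (immobilized sino-tubular
                           junction), Tmax 0.2 MPa
* ``stiff_aa_inotropy`` -- root spring 10 N/mm, contractility doubled to
                           Tmax 0.4 MPa
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import circulation as circ
from . import kinematics as kin
from .constitutive import ActiveMaterialParams, PassiveMaterialParams
from .geometry import LVGeometryConfig, build_idealized_lv, cavity_volume
from .kinematics import GeneralizedCoords
from .mechanics import EquilibriumSolver, SpringSet, aortic_root_displacement

log = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "RunConfig",
    "CycleTrace",
    "HeartModel",
    "ScenarioResult",
    "SCENARIOS",
    "run_scenario",
]

#: scenario presets: (k_aa N/mm, ventricular Tmax MPa)
SCENARIOS = {
    "baseline": (0.5, 0.2),
    "stiff_aa": (10.0, 0.2),
    "stiff_aa_inotropy": (10.0, 0.4),
}
SCENARIO_ALIASES = {"A": "baseline", "B": "stiff_aa", "C": "stiff_aa_inotropy"}


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation condition."""

    scenario: str = "baseline"
    k_aa: float = 0.5
    tmax_ventricle: float = 0.2
    cycle_period: float = 1.0
    dt: float = 0.005
    n_cycles_max: int = 10
    periodicity_tol: float = 0.5   # mL

    @classmethod
    def preset(cls, name: str, **overrides) -> "ScenarioConfig":
        name = SCENARIO_ALIASES.get(name, name)
        if name not in SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}")
        k_aa, tmax = SCENARIOS[name]
        return cls(scenario=name, k_aa=k_aa, tmax_ventricle=tmax, **overrides)


@dataclass
class RunConfig:
    """Full model configuration: geometry, materials, springs, circulation."""

    geometry: LVGeometryConfig = field(default_factory=LVGeometryConfig)
    passive: PassiveMaterialParams = field(
        default_factory=PassiveMaterialParams.ventricle)
    active: ActiveMaterialParams = field(
        default_factory=ActiveMaterialParams.ventricle)
    circulation: circ.CirculationParams = field(
        default_factory=circ.CirculationParams)
    edp_reference: float = 11.85
    fiber_prestretch: float = 1.12
    blend_width: float = kin.DEFAULT_BLEND_WIDTH
    solver_tol: float = 1e-8
    root_rest_position: float = 0.0


@dataclass
class CycleTrace:
    """Time series of one cardiac cycle."""

    t: np.ndarray
    p_lv: np.ndarray
    p_la: np.ndarray
    p_art: np.ndarray
    p_ven: np.ndarray
    v_lv: np.ndarray
    v_la: np.ndarray
    v_art: np.ndarray
    v_ven: np.ndarray
    root_disp: np.ndarray
    q: np.ndarray            # (n_steps, 9)

    @property
    def i_ed(self) -> int:
        """End-diastolic index: maximum LV volume of the cycle."""
        return int(np.argmax(self.v_lv))

    @property
    def i_es(self) -> int:
        """End-systolic index: minimum LV volume of the cycle."""
        return int(np.argmin(self.v_lv))

    @property
    def q_ed(self) -> GeneralizedCoords:
        return GeneralizedCoords.from_array(self.q[self.i_ed])

    @property
    def q_es(self) -> GeneralizedCoords:
        return GeneralizedCoords.from_array(self.q[self.i_es])

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({
            "t": self.t, "p_lv": self.p_lv, "p_la": self.p_la,
            "p_art": self.p_art, "p_ven": self.p_ven,
            "v_lv": self.v_lv, "v_la": self.v_la,
            "v_art": self.v_art, "v_ven": self.v_ven,
            "root_disp": self.root_disp,
        })
        for j in range(self.q.shape[1]):
            df[f"q{j}"] = self.q[:, j]
        return df


@dataclass
class ScenarioResult:
    scenario: ScenarioConfig
    trace: CycleTrace
    mesh: object
    model: "HeartModel"
    n_cycles: int
    edv_history: list

    @property
    def peak_root_displacement(self) -> float:
        return float(np.max(self.trace.root_disp))


class HeartModel:
    """Coupled reduced-order LV + closed-loop circulation."""

    def __init__(self, config: RunConfig | None = None,
                 scenario: ScenarioConfig | None = None):
        self.config = config or RunConfig()
        self.scenario = scenario or ScenarioConfig()
        self.mesh = build_idealized_lv(self.config.geometry)
        self.springs = SpringSet(k_aa=self.scenario.k_aa,
                                 root_rest_position=self.config.root_rest_position)
        active = self.config.active.with_tmax(self.scenario.tmax_ventricle) \
            if self.scenario.tmax_ventricle > 0 else self.config.active
        self._active_scale = 1.0 if self.scenario.tmax_ventricle > 0 else 0.0
        self.solver = EquilibriumSolver(
            self.mesh, self.config.passive, active, self.springs,
            edp_reference=self.config.edp_reference,
            blend_width=self.config.blend_width,
            tol=self.config.solver_tol,
            active_scale=self._active_scale,
            fiber_prestretch=self.config.fiber_prestretch)
        cp = self.config.circulation
        if abs(cp.cycle_period - self.scenario.cycle_period) > 1e-12:
            cp = replace(cp, cycle_period=self.scenario.cycle_period)
        self.circ_params = cp
        self._dgdp = None   # scalar-coupling slope memory (mL per mmHg)

    # -- coupled step -----------------------------------------------------

    def _mech_volume(self, t_cycle: float, p: float,
                     q_guess: GeneralizedCoords) -> tuple[float, GeneralizedCoords]:
        sol = self.solver.solve(t_cycle, p, q_guess)
        return cavity_volume(self.mesh, sol.q), sol.q

    def _coupled_step(self, state: circ.CirculationState, v_lv: float,
                      p_prev: float, q_prev: GeneralizedCoords,
                      t_cycle: float, dt: float):
        """Solve the implicit (p_lv, q) step; returns (p, q, new_state, v_lv')."""

        def g(p, q_guess):
            v_mech, q_new = self._mech_volume(t_cycle, p, q_guess)
            v_flow = v_lv + dt * circ.lv_net_inflow(state, p, t_cycle,
                                                    self.circ_params)
            return v_mech - v_flow, q_new

        # bracket a sign change around the previous pressure; g is
        # increasing in p (stiffer cavity at higher pressure, less inflow).
        # A slope memory from the previous step seeds the first proposal.
        p0 = p_prev
        g0, q0 = g(p0, q_prev)
        if abs(g0) < 1e-6:
            v_flow = v_lv + dt * circ.lv_net_inflow(state, p0, t_cycle,
                                                    self.circ_params)
            new_state = circ.step_circulation(state, v_lv, p0, t_cycle, dt,
                                              self.circ_params)
            return p0, q0, new_state, v_flow
        if self._dgdp is not None and self._dgdp > 0:
            p1 = p0 - g0 / self._dgdp
            g1, q1 = g(p1, q0)
        else:
            p1 = p0 - np.sign(g0) * max(2.0, 0.05 * abs(p0))
            g1, q1 = g(p1, q0)
        if p1 != p0 and g1 != g0:
            self._dgdp = max((g1 - g0) / (p1 - p0), 1e-6)
        step = max(2.0, 0.05 * abs(p0))
        direction = -np.sign(g1) if g1 != 0 else 0.0
        tries = 0
        while g0 * g1 > 0 and tries < 60:
            p0, g0, q0 = p1, g1, q1
            p1 = p1 + direction * step
            g1, q1 = g(p1, q0)
            step *= 1.7
            tries += 1
        if g0 * g1 > 0:
            raise RuntimeError(f"could not bracket LV pressure at t={t_cycle}")
        lo, hi = (p0, p1) if p0 < p1 else (p1, p0)
        glo, ghi = (g0, g1) if p0 < p1 else (g1, g0)
        p, gp, q = (p0, g0, q0) if abs(g0) < abs(g1) else (p1, g1, q1)

        for _ in range(60):
            if abs(gp) < 1e-6 or hi - lo < 1e-11 * max(1.0, abs(hi)):
                break
            # secant proposal, safeguarded by the bracket
            denom = ghi - glo
            p_new = hi - ghi * (hi - lo) / denom if denom != 0 else 0.5 * (lo + hi)
            if not (lo < p_new < hi):
                p_new = 0.5 * (lo + hi)
            g_new, q = g(p_new, q)
            if g_new == 0.0:
                p, gp = p_new, g_new
                break
            if g_new < 0:
                lo, glo = p_new, g_new
            else:
                hi, ghi = p_new, g_new
            p, gp = p_new, g_new

        if hi > lo and ghi > glo:
            self._dgdp = max((ghi - glo) / (hi - lo), 1e-6)
        v_flow = v_lv + dt * circ.lv_net_inflow(state, p, t_cycle,
                                                self.circ_params)
        new_state = circ.step_circulation(state, v_lv, p, t_cycle, dt,
                                          self.circ_params)
        return p, q, new_state, v_flow

    # -- cycle drivers ----------------------------------------------------

    def run_cycle(self, state: circ.CirculationState, v_lv: float,
                  q: GeneralizedCoords, p: float):
        """Advance one cardiac period; returns (trace, state, v_lv, q, p)."""
        sc = self.scenario
        n = int(round(sc.cycle_period / sc.dt))
        rec = {k: np.empty(n) for k in
               ("t", "p_lv", "p_la", "p_art", "p_ven", "v_lv", "v_la",
                "v_art", "v_ven", "root_disp")}
        qs = np.empty((n, kin.N_COORDS))
        for k in range(n):
            t_c = k * sc.dt
            p, q, state, v_lv = self._coupled_step(state, v_lv, p, q, t_c, sc.dt)
            rec["t"][k] = t_c
            rec["p_lv"][k] = p
            rec["p_la"][k] = state.p_la
            rec["p_art"][k] = state.p_art
            rec["p_ven"][k] = state.p_ven
            rec["v_lv"][k] = v_lv
            rec["v_la"][k] = state.v_la
            rec["v_art"][k] = state.v_art
            rec["v_ven"][k] = state.v_ven
            rec["root_disp"][k] = aortic_root_displacement(self.mesh, q)
            qs[k] = q.to_array()
        trace = CycleTrace(q=qs, **rec)
        return trace, state, v_lv, q, p

    def run_to_limit_cycle(self) -> ScenarioResult:
        """Cycle until the end-diastolic volume is periodic.

        Stops when |EDV_n - EDV_{n-1}| < periodicity_tol (mL) or after
        n_cycles_max cycles; returns the final cycle.  Deterministic: there
        are no stochastic elements in the solver or the integrator.
        """
        sc = self.scenario
        v_lv = cavity_volume(self.mesh, GeneralizedCoords.identity())
        state = circ.initial_state(self.circ_params, v_lv)
        q = GeneralizedCoords.identity()
        p = self.config.edp_reference
        edv_hist: list[float] = []
        trace = None
        for cycle in range(sc.n_cycles_max):
            trace, state, v_lv, q, p = self.run_cycle(state, v_lv, q, p)
            edv = float(np.max(trace.v_lv))
            edv_hist.append(edv)
            log.info("cycle %d: EDV=%.2f mL ESV=%.2f mL", cycle + 1, edv,
                     float(np.min(trace.v_lv)))
            if cycle > 0 and abs(edv_hist[-1] - edv_hist[-2]) < sc.periodicity_tol:
                break
        else:
            cycle = sc.n_cycles_max - 1
            if len(edv_hist) > 1 and \
                    abs(edv_hist[-1] - edv_hist[-2]) >= sc.periodicity_tol:
                raise RuntimeError(
                    f"no limit cycle after {sc.n_cycles_max} cycles; "
                    f"EDV sequence: {np.round(edv_hist, 2)}")
        return ScenarioResult(scenario=sc, trace=trace, mesh=self.mesh,
                              model=self, n_cycles=cycle + 1,
                              edv_history=edv_hist)

    def pointwise_state(self, q: GeneralizedCoords, t_cycle: float) -> dict:
        from .mechanics import pointwise_state

        return pointwise_state(self.mesh, q, t_cycle, self.config.passive,
                               self.solver.active, self.config.blend_width,
                               active_scale=self._active_scale)


def run_scenario(name: str, config: RunConfig | None = None,
                 **scenario_overrides) -> ScenarioResult:
    """Run one named scenario (A/B/C or long alias) to its limit cycle."""
    sc = ScenarioConfig.preset(name, **scenario_overrides)
    model = HeartModel(config, sc)
    return model.run_to_limit_cycle()
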