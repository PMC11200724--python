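"""Closed-loop lumped hemodynamics.

Four blood compartments exchange volume through resistive links: the LV
cavity (volume supplied by the mechanics model), a systemic arterial
compliance chamber, a pulmonary-venous compliance chamber and a lumped left
atrium.  Valves are ideal diodes with a small open resistance (no
inertance, no regurgitation).  The left atrium is a pressure-volume
elastance with an active component whose timing and waveform follow the
atrial activation parameters (short time-to-peak, late-diastolic onset),
replacing a three-dimensional atrium; the right heart is absent, with
venous return closing the loop directly into the pulmonary-venous chamber.

Volume conservation is exact by construction: every flow leaves one
compartment and enters another within the same update.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constitutive import ActiveMaterialParams, active_fiber_stress

__all__ = [
    "CirculationParams",
    "CirculationState",
    "valve_flow",
    "step_circulation",
    "la_pressure",
    "total_volume",
]


@dataclass(frozen=True)
class CirculationParams:
    """Closed-loop parameters.

    Resistances in mmHg*s/mL, compliances in mL/mmHg, volumes in mL.
    ``la_*`` parameters define the lumped-atrium elastance; the active
    elastance is shaped by the atrial activation waveform (``la_active``)
    with onset ``la_activation_time`` seconds into the cycle (late
    diastole, providing the atrial kick just before ventricular systole).
    """

    r_av: float = 0.02
    r_mv: float = 0.03
    r_sys: float = 1.03
    r_ven: float = 0.04
    c_art: float = 1.7
    c_ven: float = 9.0
    total_blood_volume: float = 3400.0
    v_art_slack: float = 420.0
    v_ven_slack: float = 2450.0
    v_la_slack: float = 20.0
    la_passive_elastance: float = 0.25
    la_active_elastance: float = 0.35
    la_active: ActiveMaterialParams = field(
        default_factory=ActiveMaterialParams.atrium)
    la_activation_time: float = 0.82
    cycle_period: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r_av", "r_mv", "r_sys", "r_ven", "c_art", "c_ven"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class CirculationState:
    """Instantaneous state of the non-LV compartments."""

    v_art: float
    v_ven: float
    v_la: float
    p_art: float = 0.0
    p_ven: float = 0.0
    p_la: float = 0.0
    valve_av_open: bool = False
    valve_mv_open: bool = False
    q_av: float = 0.0
    q_mv: float = 0.0
    q_sys: float = 0.0
    q_ven: float = 0.0

    def copy(self) -> "CirculationState":
        return replace(self)


def valve_flow(delta_p: float, r: float) -> float:
    """Ideal-diode valve: forward flow delta_p/r when delta_p > 0, else 0."""
    if not r > 0:
        raise ValueError("valve resistance must be > 0")
    return delta_p / r if delta_p > 0.0 else 0.0


def la_pressure(params: CirculationParams, v_la: float, t: float) -> float:
    """Lumped left-atrial pressure (mmHg) at volume ``v_la`` and cycle time ``t``.

    Passive elastance plus an active elastance scaled by the atrial
    activation waveform; the waveform wraps around the cycle so the late-
    diastolic contraction can relax into the following beat.
    """
    act = params.la_active
    t_a = (t - params.la_activation_time) % params.cycle_period
    # normalized activation shape in [0, 1] from the atrial-row waveform
    a = active_fiber_stress(t_a, 0.0, act) / act.Tmax
    scale = 1.0 / (0.5 * act.Ca0 ** 2 / (act.Ca0 ** 2 +
                   _eca50_sq_at_rest(act)) * 2.0)
    e = params.la_passive_elastance + params.la_active_elastance * min(a * scale, 1.0)
    return e * (v_la - params.v_la_slack)


def _eca50_sq_at_rest(act: ActiveMaterialParams) -> float:
    return (act.Ca0max ** 2) / np.expm1(act.B * (act.lr - act.l0))


def pressures(params: CirculationParams, state: CirculationState,
              t: float) -> tuple[float, float, float]:
    """(p_art, p_ven, p_la) from the compliance/elastance relations."""
    p_art = (state.v_art - params.v_art_slack) / params.c_art
    p_ven = (state.v_ven - params.v_ven_slack) / params.c_ven
    p_la = la_pressure(params, state.v_la, t)
    return p_art, p_ven, p_la


def step_circulation(state: CirculationState, v_lv: float, p_lv: float,
                     t: float, dt: float,
                     params: CirculationParams) -> CirculationState:
    """Advance the non-LV compartments by one explicit flow-balance step.

    Flows are evaluated at the beginning-of-step pressures (the LV side
    uses the supplied ``p_lv``, which the simulator makes implicit by
    iterating the coupled step); each flow is debited from one compartment
    and credited to another, so total blood volume including ``v_lv`` is
    conserved to machine precision.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    p_art, p_ven, p_la = pressures(params, state, t)

    q_mv = valve_flow(p_la - p_lv, params.r_mv)
    q_av = valve_flow(p_lv - p_art, params.r_av)
    q_sys = (p_art - p_ven) / params.r_sys
    q_ven = (p_ven - p_la) / params.r_ven

    new = state.copy()
    new.v_art = state.v_art + dt * (q_av - q_sys)
    new.v_ven = state.v_ven + dt * (q_sys - q_ven)
    new.v_la = state.v_la + dt * (q_ven - q_mv)
    if min(new.v_art, new.v_ven, new.v_la) < 0.0:
        raise RuntimeError("negative compartment volume: dt too large or "
                           "parameters infeasible")
    new.p_art, new.p_ven, new.p_la = pressures(params, new, t + dt)
    new.q_mv, new.q_av, new.q_sys, new.q_ven = q_mv, q_av, q_sys, q_ven
    new.valve_mv_open = q_mv > 0.0
    new.valve_av_open = q_av > 0.0
    return new


def lv_net_inflow(state: CirculationState, p_lv: float, t: float,
                  params: CirculationParams) -> float:
    """Net LV inflow (mL/s) at the current state for a candidate ``p_lv``."""
    p_art, _, p_la = pressures(params, state, t)
    return valve_flow(p_la - p_lv, params.r_mv) - valve_flow(p_lv - p_art,
                                                             params.r_av)


def total_volume(state: CirculationState, v_lv: float) -> float:
    """Total blood volume (mL) including the LV cavity."""
    return state.v_art + state.v_ven + state.v_la + v_lv


def initial_state(params: CirculationParams, v_lv: float) -> CirculationState:
    """Distribute the total blood volume into a plausible starting state."""
    v_la = params.v_la_slack + 10.0 / max(params.la_passive_elastance, 1e-6) * 0.25
    v_art = params.v_art_slack + 80.0 * params.c_art
    v_ven = params.total_blood_volume - v_lv - v_la - v_art
    if v_ven <= 0:
        raise ValueError("total blood volume too small for the slack volumes")
    return CirculationState(v_art=v_art, v_ven=v_ven, v_la=v_la)
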