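"""Adaptive model-predictive controller for closed-loop neonatal glucose control.

Every 15 minutes the controller ingests the newest sensor-glucose (SG)
reading, updates two adaptive quantities, and picks infusion rates by
exhaustive grid search over its internal patient model:

* ``d_fast`` — a rapidly adapting glucose-flux correction (mg/kg/min) that
  absorbs errors in model-based predictions — deviations of the untold
  nutrition from the controller's built-in turnover prior, EGP mismatch,
  sensor drift (time constant ~30 min);
* ``b_slow`` — a slowly adapting estimate of the basal insulin rate that
  maintains normoglycaemia (U/kg/h, time constant ~2 h).  Each cycle the
  internal model's sensitivity multiplier is re-derived in closed form so
  that the model's steady-state insulin requirement at the 6.0 mmol/L
  reference equals ``b_slow``.

Insulin is chosen to minimise an asymmetric quadratic cost over a 1.5 h
predicted trajectory (deviations below 4.0 mmol/L weighted x4); if the
30-40 min predicted minimum falls below 3.5 mmol/L the controller instead
commands the smallest 20% dextrose rate lifting that minimum above 4.0, and
insulin is forced to zero.  Both searches are plain grids at pump
resolution, so an exhaustive oracle can reproduce the argmin exactly.

If SG is lost, hourly blood-glucose values keep the controller informed for
up to 4 hours; beyond that it holds the last rates and raises an alarm.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from . import physiology as phys
from .physiology import (MGDL_PER_MMOL, MU_PER_MIN_PER_U_PER_H, InfusionInput,
                         PatientParams, PatientState)
from .sensing import GlucoseReading

log = logging.getLogger(__name__)

PUMP_RESOLUTION_ML_H = 0.1  # Alaris-class syringe pump step


@dataclass(frozen=True)
class MpcConfig:
    setpoint: float = 6.0             # mmol/L reference
    hypo_threshold: float = 4.0       # cost-asymmetry / safety level, mmol/L
    hypo_weight: float = 4.0          # cost multiplier below hypo_threshold
    max_insulin: float = 0.5          # U/kg/h dose cap
    insulin_conc: float = 5.0         # U/kg per 50 mL (closed-loop dilution)
    horizon_insulin: float = 90.0     # min
    dextrose_window: Tuple[float, float] = (30.0, 40.0)  # min
    dextrose_trigger: float = 3.5     # mmol/L predicted minimum triggering rescue
    dextrose_target: float = 4.0      # lift predicted minimum above this
    max_dextrose: float = 1.0         # mL/kg/h of 20% dextrose
    dextrose_step: float = 0.01       # mL/kg/h grid step
    cycle_min: float = 15.0
    predict_dt: float = 5.0           # prediction resolution, min
    tau_fast: float = 30.0            # d_fast observer time constant, min
    tau_slow: float = 120.0           # b_slow time constant, min
    kappa_slow: float = 0.05          # U/kg/h of implied insulin per mmol/L error
    b_slow_init: float = 0.02         # U/kg/h
    flux_prior: float = 8.4           # nominal glucose turnover prior, mg/kg/min
    fallback_limit: float = 240.0     # min of BG-informed operation before hold
    d_fast_bounds: Tuple[float, float] = (-10.0, 15.0)  # mg/kg/min
    max_step_up: float = 0.05         # U/kg/h largest per-cycle dose increase

    @property
    def insulin_step(self) -> float:
        """Achievable dose grid: pump step (mL/h) times U/kg per mL."""
        return PUMP_RESOLUTION_ML_H * self.insulin_conc / 50.0


@dataclass(frozen=True)
class ControlAction:
    insulin_rate: float            # U/kg/h
    dextrose20_rate: float         # mL/kg/h
    pump_rate_insulin: float       # mL/h
    pump_rate_dextrose: float      # mL/h
    mode: str                      # "sg" | "bg_fallback" | "hold"
    predicted_min_40: float = float("nan")  # mmol/L, at the emitted insulin rate

    def __post_init__(self) -> None:
        if self.insulin_rate < 0 or self.dextrose20_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.insulin_rate > 0 and self.dextrose20_rate > 0:
            raise ValueError("insulin and dextrose rescue are mutually exclusive")


@dataclass
class MpcState:
    weight: float                         # grams
    model_params: PatientParams
    model_state: PatientState
    d_fast: float = 0.0                   # mg/kg/min
    b_slow: float = 0.02                  # U/kg/h
    history: List[GlucoseReading] = field(default_factory=list)
    mode: str = "sg"
    fallback_started: Optional[float] = None
    last_reading_time: float = -math.inf
    current_insulin: float = 0.02         # U/kg/h actually running
    current_dextrose: float = 0.0         # mL/kg/h
    last_action: Optional[ControlAction] = None
    config: MpcConfig = field(default_factory=MpcConfig)


def rate_to_pump(rate_u_kg_h: float, conc_u_kg_per_50ml: float) -> float:
    """Insulin dose (U/kg/h) to syringe-pump rate (mL/h), quantised 0.1 mL/h."""
    if conc_u_kg_per_50ml <= 0:
        raise ValueError("concentration must be positive")
    ml_h = rate_u_kg_h / (conc_u_kg_per_50ml / 50.0)
    return math.floor(ml_h / PUMP_RESOLUTION_ML_H + 0.5) * PUMP_RESOLUTION_ML_H


def mpc_init(weight: float, config: Optional[MpcConfig] = None,
             params: Optional[PatientParams] = None) -> MpcState:
    """Initialise the controller from the infant's weight alone.

    The internal model starts at nominal preterm parameters (per-kg, so the
    weight enters only through pump arithmetic), resting at the setpoint with
    the plasma-insulin level implied by the initial basal estimate.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    cfg = config or MpcConfig()
    p = params or PatientParams()
    q1 = cfg.setpoint * MGDL_PER_MMOL * p.v_g
    i_p = cfg.b_slow_init * MU_PER_MIN_PER_U_PER_H / (p.v_i * p.k_e)
    state = PatientState(q1=q1, q2=p.k21 * q1 / p.k12, i_p=i_p,
                         x=p.s_base * i_p, g_isf=cfg.setpoint)
    st = MpcState(weight=weight, model_params=p, model_state=state,
                  b_slow=cfg.b_slow_init, current_insulin=cfg.b_slow_init,
                  config=cfg)
    st.model_params = _adapt_model_sensitivity(st)
    return st


def _adapt_model_sensitivity(state: MpcState) -> PatientParams:
    """Closed-form s_i making the model's basal at the setpoint equal b_slow.

    Solves the model's steady-state flux balance at the reference glucose,
    under the nominal turnover prior, for the sensitivity multiplier that
    makes the sustaining insulin rate exactly ``b_slow``.  This is how the
    slow adaptation individualises the model's insulin gain; the fast flux
    correction d_fast is a residual on top of the prior and deliberately
    does not enter the gain calibration.
    """
    p, cfg = state.model_params, state.config
    i_p = max(state.b_slow, 1e-4) * MU_PER_MIN_PER_U_PER_H / (p.v_i * p.k_e)
    x = p.s_base * i_p
    q1 = cfg.setpoint * MGDL_PER_MMOL * p.v_g
    f01_eff = p.f01 * min(1.0, cfg.setpoint / p.f01_sat)
    renal = p.renal_cl * max(0.0, q1 - p.renal_thresh * MGDL_PER_MMOL * p.v_g)
    need = cfg.flux_prior + p.egp0 - f01_eff - renal
    s_i = need / (x * (q1 + p.egp0 / p.x_egp))
    if s_i * x > p.x_egp:  # EGP fully suppressed at the operating point
        s_i = (cfg.flux_prior - f01_eff - renal) / (x * q1)
    s_i = min(max(s_i, 0.05), 50.0)
    return replace(p, s_i=s_i)


def _predict_grid(state: MpcState, insulin_rates: np.ndarray,
                  dextrose_rates: np.ndarray, horizon: float) -> np.ndarray:
    """Predicted plasma glucose (mmol/L) for each candidate rate pair.

    RK4 at the prediction resolution over the internal model with d_fast held
    constant.  Returns shape (n_steps + 1, n_candidates) including t=0.
    """
    p, cfg = state.model_params, state.config
    dt = cfg.predict_dt
    n = int(round(horizon / dt))
    ms = state.model_state
    n_sub = _substeps(state, float(np.max(insulin_rates)), dt)
    h = dt / n_sub
    shape = np.broadcast(insulin_rates, dextrose_rates).shape
    y = [np.full(shape, ms.q1), np.full(shape, ms.q2), np.full(shape, ms.i_p),
         np.full(shape, ms.x), np.full(shape, ms.g_isf)]
    out = np.empty((n + 1,) + shape)
    out[0] = y[0] / (p.v_g * MGDL_PER_MMOL)

    def f(v):
        return phys.derivatives_vec(v[0], v[1], v[2], v[3], v[4], p,
                                    insulin_rates, dextrose_rates,
                                    extra_flux=cfg.flux_prior + state.d_fast)

    for k in range(n):
        for _ in range(n_sub):
            k1 = f(y)
            k2 = f([y[i] + 0.5 * h * k1[i] for i in range(5)])
            k3 = f([y[i] + 0.5 * h * k2[i] for i in range(5)])
            k4 = f([y[i] + h * k3[i] for i in range(5)])
            y = [np.maximum(0.0, y[i] + h / 6.0 * (k1[i] + 2 * k2[i]
                                                   + 2 * k3[i] + k4[i]))
                 for i in range(5)]
        out[k + 1] = y[0] / (p.v_g * MGDL_PER_MMOL)
    return out


def _substeps(state: MpcState, max_rate: float, dt_out: float) -> int:
    """Substeps keeping RK4 stable for the fastest glucose eigenvalue.

    The stiff direction is the insulin-mediated clearance s_i*x; its bound
    over a prediction is set by the largest candidate rate (or the current
    plasma insulin if higher).
    """
    p = state.model_params
    i_p_max = max(state.model_state.i_p,
                  max_rate * MU_PER_MIN_PER_U_PER_H / (p.v_i * p.k_e))
    lam = p.s_i * p.s_base * i_p_max + p.k21 + p.k12 + p.renal_cl
    return max(1, math.ceil(dt_out * lam / 1.5))


def mpc_predict(state: MpcState, insulin_rate: float, horizon: float,
                dextrose_rate: float = 0.0) -> List[Tuple[float, float]]:
    """Forecast trajectory [(t_min, glucose mmol/L)] under a candidate rate."""
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if horizon == 0:
        return [(0.0, phys.plasma_glucose(state.model_state,
                                          state.model_params))]
    traj = _predict_grid(state, np.asarray([insulin_rate]),
                         np.asarray([dextrose_rate]), horizon)
    dt = state.config.predict_dt
    return [(k * dt, float(traj[k, 0])) for k in range(traj.shape[0])]


def insulin_candidates(cfg: MpcConfig) -> np.ndarray:
    step = cfg.insulin_step
    n = int(round(cfg.max_insulin / step))
    return np.round(np.arange(n + 1) * step, 10)


def mpc_insulin(state: MpcState) -> float:
    """Grid-search insulin rate minimising the asymmetric trajectory cost.

    Cost = sum over the 1.5 h predicted trajectory of w(g) * (g - setpoint)^2
    with w = hypo_weight below the hypo threshold; ties resolve to the lower
    rate.  A safety override zeroes insulin if the 40-min predicted minimum
    at the chosen rate is below the hypo threshold.
    """
    if state.mode == "hold":
        return state.current_insulin
    cfg = state.config
    cands = insulin_candidates(cfg)
    traj = _predict_grid(state, cands, np.zeros_like(cands),
                         cfg.horizon_insulin)
    dev = traj - cfg.setpoint
    w = np.where(traj < cfg.hypo_threshold, cfg.hypo_weight, 1.0)
    cost = (w * dev * dev).sum(axis=0)
    u = float(cands[int(np.argmin(cost))])  # argmin -> first = lowest rate
    if _predicted_min_40(state, u) < cfg.hypo_threshold:
        u = 0.0
    return u


def _predicted_min_40(state: MpcState, insulin_rate: float,
                      dextrose_rate: float = 0.0) -> float:
    traj = _predict_grid(state, np.asarray([insulin_rate]),
                         np.asarray([dextrose_rate]), 40.0)
    return float(traj.min())


def mpc_dextrose(state: MpcState) -> float:
    """Smallest 20% dextrose rate averting predicted hypoglycaemia.

    Looks at the predicted minimum over minutes 30-40 under zero insulin; if
    below the trigger, returns the smallest grid rate (step 0.01, cap
    1.0 mL/kg/h) lifting that minimum above 4.0 mmol/L, or the cap if none
    suffices.  Returns 0 when no rescue is needed.
    """
    if state.mode == "hold":
        return state.current_dextrose
    cfg = state.config
    lo, hi = cfg.dextrose_window
    dt = cfg.predict_dt
    k_lo, k_hi = int(round(lo / dt)), int(round(hi / dt))
    base = _predict_grid(state, np.asarray([0.0]), np.asarray([0.0]), hi)
    if float(base[k_lo:k_hi + 1].min()) >= cfg.dextrose_trigger:
        return 0.0
    n = int(round(cfg.max_dextrose / cfg.dextrose_step))
    cands = np.round(np.arange(1, n + 1) * cfg.dextrose_step, 10)
    traj = _predict_grid(state, np.zeros_like(cands), cands, hi)
    window_min = traj[k_lo:k_hi + 1].min(axis=0)
    ok = np.nonzero(window_min > cfg.dextrose_target)[0]
    if ok.size == 0:
        return cfg.max_dextrose
    return float(cands[int(ok[0])])


def mpc_ingest(state: MpcState, reading: GlucoseReading) -> MpcState:
    """One observer update from a new SG or BG reading.

    The prediction error e = reading - model glucose drives:
    d_fast (fast flux correction, dt-aware gain, tau ~30 min), b_slow (a
    low-pass of the delivered insulin plus an error-implied increment,
    tau ~6 h), and a full re-anchor of the accessible glucose state to the
    reading.  Stale readings are rejected with a warning.
    """
    if reading.time <= state.last_reading_time:
        log.warning("stale reading at t=%.1f rejected", reading.time)
        return state
    cfg, p = state.config, state.model_params
    g_model = phys.plasma_glucose(state.model_state, p)
    e = reading.value - g_model
    if math.isfinite(state.last_reading_time):
        dt = min(reading.time - state.last_reading_time, cfg.fallback_limit)
    else:
        dt = cfg.cycle_min
    gain_fast = 1.0 - math.exp(-dt / cfg.tau_fast)
    state.d_fast += gain_fast * e * MGDL_PER_MMOL * p.v_g / dt
    state.d_fast = min(max(state.d_fast, cfg.d_fast_bounds[0]),
                       cfg.d_fast_bounds[1])
    gain_slow = 1.0 - math.exp(-dt / cfg.tau_slow)
    implied = state.current_insulin + cfg.kappa_slow * e
    state.b_slow = max(0.0, state.b_slow + gain_slow * (implied - state.b_slow))
    ms = state.model_state
    state.model_state = PatientState(
        q1=max(0.0, reading.value * MGDL_PER_MMOL * p.v_g),
        q2=ms.q2, i_p=ms.i_p, x=ms.x, g_isf=reading.value)
    state.history.append(reading)
    if len(state.history) > 64:
        del state.history[0]
    state.last_reading_time = reading.time
    state.model_params = _adapt_model_sensitivity(state)
    return state


def _advance_model(state: MpcState, dt_total: float) -> None:
    """Propagate the internal model between cycles under the running rates."""
    cfg = state.config
    inputs = InfusionInput(insulin_rate=state.current_insulin,
                           dextrose20_rate=state.current_dextrose)
    n_sub = _substeps(state, state.current_insulin, cfg.predict_dt)
    t = 0.0
    s = state.model_state
    while t < dt_total - 1e-9:
        h = min(cfg.predict_dt / n_sub, dt_total - t)
        s = phys._rk4(s, state.model_params, inputs, h,
                      extra_flux=cfg.flux_prior + state.d_fast)
        t += h
    state.model_state = s


def mpc_cycle(state: MpcState, t: float,
              sg: Optional[GlucoseReading] = None,
              bg: Optional[GlucoseReading] = None
              ) -> Tuple[MpcState, ControlAction]:
    """One 15-minute control cycle at time ``t`` (minutes, on the cycle grid).

    Data-source logic: a fresh SG reading keeps (or returns) the controller
    in ``sg`` mode; with SG lost, hourly BG readings sustain ``bg_fallback``
    for up to 4 h; beyond that the controller holds the last rates and
    alarms, never dosing on absent data.  Dextrose rescue takes priority and
    forces insulin to zero.
    """
    cfg = state.config
    if abs(t / cfg.cycle_min - round(t / cfg.cycle_min)) > 1e-9:
        raise ValueError(f"t={t} is not on the {cfg.cycle_min}-min cycle grid")
    if state.last_action is not None:
        _advance_model(state, cfg.cycle_min)

    if sg is not None:
        state.mode = "sg"
        state.fallback_started = None
        state = mpc_ingest(state, sg)
    else:
        if state.fallback_started is None:
            state.fallback_started = t
        if t - state.fallback_started >= cfg.fallback_limit:
            state.mode = "hold"
        else:
            state.mode = "bg_fallback"
            if bg is not None:
                state = mpc_ingest(state, bg)

    if state.mode == "hold":
        action = ControlAction(
            insulin_rate=state.current_insulin,
            dextrose20_rate=state.current_dextrose,
            pump_rate_insulin=rate_to_pump(state.current_insulin,
                                           cfg.insulin_conc),
            pump_rate_dextrose=_dextrose_pump(state),
            mode="hold",
            predicted_min_40=float("nan"))
        state.last_action = action
        return state, action

    dex = mpc_dextrose(state)
    if dex > 0:
        insulin = 0.0
    else:
        # dose increases are ramp-limited; cuts (incl. safety zeros) are not
        insulin = min(mpc_insulin(state),
                      state.current_insulin + cfg.max_step_up)
    pred_min = _predicted_min_40(state, insulin, dex)
    state.current_insulin = insulin
    state.current_dextrose = dex
    action = ControlAction(
        insulin_rate=insulin, dextrose20_rate=dex,
        pump_rate_insulin=rate_to_pump(insulin, cfg.insulin_conc),
        pump_rate_dextrose=_dextrose_pump(state),
        mode=state.mode, predicted_min_40=pred_min)
    state.last_action = action
    return state, action


def _dextrose_pump(state: MpcState) -> float:
    ml_h = state.current_dextrose * state.weight / 1000.0
    return math.floor(ml_h / PUMP_RESOLUTION_ML_H + 0.5) * PUMP_RESOLUTION_ML_H
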