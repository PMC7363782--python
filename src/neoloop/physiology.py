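"""Glucose-insulin kinetics of a virtual extremely preterm infant.

The model is a Hovorka-family two-compartment glucose system with a remote
insulin-action compartment, adapted for the neonatal intensive-care setting:
insulin is given intravenously (a single plasma compartment with first-order
elimination, no subcutaneous absorption), glucose enters as a continuous
parenteral/enteral flux, and endogenous glucose production is suppressed
multiplicatively by insulin action.  All quantities are expressed per kg of
body weight so one parameter set covers the whole cohort; glucose
concentrations are mmol/L, insulin rates U/kg/h externally and mU/kg/min
internally, time is minutes.

State variables
---------------
q1      accessible (plasma-equilibrating) glucose mass, mg/kg
q2      non-accessible glucose mass, mg/kg
i_p     plasma insulin, mU/L
x       remote insulin action, 1/min (fractional glucose clearance)
g_isf   interstitial glucose seen by the CGM, mmol/L

Two glucose-dependent loss terms keep the insulin-free system bounded, as in
the adult critical-care models this structure descends from: the
insulin-independent uptake saturates below 4.5 mmol/L (brain uptake falls with
supply) and glucose spills renally above a low neonatal threshold.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

log = logging.getLogger(__name__)

#: mg/dL per mmol/L of glucose (molar mass 180.16 g/mol).
MGDL_PER_MMOL = 18.016

#: U/kg/h -> mU/kg/min
MU_PER_MIN_PER_U_PER_H = 1000.0 / 60.0


@dataclass(frozen=True)
class PatientParams:
    """Physiological parameters of one virtual infant (per-kg convention).

    Defaults are plausible extremely-preterm values, not fitted to any
    individual data; every field is configurable.
    """

    v_g: float = 4.5          # glucose distribution volume, dL/kg
    f01: float = 2.5          # insulin-independent uptake at G >= f01_sat, mg/kg/min
    egp0: float = 4.0         # endogenous glucose production at zero action, mg/kg/min
    k12: float = 0.06         # q2 -> q1 transfer, 1/min
    k21: float = 0.03         # q1 -> q2 transfer, 1/min
    s_i: float = 1.0          # dimensionless sensitivity multiplier on insulin action
    s_base: float = 2.2e-4    # action per plasma insulin, (1/min) per (mU/L)
    k_a: float = 0.025        # insulin-action activation rate, 1/min (tau = 40 min)
    k_e: float = 0.0693       # plasma insulin elimination, 1/min (t1/2 = 10 min)
    tau_isf: float = 10.0     # plasma -> interstitium lag, min
    v_i: float = 0.12         # insulin distribution volume, L/kg
    x_egp: float = 0.05       # effective action (s_i*x) fully suppressing EGP, 1/min
    renal_thresh: float = 9.0  # renal spill threshold, mmol/L
    renal_cl: float = 0.01    # renal clearance of supra-threshold q1, 1/min
    f01_sat: float = 4.5      # glucose below which f01 scales linearly, mmol/L

    def __post_init__(self) -> None:
        for name in ("v_g", "f01", "egp0", "k12", "k21", "s_i", "s_base",
                     "k_a", "k_e", "tau_isf", "v_i", "x_egp", "f01_sat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PatientParams.{name} must be positive")
        if not (5.0 <= self.tau_isf <= 20.0):
            raise ValueError("tau_isf must lie in [5, 20] min")


@dataclass
class PatientState:
    """Instantaneous physiological state; all components non-negative."""

    q1: float      # mg/kg
    q2: float      # mg/kg
    i_p: float     # mU/L
    x: float       # 1/min
    g_isf: float   # mmol/L

    def copy(self) -> "PatientState":
        return replace(self)


@dataclass(frozen=True)
class InfusionInput:
    """External inputs over one integration step."""

    insulin_rate: float = 0.0          # U/kg/h
    dextrose20_rate: float = 0.0       # mL/kg/h of 20% dextrose
    maintenance_dextrose: float = 0.0  # mg/kg/min
    enteral_carb: float = 0.0          # mg/kg/min

    def __post_init__(self) -> None:
        for name in ("insulin_rate", "dextrose20_rate",
                     "maintenance_dextrose", "enteral_carb"):
            if getattr(self, name) < 0:
                raise ValueError(f"InfusionInput.{name} must be >= 0")


def dextrose_to_flux(rate_ml_kg_h: float, concentration_pct: float) -> float:
    """Convert a dextrose infusion rate (mL/kg/h) to a glucose flux (mg/kg/min).

    A c% w/v solution carries 10*c mg of glucose per mL, so
    flux = rate * c * 10 / 60.
    """
    if rate_ml_kg_h < 0:
        raise ValueError("dextrose rate must be >= 0")
    if not (0 < concentration_pct <= 100):
        raise ValueError("concentration must be in (0, 100] percent")
    return rate_ml_kg_h * concentration_pct * 10.0 / 60.0


def plasma_glucose(state: PatientState, params: PatientParams) -> float:
    """Plasma glucose concentration in mmol/L (q1 / V_g, mg/dL -> mmol/L)."""
    return state.q1 / params.v_g / MGDL_PER_MMOL


def total_glucose_flux(inputs: InfusionInput) -> float:
    """Exogenous glucose appearance, mg/kg/min."""
    return (inputs.maintenance_dextrose
            + dextrose_to_flux(inputs.dextrose20_rate, 20.0)
            + inputs.enteral_carb)


def insulin_mediated_uptake(state: PatientState, params: PatientParams) -> float:
    """Insulin-mediated glucose disposal s_i * x * q1, mg/kg/min."""
    return params.s_i * state.x * state.q1


def derivatives(state: PatientState, params: PatientParams,
                inputs: InfusionInput, extra_flux: float = 0.0):
    """Time derivatives of the five state variables.

    ``extra_flux`` is a signed glucose flux (mg/kg/min) added to q1; the MPC
    controller uses it for its adaptive flux correction.  Returns a 5-tuple
    (dq1, dq2, di_p, dx, dg_isf).
    """
    g = state.q1 / (params.v_g * MGDL_PER_MMOL)  # mmol/L
    flux_in = total_glucose_flux(inputs) + extra_flux
    s_eff = params.s_i * state.x
    egp = params.egp0 * max(0.0, 1.0 - s_eff / params.x_egp)
    f01_eff = params.f01 * min(1.0, g / params.f01_sat)
    renal = params.renal_cl * max(
        0.0, state.q1 - params.renal_thresh * MGDL_PER_MMOL * params.v_g)
    dq1 = (flux_in + egp - f01_eff - s_eff * state.q1 - renal
           - params.k21 * state.q1 + params.k12 * state.q2)
    dq2 = params.k21 * state.q1 - params.k12 * state.q2
    di = (inputs.insulin_rate * MU_PER_MIN_PER_U_PER_H / params.v_i
          - params.k_e * state.i_p)
    dx = params.k_a * (params.s_base * state.i_p - state.x)
    dg = (g - state.g_isf) / params.tau_isf
    return dq1, dq2, di, dx, dg


def derivatives_vec(q1, q2, i_p, x, g_isf, params: PatientParams,
                    insulin_rate, dextrose20_rate=0.0, extra_flux=0.0):
    """Vectorised twin of :func:`derivatives` over numpy arrays.

    Accepts broadcastable arrays for the state components and the infusion
    rates (maintenance/enteral fluxes fold into ``extra_flux``); used by the
    controller to evaluate whole candidate-rate grids in one sweep.  Kept in
    this module, next to the scalar form, so the two cannot silently diverge
    (a unit test asserts their equality).
    """
    g = q1 / (params.v_g * MGDL_PER_MMOL)
    flux_in = np.asarray(dextrose20_rate) * 20.0 * 10.0 / 60.0 + extra_flux
    s_eff = params.s_i * x
    egp = params.egp0 * np.maximum(0.0, 1.0 - s_eff / params.x_egp)
    f01_eff = params.f01 * np.minimum(1.0, g / params.f01_sat)
    renal = params.renal_cl * np.maximum(
        0.0, q1 - params.renal_thresh * MGDL_PER_MMOL * params.v_g)
    dq1 = (flux_in + egp - f01_eff - s_eff * q1 - renal
           - params.k21 * q1 + params.k12 * q2)
    dq2 = params.k21 * q1 - params.k12 * q2
    di = (np.asarray(insulin_rate) * MU_PER_MIN_PER_U_PER_H / params.v_i
          - params.k_e * i_p)
    dx = params.k_a * (params.s_base * i_p - x)
    dg = (g - g_isf) / params.tau_isf
    return dq1, dq2, di, dx, dg


def step(state: PatientState, params: PatientParams, inputs: InfusionInput,
         dt: float, extra_flux: float = 0.0) -> PatientState:
    """One classical 4th-order Runge-Kutta step of length ``dt`` minutes.

    dt must lie in (0, 1] for the trial-resolution integrator.  Any state
    component driven negative is clamped to zero with a logged warning rather
    than raising, so long trial runs cannot abort mid-simulation.
    """
    if not (0 < dt <= 1.0):
        raise ValueError("dt must be in (0, 1] min")
    return _rk4(state, params, inputs, dt, extra_flux)


def _rk4(state: PatientState, params: PatientParams, inputs: InfusionInput,
         dt: float, extra_flux: float = 0.0) -> PatientState:
    """RK4 update without the dt <= 1 guard (controller predictions use dt=5)."""
    y = (state.q1, state.q2, state.i_p, state.x, state.g_isf)

    def f(v):
        s = PatientState(*v)
        return derivatives(s, params, inputs, extra_flux)

    k1 = f(y)
    k2 = f(tuple(y[i] + 0.5 * dt * k1[i] for i in range(5)))
    k3 = f(tuple(y[i] + 0.5 * dt * k2[i] for i in range(5)))
    k4 = f(tuple(y[i] + dt * k3[i] for i in range(5)))
    new = [y[i] + dt / 6.0 * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i])
           for i in range(5)]
    clamped = [v if v >= 0 else 0.0 for v in new]
    if any(v < 0 for v in new):
        log.warning("negative state clamped to zero: %s", new)
    return PatientState(*clamped)


@dataclass(frozen=True)
class SteadyStateResult:
    state: PatientState
    basal_insulin: float  # U/kg/h
    reachable: bool


def steady_state(params: PatientParams, target_glucose: float,
                 inputs: InfusionInput) -> SteadyStateResult:
    """Fixed point of the model at a given plasma glucose target.

    Solves the flux balance for the effective insulin action S = s_i * x
    holding plasma glucose at ``target_glucose`` (mmol/L) under the given
    insulin-free inputs, then back-computes the constant insulin infusion
    sustaining that action.  If the balance would need negative insulin the
    target is unreachable without withdrawing glucose: the insulin-free state
    is returned with ``reachable=False`` and rate 0.
    """
    if target_glucose <= 0:
        raise ValueError("target glucose must be positive")
    q1 = target_glucose * MGDL_PER_MMOL * params.v_g
    q2 = params.k21 * q1 / params.k12
    f01_eff = params.f01 * min(1.0, target_glucose / params.f01_sat)
    renal = params.renal_cl * max(
        0.0, q1 - params.renal_thresh * MGDL_PER_MMOL * params.v_g)
    flux = total_glucose_flux(inputs)
    # unsuppressed-EGP branch: flux + egp0*(1 - S/x_egp) = f01_eff + renal + S*q1
    s_eff = (flux + params.egp0 - f01_eff - renal) / (q1 + params.egp0 / params.x_egp)
    if s_eff > params.x_egp:
        # EGP fully suppressed at the fixed point
        s_eff = (flux - f01_eff - renal) / q1
    reachable = s_eff >= 0
    if not reachable:
        s_eff = 0.0
    x = s_eff / params.s_i
    i_p = x / params.s_base
    rate_u_kg_h = params.k_e * i_p * params.v_i / MU_PER_MIN_PER_U_PER_H
    state = PatientState(q1=q1, q2=q2, i_p=i_p, x=x, g_isf=target_glucose)
    return SteadyStateResult(state=state, basal_insulin=rate_u_kg_h,
                             reachable=reachable)


def evolve_sensitivity(s_i: float, dt: float, volatility: float,
                       reversion_time: float, rng: np.random.Generator,
                       baseline: float = 1.0) -> float:
    """Mean-reverting stochastic insulin-sensitivity update (log-OU).

    The log of the sensitivity multiplier follows an Ornstein-Uhlenbeck
    process reverting to log(baseline) with time constant ``reversion_time``
    (min).  ``volatility`` is the stationary coefficient of variation of the
    multiplier itself, so the stationary median equals ``baseline`` and the
    long-run CV equals the configured value.  Uses the exact discretisation,
    valid for any dt.
    """
    if s_i <= 0:
        raise ValueError("s_i must be positive")
    if volatility <= 0:
        return s_i
    if reversion_time <= 0:
        return baseline
    sd_log = math.sqrt(math.log1p(volatility ** 2))
    phi = math.exp(-dt / reversion_time)
    z = rng.standard_normal()
    ln_new = (math.log(baseline) + (math.log(s_i) - math.log(baseline)) * phi
              + sd_log * math.sqrt(1.0 - phi * phi) * z)
    return math.exp(ln_new)
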