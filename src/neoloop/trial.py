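"""Orchestration of the in-silico randomised trial.

Each virtual infant is monitored by CGM for up to 160 hours from birth.
Outside the prespecified 48-72 h intervention window both arms are managed
by the ward paper guideline; inside the window the closed-loop arm switches
to the adaptive MPC controller (with the finer 5 U/kg/50 mL insulin
dilution and 6-hourly sensor calibration) while the control arm continues
on the guideline (25 U/kg/50 mL, 12-hourly calibration).

``run_window`` simulates only the intervention window from a baseline
steady state drawn around the study's entry glucose (median ~8 mmol/L) —
the surrogate used for the headline between-arm contrasts; ``run_arm`` /
``run_trial`` run the full protocol.
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import control_guideline as guideline
from . import control_mpc as mpc
from . import physiology as phys
from . import sensing
from .cohort import (ArmAssignment, CohortSpec, InfantProfile,
                     assign_arms_minimisation, cohort_to_frame,
                     frame_to_cohort, sample_cohort)
from .physiology import InfusionInput, PatientParams, PatientState

REQUIRED_COLUMNS = ("time_min", "sg", "bg", "plasma_glucose",
                    "insulin_u_kg_h", "dextrose20_ml_kg_h",
                    "maintenance_dextrose", "event")


class SchemaError(ValueError):
    """A trial CSV does not match the expected schema."""


@dataclass(frozen=True)
class Protocol:
    total_h: float = 160.0
    window_start_h: float = 48.0
    window_end_h: float = 72.0           # half-open window [start, end)
    dt_min: float = 1.0
    cgm_period_min: int = 5
    control_period_min: int = 15
    cal_ward_h: float = 12.0
    cal_loop_h: float = 6.0
    eval_period_min: int = 60
    bg_checks_per_day: float = 5.5
    dropout_rate_per_min: float = 1.0 / (72.0 * 60.0)
    dropout_max_min: float = 210.0
    cgm_noise_cv: float = 0.07
    bg_meter_sd: float = 0.3
    sens_reversion_min: float = 720.0    # sensitivity mean-reversion time
    baseline_glucose_median: float = 8.0  # mmol/L at 48 h window entry
    baseline_glucose_sd_log: float = 0.25
    birth_glucose_median: float = 5.5
    birth_glucose_sd_log: float = 0.15
    ward_insulin_conc: float = 25.0      # U/kg per 50 mL
    loop_insulin_conc: float = 5.0
    review_dextrose_rate: float = 0.5    # mL/kg/h nurse response to review flag
    fluid_change_events: bool = False
    fluid_change_min: float = 30.0       # line-change interruption length

    def __post_init__(self) -> None:
        if not (0 <= self.window_start_h < self.window_end_h <= self.total_h):
            raise ValueError("intervention window must lie within the protocol")
        if self.control_period_min % self.cgm_period_min:
            raise ValueError("control period must be a multiple of CGM period")


@dataclass
class TrialRecord:
    infant_id: str
    arm: str
    seed: int
    data: pd.DataFrame

    @property
    def events(self) -> pd.DataFrame:
        ev = self.data[self.data["event"] != ""][["time_min", "event"]]
        return ev.reset_index(drop=True)


@dataclass
class TrialDataset:
    records: List[TrialRecord]
    cohort: List[InfantProfile]
    assignment: ArmAssignment
    config: Dict
    seed: int

    def by_arm(self, arm: str) -> List[TrialRecord]:
        return [r for r in self.records if r.arm == arm]


def _ward_quantise(rate: float) -> float:
    """Deliverable dose on the ward dilution (0.1 mL/h at 25 U/kg/50 mL).

    Non-zero advised rates deliver at least one pump step (0.05 U/kg/h).
    """
    step = mpc.PUMP_RESOLUTION_ML_H * 25.0 / 50.0
    if rate <= 0:
        return 0.0
    return max(step, math.floor(rate / step + 0.5) * step)


def _params_for(profile: InfantProfile, s_i: float = 1.0) -> PatientParams:
    return PatientParams(egp0=profile.egp0,
                         s_base=profile.baseline_insulin_sensitivity,
                         s_i=s_i)


class _Engine:
    """Minute-resolution simulation of one infant over [t0, t1) minutes."""

    def __init__(self, profile: InfantProfile, arm: str, protocol: Protocol,
                 seed: int, t0: int, t1: int,
                 init_state: PatientState, init_params: PatientParams,
                 init_insulin: float):
        self.profile, self.arm, self.pr = profile, arm, protocol
        self.t0, self.t1 = t0, t1
        ss = np.random.SeedSequence(seed)
        (self.rng_sens, self.rng_sensor, self.rng_meter, self.rng_drop,
         self.rng_sched) = [np.random.default_rng(s) for s in ss.spawn(5)]
        self.state = init_state
        self.params = init_params
        self.current_insulin = init_insulin
        self.current_dextrose = 0.0
        self.sensor = sensing.new_sensor(self.rng_sensor)
        windows = sensing.schedule_dropouts(
            t1 - t0, self.rng_drop, protocol.dropout_max_min,
            protocol.dropout_rate_per_min)
        self.sensor = replace(
            self.sensor,
            dropout_windows=tuple((a + t0, b + t0) for a, b in windows),
            last_calibration=float(t0))
        sched = guideline.evaluation_schedule(
            t1 - t0, self.rng_sched, bg_per_day=protocol.bg_checks_per_day,
            cal_period=protocol.cal_ward_h * 60.0)
        self.clinical_bg = {int(round(t + t0)) for t in sched.bg_times
                            if t + t0 < t1} - {
            int(round(c + t0)) for c in sched.calibration_times}
        self.rules = guideline.default_rules()
        self.history: List[sensing.GlucoseReading] = []
        self.mpc_state: Optional[mpc.MpcState] = None
        self.was_holding = False
        self.review_active = False
        self.rows: List[dict] = []
        self.fluid_change_until = -1.0

    # -- helpers ---------------------------------------------------------
    def _in_window(self, t: int) -> bool:
        return (self.pr.window_start_h * 60 <= t < self.pr.window_end_h * 60)

    def _mpc_phase(self, t: int) -> bool:
        return self.arm == "closed_loop" and self._in_window(t)

    def _cal_due(self, t: int) -> bool:
        if self._mpc_phase(t):
            period = self.pr.cal_loop_h * 60.0
            return (t - self.pr.window_start_h * 60) % period == 0
        return t % (self.pr.cal_ward_h * 60.0) == 0 and t > self.t0

    def _maintenance(self, t: int) -> float:
        base = self.profile.nutrition.maintenance_dextrose
        if self.pr.fluid_change_events and t < self.fluid_change_until:
            return 0.5 * base
        return base

    def _meter(self, t: int) -> sensing.GlucoseReading:
        pg = phys.plasma_glucose(self.state, self.params)
        return sensing.bg_meter_read(pg, self.rng_meter,
                                     sd=self.pr.bg_meter_sd, t=float(t))

    # -- main loop -------------------------------------------------------
    def run(self) -> TrialRecord:
        pr = self.pr
        events: List[str] = []
        last_sg: Optional[sensing.GlucoseReading] = None
        prev_sg_value: Optional[float] = None
        for t in range(self.t0, self.t1):
            bg_val = float("nan")
            sg_reading = None
            if t % pr.cgm_period_min == 0:
                sg_reading = sensing.cgm_read(
                    self.state.g_isf, self.sensor, float(t),
                    self.rng_sensor, noise_cv=pr.cgm_noise_cv)
                if sg_reading is not None:
                    self.history.append(sg_reading)
                    if len(self.history) > 64:
                        del self.history[0]
                elif last_sg is not None and last_sg.time == t - pr.cgm_period_min:
                    events.append("dropout")
            if pr.fluid_change_events and t > self.t0 and t % 1440 == 0:
                self.fluid_change_until = t + pr.fluid_change_min
                events.append("fluid_change")

            if self._cal_due(t):
                bg = self._meter(t)
                bg_val = bg.value
                if sg_reading is not None and sg_reading.value > 0 and bg.value > 0:
                    self.sensor = sensing.calibrate(
                        self.sensor, bg.value, sg_reading.value, float(t))
                    events.append("calibration")
                else:
                    events.append("calibration_skipped")
                if bg.value < 2.6:
                    events.append("hypo_bg")
            elif t in self.clinical_bg:
                bg = self._meter(t)
                bg_val = bg.value
                events.append("bg_check")
                if bg.value < 2.6:
                    events.append("hypo_bg")

            if self._mpc_phase(t):
                if t == pr.window_start_h * 60:
                    self.mpc_state = mpc.mpc_init(
                        self.profile.birth_weight,
                        config=mpc.MpcConfig(insulin_conc=pr.loop_insulin_conc))
                    events.append("window_start")
                if t % pr.control_period_min == 0:
                    bg_arg = None
                    if sg_reading is None and t % 60 == 0:
                        bg_arg = self._meter(t)
                        bg_val = bg_arg.value
                        events.append("fallback_bg")
                    self.mpc_state, action = mpc.mpc_cycle(
                        self.mpc_state, float(t), sg=sg_reading, bg=bg_arg)
                    self.current_insulin = action.insulin_rate
                    self.current_dextrose = action.dextrose20_rate
                    if action.mode == "hold" and not self.was_holding:
                        events.append("hold_alarm")
                    self.was_holding = action.mode == "hold"
            else:
                if (self.arm == "closed_loop"
                        and t == pr.window_end_h * 60):
                    self.current_dextrose = 0.0
                    self.current_insulin = _ward_quantise(self.current_insulin)
                    events.append("window_end")
                alarm = (sg_reading is not None
                         and (sg_reading.value < 3.5
                              or (sg_reading.value > 10.0
                                  and prev_sg_value is not None
                                  and prev_sg_value <= 10.0)))
                fresh = (last_sg is not None
                         and last_sg.time >= t - pr.control_period_min) or \
                        (sg_reading is not None)
                if (t % pr.eval_period_min == 0 or alarm) and fresh and t > self.t0:
                    sg_now = (sg_reading or last_sg).value
                    tr = guideline.trend(self.history)
                    new_rate, review = guideline.guideline_decide(
                        sg_now, tr, self.current_insulin, self.rules)
                    self.current_insulin = _ward_quantise(new_rate)
                    if review:
                        if not self.review_active:
                            events.append("dextrose_review")
                            self.current_dextrose = pr.review_dextrose_rate
                        else:
                            # still low at re-review: escalate the rescue
                            self.current_dextrose = min(
                                self.current_dextrose + pr.review_dextrose_rate,
                                4.0 * pr.review_dextrose_rate)
                        self.review_active = True
                    elif sg_now >= 4.0 and self.review_active:
                        self.review_active = False
                        self.current_dextrose = 0.0

            if sg_reading is not None:
                prev_sg_value = sg_reading.value
                last_sg = sg_reading

            if t % pr.cgm_period_min == 0:
                self.rows.append({
                    "time_min": float(t),
                    "sg": sg_reading.value if sg_reading else float("nan"),
                    "bg": bg_val,
                    "plasma_glucose": phys.plasma_glucose(self.state,
                                                          self.params),
                    "insulin_u_kg_h": self.current_insulin,
                    "dextrose20_ml_kg_h": self.current_dextrose,
                    "maintenance_dextrose": self._maintenance(t),
                    "event": ";".join(events),
                })
                events = []

            s_i = phys.evolve_sensitivity(
                self.params.s_i, pr.dt_min,
                self.profile.sensitivity_volatility,
                pr.sens_reversion_min, self.rng_sens)
            self.params = replace(self.params, s_i=s_i)
            inputs = InfusionInput(
                insulin_rate=self.current_insulin,
                dextrose20_rate=self.current_dextrose,
                maintenance_dextrose=self._maintenance(t),
                enteral_carb=self.profile.nutrition.enteral_carb)
            self.state = phys.step(self.state, self.params, inputs, pr.dt_min)

        df = pd.DataFrame(self.rows, columns=list(REQUIRED_COLUMNS))
        return TrialRecord(infant_id=self.profile.id, arm=self.arm,
                           seed=-1, data=df)


def run_arm(profile: InfantProfile, arm: str, protocol: Protocol,
            seed: int) -> TrialRecord:
    """Full-protocol simulation of one infant from birth; deterministic."""
    if arm not in ("closed_loop", "control"):
        raise ValueError(f"unknown arm {arm!r}")
    rng_init = np.random.default_rng(np.random.SeedSequence((seed, 9)))
    pg0 = protocol.birth_glucose_median * float(
        np.exp(rng_init.normal(0.0, protocol.birth_glucose_sd_log)))
    s_i0 = _stationary_sensitivity(profile, rng_init)
    params = _params_for(profile, s_i=s_i0)
    q1 = pg0 * phys.MGDL_PER_MMOL * params.v_g
    state = PatientState(q1=q1, q2=params.k21 * q1 / params.k12,
                         i_p=0.0, x=0.0, g_isf=pg0)
    eng = _Engine(profile, arm, protocol, seed, 0,
                  int(protocol.total_h * 60), state, params, 0.0)
    rec = eng.run()
    rec.seed = seed
    return rec


def _stationary_sensitivity(profile: InfantProfile,
                            rng: np.random.Generator) -> float:
    cv = profile.sensitivity_volatility
    if cv <= 0:
        return 1.0
    sd = math.sqrt(math.log1p(cv * cv))
    return float(np.exp(rng.normal(0.0, sd)))


def run_window(profile: InfantProfile, controller: str, protocol: Protocol,
               seed: int) -> TrialRecord:
    """Intervention-window-only simulation (the 24 h surrogate trial).

    The infant enters the window at a baseline glucose drawn log-normally
    around the study entry level, in steady state on the ward insulin rate
    that sustains it (quantised to the ward pump grid).
    """
    if controller not in ("mpc", "guideline"):
        raise ValueError(f"unknown controller {controller!r}")
    arm = "closed_loop" if controller == "mpc" else "control"
    rng_init = np.random.default_rng(np.random.SeedSequence((seed, 9)))
    pg0 = protocol.baseline_glucose_median * float(
        np.exp(rng_init.normal(0.0, protocol.baseline_glucose_sd_log)))
    pg0 = min(max(pg0, 4.0), 15.0)
    s_i0 = _stationary_sensitivity(profile, rng_init)
    params = _params_for(profile, s_i=s_i0)
    inputs = InfusionInput(
        maintenance_dextrose=profile.nutrition.maintenance_dextrose,
        enteral_carb=profile.nutrition.enteral_carb)
    ss = phys.steady_state(params, pg0, inputs)
    u0 = _ward_quantise(ss.basal_insulin) if ss.reachable else 0.0
    eng = _Engine(profile, arm, protocol, seed,
                  int(protocol.window_start_h * 60),
                  int(protocol.window_end_h * 60),
                  ss.state.copy(), params, u0)
    rec = eng.run()
    rec.seed = seed
    return rec


def run_trial(cohort_spec: CohortSpec, protocol: Protocol,
              seed: int) -> TrialDataset:
    """Sample a cohort, minimisation-assign arms, run every infant."""
    root = np.random.SeedSequence(seed)
    sub = root.spawn(3)
    cohort_seed = int(sub[0].generate_state(1)[0] % (2 ** 31))
    assign_seed = int(sub[1].generate_state(1)[0] % (2 ** 31))
    spec = replace(cohort_spec, seed=cohort_seed)
    profiles = sample_cohort(spec)
    records: List[TrialRecord] = []
    if profiles:
        assignment = assign_arms_minimisation(profiles, seed=assign_seed)
        infant_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                        for s in sub[2].spawn(len(profiles))]
        for p, s in zip(profiles, infant_seeds):
            records.append(run_arm(p, assignment.arms[p.id], protocol, s))
    else:
        assignment = ArmAssignment(arms={}, strata={})
    config = {"protocol": asdict(protocol), "cohort_spec": asdict(spec)}
    return TrialDataset(records=records, cohort=profiles,
                        assignment=assignment, config=config, seed=seed)


def run_window_cohort(cohort_spec: CohortSpec, protocol: Protocol, seed: int,
                      controller: str) -> List[TrialRecord]:
    """Window-only surrogate: every sampled infant under one controller.

    Sharing ``seed`` between controllers yields a paired comparison: the same
    infants, sensitivity trajectories and sensor noise, differing only in how
    insulin is titrated.
    """
    root = np.random.SeedSequence((seed, 17))
    spec = replace(cohort_spec,
                   seed=int(root.generate_state(1)[0] % (2 ** 31)))
    profiles = sample_cohort(spec)
    infant_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                    for s in root.spawn(len(profiles))]
    return [run_window(p, controller, protocol, s)
            for p, s in zip(profiles, infant_seeds)]


# -- persistence ---------------------------------------------------------

def save_dataset(dataset: TrialDataset, path: str) -> None:
    """One CSV per infant plus a JSON manifest with config and assignment."""
    os.makedirs(path, exist_ok=True)
    files = {}
    for rec in dataset.records:
        fname = f"{rec.infant_id}.csv"
        rec.data.to_csv(os.path.join(path, fname), index=False)
        files[rec.infant_id] = {"file": fname, "arm": rec.arm,
                                "seed": rec.seed}
    cohort_to_frame(dataset.cohort, dataset.assignment).to_csv(
        os.path.join(path, "cohort.csv"), index=False)
    manifest = {
        "seed": dataset.seed,
        "config": dataset.config,
        "arms": dataset.assignment.arms,
        "strata": dataset.assignment.strata,
        "records": files,
    }
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_dataset(path: str) -> TrialDataset:
    with open(os.path.join(path, "manifest.json")) as fh:
        manifest = json.load(fh)
    cohort = frame_to_cohort(pd.read_csv(os.path.join(path, "cohort.csv")))
    records = []
    for infant_id, meta in sorted(manifest["records"].items()):
        df = pd.read_csv(os.path.join(path, meta["file"]),
                         keep_default_na=True)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{meta['file']}: missing columns {missing}")
        df["event"] = df["event"].fillna("")
        records.append(TrialRecord(infant_id=infant_id, arm=meta["arm"],
                                   seed=meta["seed"], data=df))
    assignment = ArmAssignment(
        arms=manifest["arms"],
        strata={k: {f: int(c) for f, c in v.items()}
                for k, v in manifest["strata"].items()})
    return TrialDataset(records=records, cohort=cohort,
                        assignment=assignment, config=manifest["config"],
                        seed=manifest["seed"])
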