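"""Nurse-executed paper-guideline insulin titration from SG value and trend.

The comparator arm mimics ward practice: the bedside guideline is consulted
hourly (and at threshold-crossing alarms), reads the absolute sensor glucose
together with its trailing trend, and advises starting, stepping, or
stopping the insulin infusion, or reviewing dextrose support at low glucose.
The published guideline table itself is not available, so the shipped
default rules are an explicit reconstruction (editable YAML in
``neoloop/data/guideline_rules.yaml``): start 0.02 U/kg/h above 10 mmol/L,
+/-50% steps, stop below 4, dextrose review below 3.5.  Its quantitative
behaviour is a plausible ward comparator, not a transcription.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .sensing import GlucoseReading

INF = float("inf")

ACTIONS = ("none", "start_insulin", "increase", "decrease", "stop_insulin",
           "start_dextrose_review")


@dataclass(frozen=True)
class Rule:
    """One row: SG band [sg_lo, sg_hi) x trend band [trend_lo, trend_hi)."""

    sg_lo: float
    sg_hi: float
    trend_lo: float
    trend_hi: float
    action: str
    magnitude: float = 0.0   # start dose (U/kg/h) or fractional step

    def matches(self, sg: float, trend: float) -> bool:
        return (self.sg_lo <= sg < self.sg_hi
                and self.trend_lo <= trend < self.trend_hi)


@dataclass(frozen=True)
class GuidelineRules:
    rows: Tuple[Rule, ...]
    start_dose: float = 0.02       # U/kg/h
    step_fraction: float = 0.5     # relative up/down titration step

    def __post_init__(self) -> None:
        for r in self.rows:
            if r.action not in ACTIONS:
                raise ValueError(f"unknown action {r.action!r}")


def default_rules() -> GuidelineRules:
    """The shipped reconstruction of the ward titration table."""
    rows = (
        Rule(0.0, 3.5, -INF, INF, "start_dextrose_review"),
        Rule(3.5, 4.0, -INF, INF, "stop_insulin"),
        Rule(4.0, 8.0, -INF, -1.0, "decrease", 0.5),
        Rule(4.0, 8.0, -1.0, INF, "none"),
        Rule(8.0, 10.0, 0.5, INF, "increase", 0.5),
        Rule(8.0, 10.0, -INF, 0.5, "none"),
        Rule(10.0, INF, -INF, -1.0, "none"),      # already falling fast
        Rule(10.0, INF, -1.0, INF, "start_insulin", 0.02),
    )
    return GuidelineRules(rows=rows)


def load_rules(path=None) -> GuidelineRules:
    """Load a rules table from YAML (the shipped default when path is None)."""
    if path is None:
        text = resources.files("neoloop.data").joinpath(
            "guideline_rules.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    rows = tuple(
        Rule(sg_lo=float(r.get("sg_lo", 0.0)),
             sg_hi=float(r["sg_hi"]) if r.get("sg_hi") is not None else INF,
             trend_lo=float(r["trend_lo"]) if r.get("trend_lo") is not None else -INF,
             trend_hi=float(r["trend_hi"]) if r.get("trend_hi") is not None else INF,
             action=str(r["action"]),
             magnitude=float(r.get("magnitude", 0.0)))
        for r in doc["rules"])
    return GuidelineRules(rows=rows,
                          start_dose=float(doc.get("start_dose", 0.02)),
                          step_fraction=float(doc.get("step_fraction", 0.5)))


def trend(readings: Sequence[GlucoseReading], window: float = 60.0) -> float:
    """Least-squares SG slope (mmol/L per hour) over the trailing window.

    With fewer than two readings in the window the trend is treated as 0.
    """
    if not readings:
        return 0.0
    t_end = readings[-1].time
    pts = [(r.time, r.value) for r in readings if r.time >= t_end - window]
    if len(pts) < 2:
        return 0.0
    t = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    slope_per_min = np.polyfit(t, v, 1)[0]
    return float(slope_per_min * 60.0)


def guideline_decide(sg: float, trend_mmol_h: float, current_insulin: float,
                     rules: Optional[GuidelineRules] = None
                     ) -> Tuple[float, bool]:
    """Apply the first matching rule; returns (new rate, dextrose-review flag).

    ``start_insulin`` with an infusion already running escalates by the
    table's step fraction instead; ``increase`` with no infusion running
    leaves it off (insulin starts only through a start rule).  Rates are
    floored at zero.  With no matching rule the rate is unchanged.
    """
    rules = rules or default_rules()
    for rule in rules.rows:
        if not rule.matches(sg, trend_mmol_h):
            continue
        if rule.action == "none":
            return current_insulin, False
        if rule.action == "stop_insulin":
            return 0.0, False
        if rule.action == "start_dextrose_review":
            return 0.0, True
        if rule.action == "start_insulin":
            if current_insulin <= 0:
                return (rule.magnitude or rules.start_dose), False
            return current_insulin * (1.0 + rules.step_fraction), False
        if rule.action == "increase":
            if current_insulin <= 0:
                return 0.0, False
            return current_insulin * (1.0 + (rule.magnitude
                                             or rules.step_fraction)), False
        if rule.action == "decrease":
            frac = rule.magnitude or rules.step_fraction
            return max(0.0, current_insulin * (1.0 - frac)), False
    return current_insulin, False


@dataclass(frozen=True)
class EvaluationSchedule:
    eval_times: Tuple[float, ...]   # hourly guideline evaluations, min
    bg_times: Tuple[float, ...]     # all BG checks incl. calibrations, min
    calibration_times: Tuple[float, ...]


def evaluation_schedule(duration: float, rng: np.random.Generator,
                        bg_per_day: float = 5.5,
                        cal_period: float = 720.0,
                        eval_period: float = 60.0) -> EvaluationSchedule:
    """Ward sampling pattern over ``duration`` minutes.

    Guideline evaluations are hourly; BG checks combine the 12-h calibration
    cadence with Poisson-arriving clinical checks at a rate chosen so the
    expected total matches ``bg_per_day`` (the calibrations count towards
    it).  All times are sorted and lie in [0, duration].
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    evals = tuple(np.arange(eval_period, duration + 1e-9, eval_period))
    cals = tuple(np.arange(cal_period, duration + 1e-9, cal_period))
    cal_per_day = 1440.0 / cal_period
    extra_rate = max(0.0, bg_per_day - cal_per_day) / 1440.0  # per min
    extras: List[float] = []
    if extra_rate > 0:
        t = 0.0
        while True:
            t += rng.exponential(1.0 / extra_rate)
            if t >= duration:
                break
            extras.append(t)
    bg = tuple(sorted(list(cals) + extras))
    return EvaluationSchedule(eval_times=evals, bg_times=bg,
                              calibration_times=cals)
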