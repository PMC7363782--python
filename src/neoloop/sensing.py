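"""CGM sensor and point-of-care blood-glucose meter models.

The CGM reads interstitial glucose through a multiplicative gain that drifts
linearly between calibrations and is rescaled whenever a reference blood
glucose (BG) is entered.  Readings carry multiplicative log-normal noise and
are quantised to the 0.1 mmol/L display precision; the sensor can drop out
for bounded episodes.  The BG meter has additive unbiased Gaussian error.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

GAIN_BOUNDS = (0.5, 2.0)


def quantise(value: float, step: float = 0.1) -> float:
    """Round half-up to the display step (deterministic, no banker's ties)."""
    return math.floor(value / step + 0.5) * step


@dataclass(frozen=True)
class GlucoseReading:
    time: float          # min
    value: float         # mmol/L, quantised to 0.1
    source: str          # "sg" or "bg"


@dataclass(frozen=True)
class SensorState:
    gain: float                 # dimensionless, clamped to [0.5, 2.0]
    drift_rate: float           # fraction per hour since last calibration
    last_calibration: float     # min
    dropout_windows: Tuple[Tuple[float, float], ...] = ()
    clamped: bool = False       # last calibration hit the gain bound


def new_sensor(rng: np.random.Generator, gain_sd: float = 0.05,
               drift_range: float = 0.02) -> SensorState:
    """A freshly inserted sensor: gain near 1, a fixed drift rate drawn
    uniformly in +/- ``drift_range`` per hour."""
    gain = float(np.exp(rng.normal(0.0, gain_sd)))
    drift = float(rng.uniform(-drift_range, drift_range))
    gain = min(max(gain, GAIN_BOUNDS[0]), GAIN_BOUNDS[1])
    return SensorState(gain=gain, drift_rate=drift, last_calibration=0.0)


def _effective_gain(sensor: SensorState, t: float) -> float:
    drift = sensor.drift_rate * (t - sensor.last_calibration) / 60.0
    return sensor.gain * (1.0 + drift)


def in_dropout(sensor: SensorState, t: float) -> bool:
    return any(a <= t < b for a, b in sensor.dropout_windows)


def cgm_read(g_isf: float, sensor: SensorState, t: float,
             rng: np.random.Generator,
             noise_cv: float = 0.07) -> Optional[GlucoseReading]:
    """One sensor-glucose reading, or None while the signal is lost.

    value = g_isf * gain * (1 + drift since calibration) * noise, with
    multiplicative log-normal noise of mean 1 and CV ``noise_cv``, quantised
    to 0.1 mmol/L.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if in_dropout(sensor, t):
        return None
    value = g_isf * _effective_gain(sensor, t)
    if noise_cv > 0:
        sd = math.sqrt(math.log1p(noise_cv ** 2))
        value *= math.exp(rng.normal(0.0, sd) - 0.5 * sd * sd)
    return GlucoseReading(time=t, value=max(0.0, quantise(value)), source="sg")


def calibrate(sensor: SensorState, bg_ref: float, raw_sg: float,
              t: float) -> SensorState:
    """Rescale the gain so a noiseless re-read at ``t`` returns ``bg_ref``.

    The accumulated drift is folded into the new gain and the drift clock
    restarts.  Gains outside [0.5, 2.0] are clamped and flagged.
    """
    if bg_ref <= 0 or raw_sg <= 0:
        raise ValueError("calibration inputs must be positive")
    eff = _effective_gain(sensor, t)
    new_gain = eff * (bg_ref / raw_sg)
    clamped = not (GAIN_BOUNDS[0] <= new_gain <= GAIN_BOUNDS[1])
    new_gain = min(max(new_gain, GAIN_BOUNDS[0]), GAIN_BOUNDS[1])
    return replace(sensor, gain=new_gain, last_calibration=t, clamped=clamped)


def bg_meter_read(plasma_glucose: float, rng: np.random.Generator,
                  sd: float = 0.3, t: float = 0.0) -> GlucoseReading:
    """Point-of-care meter: unbiased Gaussian error, floored at 0, 0.1 steps."""
    if plasma_glucose < 0:
        raise ValueError("plasma glucose must be >= 0")
    value = plasma_glucose + (rng.normal(0.0, sd) if sd > 0 else 0.0)
    return GlucoseReading(time=t, value=max(0.0, quantise(value)), source="bg")


def schedule_dropouts(duration: float, rng: np.random.Generator,
                      max_episode: float = 210.0,
                      rate_per_min: float = 1.0 / (72.0 * 60.0)
                      ) -> List[Tuple[float, float]]:
    """Sensor signal-loss episodes over ``duration`` minutes.

    Episodes arrive as a Poisson process (default one per 72 h) and last
    Uniform(0, max_episode] minutes — the cap mirrors the longest loss the
    closed-loop protocol tolerates on sensor data alone (3.5 h).  Windows are
    returned sorted and non-overlapping, truncated at ``duration``.
    """
    if max_episode > duration:
        raise ValueError("max_episode must be <= duration")
    windows: List[Tuple[float, float]] = []
    if rate_per_min <= 0:
        return windows
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_per_min)
        if t >= duration:
            break
        end = min(t + rng.uniform(0.0, max_episode), duration)
        if windows and t < windows[-1][1]:
            t = max(t, windows[-1][1])
            if t >= end:
                continue
        windows.append((t, end))
        t = end
    return windows
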