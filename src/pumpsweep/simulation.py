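"""Closed-loop engine: one patient, one controller, one meal scenario.

The reference scenario is a single simulated day with three announced
meals of 40, 50 and 70 g of carbohydrate at 07:00, 12:00 and 19:00, no
meal boluses and no exercise.  The per-run control-goodness value is the
mean absolute deviation of interstitial glucose from 6.66 mmol/L (an
*error*: lower is better; the global extremum of an evaluation grid is
its minimum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .controllers import make_controller
from .patient import PatientParams, equilibrium_state, sample_cgm, step_model

__all__ = [
    "GLYCEMIC_TARGET",
    "DEFAULT_MEALS",
    "Scenario",
    "GlucoseTrace",
    "run_closed_loop",
    "average_error",
    "time_in_range",
]

#: Glycemic target used by the average-error metric (mmol/L).
GLYCEMIC_TARGET = 6.66

#: Single-day certified meal plan: (time-of-day in minutes, grams).
DEFAULT_MEALS = ((420, 40.0), (720, 50.0), (1140, 70.0))


@dataclass(frozen=True)
class Scenario:
    """A single-day simulation scenario (at most three meals)."""

    duration: float = 1440.0          # min
    meals: tuple = DEFAULT_MEALS      # ((time-of-day min, grams), ...)
    sampling_interval: float = 5.0    # min
    cgm_noise_sd: float = 0.0         # mmol/L
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.cgm_noise_sd < 0:
            raise ValueError("cgm_noise_sd must be >= 0")
        if len(self.meals) > 3:
            raise ValueError("at most 3 meals per day are supported")
        for t_meal, grams in self.meals:
            if not 0 <= t_meal < self.duration:
                raise ValueError("meal times must lie within the duration")
            if grams < 0:
                raise ValueError("meal grams must be >= 0")


@dataclass
class GlucoseTrace:
    """Sampled IG/BG trajectory plus the insulin and carbohydrate logs."""

    samples: list            # [(t, IG, BG), ...]
    insulin_log: list        # [(t, basal rate U/hr), ...]
    carb_log: list           # [(t, grams), ...]

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as one row per sample: t_min, IG, BG, basal_Uhr, carbs_g."""
        rate = dict((t, r) for t, r in self.insulin_log)
        carbs = dict((t, g) for t, g in self.carb_log)
        rows = [(t, ig, bg, rate.get(t, 0.0), carbs.get(t, 0.0))
                for t, ig, bg in self.samples]
        return pd.DataFrame(rows, columns=["t_min", "IG", "BG",
                                           "basal_Uhr", "carbs_g"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GlucoseTrace":
        df = pd.read_csv(path)
        samples = list(zip(df.t_min, df.IG, df.BG))
        insulin_log = list(zip(df.t_min, df.basal_Uhr))
        carb_log = [(t, g) for t, g in zip(df.t_min, df.carbs_g) if g > 0]
        return cls(samples=samples, insulin_log=insulin_log, carb_log=carb_log)


def run_closed_loop(patient: PatientParams, controller,
                    scenario: Scenario) -> GlucoseTrace:
    """Simulate one closed-loop day and return the glucose trace.

    ``controller`` is either a controller instance (reset before use) or a
    ``(name, params)`` pair resolved through the plug-in registry.  The
    patient starts at their fasting equilibrium.  At each sampling
    instant: announce any meal due, sample the CGM, ask the controller for
    a decision, then advance the model by one sampling interval with that
    basal rate (and the meal carbohydrates as an impulse).  Deterministic
    for a fixed scenario seed.
    """
    if isinstance(controller, tuple):
        name, params = controller
        controller = make_controller(name, params, patient=patient)
    else:
        controller.reset()

    rng = np.random.default_rng(np.random.SeedSequence([max(0, scenario.seed)]))
    state = equilibrium_state(patient)
    meals = sorted(scenario.meals)
    n_steps = int(round(scenario.duration / scenario.sampling_interval))
    dt = scenario.sampling_interval

    samples, insulin_log, carb_log = [], [], []
    meal_idx = 0
    for k in range(n_steps):
        t = k * dt
        carbs_now = 0.0
        while meal_idx < len(meals) and meals[meal_idx][0] < t + dt:
            mt, grams = meals[meal_idx]
            if mt >= t:  # meals align to the sampling lattice in practice
                carbs_now += grams
                carb_log.append((t, grams))
                controller.on_carbs(t, grams)
            meal_idx += 1
        ig_reading = sample_cgm(state, scenario.cgm_noise_sd, rng)
        decision = controller.decide(ig_reading, t)
        samples.append((t, ig_reading, state.G))
        insulin_log.append((t, decision.basal_rate))
        state = step_model(state, patient,
                           {"basal_rate": decision.basal_rate,
                            "bolus": decision.bolus,
                            "carbs": carbs_now}, dt)
    return GlucoseTrace(samples=samples, insulin_log=insulin_log,
                        carb_log=carb_log)


def average_error(trace: GlucoseTrace,
                  target: float = GLYCEMIC_TARGET) -> float:
    """Mean absolute deviation of the sampled IG from the target (mmol/L)."""
    if not trace.samples:
        raise ValueError("trace has no samples")
    ig = np.asarray([s[1] for s in trace.samples], dtype=float)
    return float(np.mean(np.abs(ig - target)))


def time_in_range(trace: GlucoseTrace, low: float = 3.5,
                  high: float = 7.5) -> float:
    """Fraction of samples with IG inside the normoglycemic band [low, high]."""
    if not trace.samples:
        raise ValueError("trace has no samples")
    ig = np.asarray([s[1] for s in trace.samples], dtype=float)
    return float(np.mean((ig >= low) & (ig <= high)))
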