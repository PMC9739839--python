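"""Pluggable CSII controllers: low-glucose suspend and a rule-based stand-in.

Two controllers are provided, each exposing the two parameters swept by the
evaluation grid:

* **LGS** (low-glucose suspend): delivers a constant default basal rate *b*
  and suspends delivery for a fixed period (default 30 min) whenever the
  CGM reading drops below the threshold theta.
* **oref-like**: a transparent three-rule basal modulator in the spirit of
  the OpenAPS oref0 family, using a 30-min linear trend projection,
  insulin-on-board (IOB) and carbs-on-board (COB) with linear decay to
  predict an eventual glucose, then setting a temp basal of 0, *b*, or an
  elevated rate capped at ``max_multiplier * b``.  It is deliberately a
  simplified, fully documented controller — not a reimplementation of
  oref0/oref1 — chosen to exercise the same swept parameters (*b* and the
  insulin sensitivity factor *s*) with rule-based discontinuities.

Controllers never dose meal boluses; meals reach them only as carbohydrate
announcements.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ControllerDecision",
    "LgsConfig",
    "OrefLikeConfig",
    "lgs_step",
    "insulin_on_board",
    "carbs_on_board",
    "oref_like_step",
    "LgsController",
    "OrefLikeController",
    "CONTROLLERS",
    "make_controller",
]

#: Number of sampling intervals ahead the oref-like controller projects the
#: CGM trend (6 x 5 min = 30 min horizon).
TREND_HORIZON_STEPS = 6

#: Half-width of the oref-like in-range deadband around the target (mmol/L).
DEADBAND = 1.0


@dataclass(frozen=True)
class ControllerDecision:
    """One controller output: a temp basal rate and a (always-zero) bolus."""

    basal_rate: float  # U/hr
    bolus: float = 0.0  # U

    def __post_init__(self):
        if self.basal_rate < 0 or self.bolus < 0:
            raise ValueError("decision components must be non-negative")


@dataclass(frozen=True)
class LgsConfig:
    """LGS parameters: default basal *b* (U/hr), threshold theta (mmol/L)."""

    b: float
    theta: float
    suspend_minutes: float = 30.0

    def __post_init__(self):
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.suspend_minutes <= 0:
            raise ValueError("suspend_minutes must be > 0")


@dataclass(frozen=True)
class OrefLikeConfig:
    """oref-like parameters.

    ``b``: default basal (U/hr); ``s``: insulin sensitivity factor
    (mmol/L per U); ``carb_ratio``: g/U; ``target``: glycemic target
    (mmol/L); ``dia_minutes``: duration of insulin action;
    ``max_multiplier``: cap on the temp basal as a multiple of ``b``.
    """

    b: float
    s: float
    carb_ratio: float
    target: float = 6.66
    dia_minutes: float = 180.0
    carb_absorb_minutes: float = 240.0
    max_multiplier: float = 4.0

    def __post_init__(self):
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.s <= 0:
            raise ValueError("s must be > 0")
        if self.carb_ratio <= 0:
            raise ValueError("carb_ratio must be > 0")
        if self.max_multiplier < 1:
            raise ValueError("max_multiplier must be >= 1")


def lgs_step(memory: dict, ig: float, t: float, cfg: LgsConfig) -> ControllerDecision:
    """One LGS decision for the CGM sample ``ig`` at time ``t`` (min).

    If a suspension is active, deliver 0; otherwise if ``ig`` falls below
    the threshold, start a new suspension of ``suspend_minutes`` and
    deliver 0; otherwise deliver the default basal.  After a suspension
    expires the threshold test resumes at the next sample, so repeated
    suspensions are possible.  ``memory`` records the suspension end time.
    """
    last_t = memory.get("last_t")
    if last_t is not None and t < last_t:
        raise ValueError(f"time regression: {t} < {last_t}")
    memory["last_t"] = t
    suspend_until = memory.get("suspend_until", -float("inf"))
    if t < suspend_until:
        return ControllerDecision(basal_rate=0.0)
    if ig < cfg.theta:
        memory["suspend_until"] = t + cfg.suspend_minutes
        return ControllerDecision(basal_rate=0.0)
    return ControllerDecision(basal_rate=cfg.b)


def insulin_on_board(history, now: float, dia_minutes: float = 180.0) -> float:
    """Remaining active insulin (U) from past doses, linear decay to zero.

    Each dose of ``units`` given at time ``t0`` contributes
    ``units * max(0, 1 - (now - t0) / dia_minutes)``.
    """
    total = 0.0
    for t0, units in history:
        age = now - t0
        if age < 0:
            raise ValueError("dose in the future")
        frac = 1.0 - age / dia_minutes
        if frac > 0:
            total += units * frac
    return total


def carbs_on_board(history, now: float, absorb_minutes: float = 240.0) -> float:
    """Remaining unabsorbed carbohydrate (g), linear decay over ``absorb_minutes``."""
    total = 0.0
    for t0, grams in history:
        age = now - t0
        if age < 0:
            raise ValueError("meal in the future")
        frac = 1.0 - age / absorb_minutes
        if frac > 0:
            total += grams * frac
    return total


def oref_like_step(memory: dict, ig: float, ig_prev: float, t: float,
                   cfg: OrefLikeConfig) -> ControllerDecision:
    """One oref-like decision.

    Predicts an eventual glucose from the current reading, a 30-min linear
    trend extrapolation, IOB (lowers it by ``s`` per unit) and COB (raises
    it by ``s / carb_ratio`` per gram), then applies three rules:

    * ``eventual < target - 1``   -> suspend (rate 0)
    * within +-1 of the target    -> default basal *b*
    * ``eventual > target + 1``   -> ``b + excess / (s * 0.5 hr)``, i.e. a
      correction spread over 30 min, capped at ``max_multiplier * b``

    ``memory`` holds the dose history (the controller records its own
    deliveries) and the carb announcements under keys ``"doses"`` and
    ``"carbs"``, each a list of ``(time, amount)`` pairs.
    """
    doses = memory.setdefault("doses", [])
    carbs = memory.setdefault("carbs", [])
    # convert the previously commanded rate into a delivered dose
    prev = memory.get("pending")
    if prev is not None:
        t_prev, rate_prev = prev
        if t < t_prev:
            raise ValueError(f"time regression: {t} < {t_prev}")
        units = rate_prev * (t - t_prev) / 60.0
        if units > 0:
            doses.append((t_prev, units))

    iob = insulin_on_board(doses, t, cfg.dia_minutes)
    cob = carbs_on_board(carbs, t, cfg.carb_absorb_minutes)
    trend = ig - ig_prev
    eventual = (ig + TREND_HORIZON_STEPS * trend
                - iob * cfg.s + cob * cfg.s / cfg.carb_ratio)

    if eventual < cfg.target - DEADBAND:
        rate = 0.0
    elif eventual <= cfg.target + DEADBAND:
        rate = cfg.b
    else:
        rate = cfg.b + (eventual - cfg.target) / (cfg.s * 0.5)
        rate = min(rate, cfg.max_multiplier * cfg.b)
    memory["pending"] = (t, rate)
    return ControllerDecision(basal_rate=rate)


# ---------------------------------------------------------------------------
# Class wrappers implementing the common controller protocol


class LgsController:
    """Stateful wrapper around :func:`lgs_step`."""

    name = "lgs"
    param_names = ("b", "theta", "suspend_minutes")

    def __init__(self, cfg: LgsConfig):
        self.cfg = cfg
        self.reset()

    def reset(self) -> None:
        self.memory: dict = {}

    def on_carbs(self, t: float, grams: float) -> None:
        pass  # LGS ignores meal announcements

    def decide(self, ig: float, t: float) -> ControllerDecision:
        return lgs_step(self.memory, ig, t, self.cfg)


class OrefLikeController:
    """Stateful wrapper around :func:`oref_like_step`; tracks the previous reading."""

    name = "oref_like"
    param_names = ("b", "s", "carb_ratio", "target", "dia_minutes",
                   "carb_absorb_minutes", "max_multiplier")

    def __init__(self, cfg: OrefLikeConfig):
        self.cfg = cfg
        self.reset()

    def reset(self) -> None:
        self.memory: dict = {}
        self._ig_prev: float | None = None

    def on_carbs(self, t: float, grams: float) -> None:
        self.memory.setdefault("carbs", []).append((t, grams))

    def decide(self, ig: float, t: float) -> ControllerDecision:
        ig_prev = ig if self._ig_prev is None else self._ig_prev
        decision = oref_like_step(self.memory, ig, ig_prev, t, self.cfg)
        self._ig_prev = ig
        return decision


CONTROLLERS = {
    "lgs": (LgsController, LgsConfig),
    "oref_like": (OrefLikeController, OrefLikeConfig),
}


def make_controller(name: str, params: dict, patient=None):
    """Instantiate a registered controller from a name -> value map.

    For the oref-like controller, ``carb_ratio`` defaults to the patient's
    own derived carb ratio when a patient is given and the map omits it.
    """
    try:
        cls, cfg_cls = CONTROLLERS[name]
    except KeyError:
        raise ValueError(f"unknown controller {name!r}; "
                         f"available: {sorted(CONTROLLERS)}") from None
    params = dict(params)
    if name == "oref_like" and "carb_ratio" not in params:
        if patient is None:
            raise ValueError("oref_like requires carb_ratio or a patient")
        params["carb_ratio"] = patient.carb_ratio
    return cls(cfg_cls(**params))
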