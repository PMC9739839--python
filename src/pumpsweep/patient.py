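"""Virtual type-1-diabetes patient: minimal-model glucose-insulin ODE.

The patient is a Bergman-style minimal model extended with a
two-compartment gut absorption chain and a first-order interstitial
glucose (IG) lag, so that a CGM sensor reading and the plasma glucose it
estimates are distinct signals:

    dG/dt  = -p1 (G - G_b) - X G + f_bio k_abs Q2 * MMOL_PER_GRAM / V_G
    dX/dt  = -p2 X + p3 (I - I_b)
    dI/dt  = -n I + u(t) / V_I
    dQ1/dt = -k_abs Q1          (+ carbohydrate impulse, grams)
    dQ2/dt =  k_abs (Q1 - Q2)
    dIG/dt = (G - IG) / tau_ig

with glucose in mmol/L, insulin in mU/L, gut compartments in grams of
carbohydrate and insulin delivery u in mU/min.  At ``u = n I_b V_I`` the
system has the exact fixed point ``(G_b, 0, I_b, 0, 0, G_b)``, which is
the patient's steady state under their optimal basal rate.

A seeded cohort generator produces child / adolescent / adult patients by
multiplicative log-normal jitter around per-category base parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "PatientParams",
    "ModelState",
    "CATEGORIES",
    "MMOL_PER_GRAM",
    "derive_optimal_basal",
    "derive_insulin_sensitivity",
    "derive_carb_ratio",
    "generate_cohort",
    "equilibrium_state",
    "step_model",
    "sample_cgm",
    "cohort_to_json",
    "cohort_from_json",
    "OdePatientBackend",
]

#: mmol of glucose per gram (molar mass 180.16 g/mol).
MMOL_PER_GRAM = 1000.0 / 180.16

MU_PER_UNIT = 1000.0  # 1 U insulin = 1000 mU

CATEGORIES = ("child", "adolescent", "adult")

# Per-category base parameters.  Rates are in the ballpark of published
# minimal-model estimates for T1D subjects; children and adolescents have
# smaller distribution volumes (body size) and higher insulin sensitivity
# p3 than adults.
_BASE_PARAMS = {
    "adult": dict(
        p1=0.015, p2=0.025, p3=1.3e-5, n=0.09,
        V_G=12.0, V_I=12.0, G_b=6.0, I_b=15.0,
        k_abs=0.035, f_bio=0.8, tau_ig=10.0,
    ),
    "adolescent": dict(
        p1=0.016, p2=0.025, p3=1.7e-5, n=0.10,
        V_G=9.0, V_I=9.0, G_b=6.2, I_b=14.0,
        k_abs=0.038, f_bio=0.8, tau_ig=9.0,
    ),
    "child": dict(
        p1=0.018, p2=0.027, p3=2.1e-5, n=0.11,
        V_G=6.0, V_I=6.0, G_b=6.4, I_b=12.0,
        k_abs=0.042, f_bio=0.8, tau_ig=8.0,
    ),
}

# Log-normal jitter sigmas used by generate_cohort (multiplicative).
_JITTER_SIGMA = {
    "p1": 0.10, "p2": 0.10, "p3": 0.12, "n": 0.08,
    "size": 0.10,           # shared by V_G and V_I (body size)
    "G_b": 0.03, "I_b": 0.10,
    "k_abs": 0.10, "f_bio": 0.05, "tau_ig": 0.10,
}


def _optimal_basal_Uhr(n: float, I_b: float, V_I: float) -> float:
    # steady state of dI/dt: u = n * I_b * V_I  [mU/min] -> U/hr
    return n * I_b * V_I * 60.0 / MU_PER_UNIT


def _insulin_sensitivity(G_b, p2, p3, n, V_I) -> float:
    # Integrated glucose disposal per 1 U bolus (linearised around G_b):
    # int(I-I_b)dt = 1000/(V_I n);  int X dt = p3/p2 * that;
    # disposal = G_b * int X dt  [mmol/L].
    return G_b * p3 * MU_PER_UNIT / (p2 * n * V_I)


def _carb_ratio(G_b, p2, p3, n, V_I, f_bio, V_G) -> float:
    # grams covered by 1 U: disposal per unit over glucose rise per gram
    rise_per_gram = f_bio * MMOL_PER_GRAM / V_G
    return _insulin_sensitivity(G_b, p2, p3, n, V_I) / rise_per_gram


@dataclass(frozen=True)
class PatientParams:
    """Physiological constants of one virtual patient.

    Rate constants are per minute, volumes in litres, glucose in mmol/L,
    insulin in mU/L.  ``optimal_basal`` (U/hr) and ``carb_ratio`` (g/U)
    are derived at construction and validated against their closed forms.
    """

    id: str
    category: str
    p1: float      # glucose effectiveness (1/min)
    p2: float      # remote-insulin decay (1/min)
    p3: float      # insulin action gain (L/(mU*min^2))
    n: float       # plasma-insulin clearance (1/min)
    V_G: float     # glucose distribution volume (L)
    V_I: float     # insulin distribution volume (L)
    G_b: float     # basal glucose (mmol/L)
    I_b: float     # basal plasma insulin (mU/L)
    k_abs: float   # gut absorption rate (1/min)
    f_bio: float   # carbohydrate bioavailability (0-1)
    tau_ig: float  # interstitial lag time constant (min)
    optimal_basal: float  # steady-state basal rate (U/hr)
    carb_ratio: float     # grams of carbohydrate per unit insulin (g/U)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        for name in ("p1", "p2", "p3", "n", "V_G", "V_I", "I_b",
                     "k_abs", "tau_ig"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.f_bio <= 1:
            raise ValueError("f_bio must be in (0, 1]")
        if not 4.0 <= self.G_b <= 8.0:
            raise ValueError("G_b must lie within 4-8 mmol/L")
        expected = _optimal_basal_Uhr(self.n, self.I_b, self.V_I)
        if not math.isclose(self.optimal_basal, expected, rel_tol=1e-9):
            raise ValueError(
                f"optimal_basal {self.optimal_basal} does not match the "
                f"closed form n*I_b*V_I = {expected} U/hr")


def make_patient(id: str, category: str, **phys: float) -> PatientParams:
    """Build a :class:`PatientParams` with derived quantities filled in."""
    phys = dict(phys)
    phys.setdefault("optimal_basal",
                    _optimal_basal_Uhr(phys["n"], phys["I_b"], phys["V_I"]))
    phys.setdefault("carb_ratio",
                    _carb_ratio(phys["G_b"], phys["p2"], phys["p3"],
                                phys["n"], phys["V_I"], phys["f_bio"],
                                phys["V_G"]))
    return PatientParams(id=id, category=category, **phys)


def derive_optimal_basal(params: PatientParams) -> float:
    """Basal rate (U/hr) holding the model at (G_b, X=0, I_b) with no meals."""
    return _optimal_basal_Uhr(params.n, params.I_b, params.V_I)


def derive_insulin_sensitivity(params: PatientParams) -> float:
    """Approximate glucose disposal per unit insulin (mmol/L per U)."""
    return _insulin_sensitivity(params.G_b, params.p2, params.p3,
                                params.n, params.V_I)


def derive_carb_ratio(params: PatientParams) -> float:
    """Grams of carbohydrate covered by one unit of insulin (g/U)."""
    return _carb_ratio(params.G_b, params.p2, params.p3, params.n,
                       params.V_I, params.f_bio, params.V_G)


def generate_cohort(seed: int, n_per_category: int = 10) -> list[PatientParams]:
    """Generate a seeded cohort of ``3 * n_per_category`` virtual patients.

    Per-category base parameters are jittered multiplicatively
    (log-normal; sigmas in ``_JITTER_SIGMA``) so patients differ while
    staying physiologically plausible.  Deterministic for a fixed seed;
    ids follow ``"category#NNN"``.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    rng = np.random.default_rng(seed)
    cohort: list[PatientParams] = []
    for category in CATEGORIES:
        base = _BASE_PARAMS[category]
        for i in range(1, n_per_category + 1):
            j = {k: float(rng.lognormal(0.0, s))
                 for k, s in _JITTER_SIGMA.items()}
            size = j["size"]
            phys = dict(
                p1=base["p1"] * j["p1"],
                p2=base["p2"] * j["p2"],
                p3=base["p3"] * j["p3"],
                n=base["n"] * j["n"],
                V_G=base["V_G"] * size,
                V_I=base["V_I"] * size,
                G_b=float(np.clip(base["G_b"] * j["G_b"], 4.0, 8.0)),
                I_b=base["I_b"] * j["I_b"],
                k_abs=base["k_abs"] * j["k_abs"],
                f_bio=float(min(base["f_bio"] * j["f_bio"], 0.98)),
                tau_ig=base["tau_ig"] * j["tau_ig"],
            )
            cohort.append(make_patient(f"{category}#{i:03d}", category, **phys))
    return cohort


@dataclass
class ModelState:
    """Instantaneous state of the glucose-insulin system."""

    t: float    # simulation time (min)
    G: float    # plasma glucose (mmol/L)
    X: float    # remote insulin action (1/min)
    I: float    # plasma insulin (mU/L)
    Q1: float   # gut carbohydrate, stomach compartment (g)
    Q2: float   # gut carbohydrate, intestine compartment (g)
    IG: float   # interstitial glucose (mmol/L)


def equilibrium_state(params: PatientParams, t: float = 0.0) -> ModelState:
    """The patient's fasting steady state under their optimal basal rate."""
    return ModelState(t=t, G=params.G_b, X=0.0, I=params.I_b,
                      Q1=0.0, Q2=0.0, IG=params.G_b)


def step_model(state: ModelState, params: PatientParams,
               inputs: dict, dt: float) -> ModelState:
    """Advance the ODE system by ``dt`` minutes with fixed-step RK4.

    ``inputs`` maps ``basal_rate`` (U/hr, held constant over the step),
    ``bolus`` (U) and ``carbs`` (g); bolus and carbs are impulses applied
    at the start of the step.  Internal RK4 step is at most 1 min; states
    are clamped at zero from below after each sub-step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    basal_rate = float(inputs.get("basal_rate", 0.0))
    bolus = float(inputs.get("bolus", 0.0))
    carbs = float(inputs.get("carbs", 0.0))
    vals = (state.G, state.X, state.I, state.Q1, state.Q2, state.IG,
            basal_rate, bolus, carbs, dt)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("non-finite state or inputs")
    if basal_rate < 0 or bolus < 0 or carbs < 0:
        raise ValueError("inputs must be non-negative")

    G, X, I = state.G, state.X, state.I
    Q1, Q2, IG = state.Q1, state.Q2, state.IG
    I += bolus * MU_PER_UNIT / params.V_I
    Q1 += carbs

    u = basal_rate * MU_PER_UNIT / 60.0  # mU/min
    p1, p2, p3, n = params.p1, params.p2, params.p3, params.n
    V_G, V_I, G_b, I_b = params.V_G, params.V_I, params.G_b, params.I_b
    k_abs, f_bio, tau_ig = params.k_abs, params.f_bio, params.tau_ig
    ra_coef = f_bio * k_abs * MMOL_PER_GRAM / V_G
    u_VI = u / V_I

    n_sub = max(1, math.ceil(dt / 1.0))
    h = dt / n_sub

    def deriv(G, X, I, Q1, Q2, IG):
        dG = -p1 * (G - G_b) - X * G + ra_coef * Q2
        dX = -p2 * X + p3 * (I - I_b)
        dI = -n * I + u_VI
        dQ1 = -k_abs * Q1
        dQ2 = k_abs * (Q1 - Q2)
        dIG = (G - IG) / tau_ig
        return dG, dX, dI, dQ1, dQ2, dIG

    for _ in range(n_sub):
        k1 = deriv(G, X, I, Q1, Q2, IG)
        k2 = deriv(G + 0.5 * h * k1[0], X + 0.5 * h * k1[1],
                   I + 0.5 * h * k1[2], Q1 + 0.5 * h * k1[3],
                   Q2 + 0.5 * h * k1[4], IG + 0.5 * h * k1[5])
        k3 = deriv(G + 0.5 * h * k2[0], X + 0.5 * h * k2[1],
                   I + 0.5 * h * k2[2], Q1 + 0.5 * h * k2[3],
                   Q2 + 0.5 * h * k2[4], IG + 0.5 * h * k2[5])
        k4 = deriv(G + h * k3[0], X + h * k3[1], I + h * k3[2],
                   Q1 + h * k3[3], Q2 + h * k3[4], IG + h * k3[5])
        G += h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        X += h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        I += h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        Q1 += h / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        Q2 += h / 6.0 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
        IG += h / 6.0 * (k1[5] + 2 * k2[5] + 2 * k3[5] + k4[5])
        if G < 0: G = 0.0
        if I < 0: I = 0.0
        if Q1 < 0: Q1 = 0.0
        if Q2 < 0: Q2 = 0.0
        if IG < 0: IG = 0.0

    return ModelState(t=state.t + dt, G=G, X=X, I=I, Q1=Q1, Q2=Q2, IG=IG)


def sample_cgm(state: ModelState, noise_sd: float = 0.0,
               rng: np.random.Generator | None = None) -> float:
    """CGM reading: interstitial glucose plus optional Gaussian sensor noise.

    Zero-mean noise with standard deviation ``noise_sd`` (mmol/L), floored
    at 0.  With ``noise_sd=0`` the reading is exactly ``state.IG``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0.0:
        return state.IG
    if rng is None:
        rng = np.random.default_rng()
    return max(0.0, state.IG + float(rng.normal(0.0, noise_sd)))


# ---------------------------------------------------------------------------
# Cohort persistence

def cohort_to_json(cohort: Sequence[PatientParams], path=None) -> str:
    """Serialise a cohort to JSON (one record per patient)."""
    text = json.dumps([asdict(p) for p in cohort], indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def cohort_from_json(source) -> list[PatientParams]:
    """Load a cohort from a JSON string or file path."""
    try:
        records = json.loads(source)
    except (json.JSONDecodeError, TypeError):
        with open(source) as fh:
            records = json.load(fh)
    return [PatientParams(**r) for r in records]


# ---------------------------------------------------------------------------
# Simulator-backend interface

class OdePatientBackend:
    """Session-oriented simulator backend over the built-in ODE patient.

    The contract mirrors a remote simulator daemon: ``select`` a patient to
    open a session, ``accumulate`` pending signal levels (``"carbs"`` in g,
    ``"bolus"`` in U, ``"basal_rate"`` in U/hr), then ``step(dt)`` applies
    them and returns the new ``{"BG", "IG"}`` pair.  Remote backends may
    implement the same three methods.
    """

    def __init__(self, cohort: Sequence[PatientParams]):
        self._by_id = {p.id: p for p in cohort}
        self._params: PatientParams | None = None
        self._state: ModelState | None = None
        self._pending: dict[str, float] = {}

    def select(self, patient_id: str) -> "OdePatientBackend":
        try:
            self._params = self._by_id[patient_id]
        except KeyError:
            raise KeyError(f"unknown patient {patient_id!r}") from None
        self._state = equilibrium_state(self._params)
        self._pending = {"basal_rate": self._params.optimal_basal}
        return self

    def accumulate(self, signal: str, value: float) -> None:
        if self._params is None:
            raise RuntimeError("no patient selected")
        if signal not in ("carbs", "bolus", "basal_rate"):
            raise ValueError(f"unknown signal {signal!r}")
        if signal == "basal_rate":
            self._pending[signal] = float(value)
        else:
            self._pending[signal] = self._pending.get(signal, 0.0) + float(value)

    def step(self, dt: float) -> dict[str, float]:
        if self._params is None or self._state is None:
            raise RuntimeError("no patient selected")
        inputs = {"basal_rate": self._pending.get("basal_rate", 0.0),
                  "bolus": self._pending.pop("bolus", 0.0),
                  "carbs": self._pending.pop("carbs", 0.0)}
        self._state = step_model(self._state, self._params, inputs, dt)
        return {"BG": self._state.G, "IG": self._state.IG}
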