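"""On-transient VO2 kinetics model forms and derived physiological measures.

Seven model forms are provided, all expressed on body-mass-normalized VO2
(mL·kg⁻¹·min⁻¹) as a function of time t (s) from exercise onset:

``mono_simple``
    VO2(t) = A0 + Ap·(1 − e^(−t/τp)) — single exponential, no time delay.
``mono_td``
    VO2(t) = A0 + H(t−TDp)·Ap·(1 − e^(−(t−TDp)/τp)) — the standard
    phase-II (primary component) model with time delay.
``mono_td_fixed_baseline``
    Same form with A0 held fixed at a measured resting baseline rather
    than estimated.
``bi_td``
    mono_td plus a delayed slow component
    H(t−TDsc)·Asc·(1 − e^(−(t−TDsc)/τsc)), for heavy/severe exercise.
``bi_fastzero_td``
    bi_td with the primary delay TDp fixed at 0.
``tri``
    bi_td plus a cardiodynamic (phase-I) term Ac·(1 − e^(−t/τc)) active
    from exercise onset.
``logistic``
    VO2(t) = A0 + Ap / (1 + e^(−k·(t−t50))) — sigmoidal alternative.

H is the Heaviside step with the convention H(0) = 1; each exponential
phase contributes only past its delay, and evaluation is continuous at
the delays because the exponential factor vanishes there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError
from .series import BreathSeries

Params = dict[str, float]

#: physical meaning and unit of every parameter name used by any model
PARAMETER_INFO: dict[str, str] = {
    "A0": "baseline VO2 at rest (mL·kg⁻¹·min⁻¹)",
    "Ap": "primary (fast) component amplitude (mL·kg⁻¹·min⁻¹)",
    "TDp": "primary component time delay (s)",
    "tau_p": "primary component time constant (s)",
    "Asc": "slow component asymptotic amplitude (mL·kg⁻¹·min⁻¹)",
    "TDsc": "slow component time delay (s)",
    "tau_sc": "slow component time constant (s)",
    "Ac": "cardiodynamic (phase I) amplitude (mL·kg⁻¹·min⁻¹)",
    "tau_c": "cardiodynamic time constant (s)",
    "k": "logistic growth rate (s⁻¹)",
    "t50": "logistic midpoint time (s)",
}

_AMPLITUDES = {"A0", "Ap", "Asc", "Ac"}
_DELAYS = {"TDp", "TDsc", "t50"}
_TIME_CONSTANTS = {"tau_p", "tau_sc", "tau_c"}


def heaviside(t) -> np.ndarray | float:
    """Unit step H(t): 0 for t < 0, 1 for t ≥ 0 (H(0) = 1)."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidInputError("heaviside argument must be finite")
    out = np.where(t >= 0.0, 1.0, 0.0)
    return float(out) if out.ndim == 0 else out


def _exp_phase(t: np.ndarray, amp: float, td: float, tau: float) -> np.ndarray:
    # H(t-td)*amp*(1-exp(-(t-td)/tau)) without overflow for t < td
    dt = np.maximum(t - td, 0.0)
    return amp * (1.0 - np.exp(-dt / tau))


@dataclass(frozen=True)
class ModelSpec:
    """One named model form: its free parameters, structurally fixed
    parameters, default bounds and evaluation rule."""

    name: str
    free_params: tuple[str, ...]
    #: parameters fixed by the model's structure (value may be overridden
    #: per fit, e.g. the measured baseline of mono_td_fixed_baseline)
    fixed_params: dict[str, float]

    @property
    def active_parameters(self) -> tuple[str, ...]:
        return self.free_params + tuple(self.fixed_params)

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def full_params(self, params: Params) -> Params:
        merged = dict(self.fixed_params)
        merged.update(params)
        missing = [p for p in self.active_parameters if p not in merged]
        if missing:
            raise InvalidParameterError(
                f"model {self.name!r} missing parameter(s): {missing}"
            )
        return merged

    def curve(self, params: Params, t: np.ndarray) -> np.ndarray:
        """Evaluate the model without invariant checks (optimizer path)."""
        p = self.full_params(params)
        t = np.asarray(t, dtype=float)
        name = self.name
        if name == "mono_simple":
            return p["A0"] + _exp_phase(t, p["Ap"], 0.0, p["tau_p"])
        if name in ("mono_td", "mono_td_fixed_baseline"):
            return p["A0"] + _exp_phase(t, p["Ap"], p["TDp"], p["tau_p"])
        if name in ("bi_td", "bi_fastzero_td"):
            return (
                p["A0"]
                + _exp_phase(t, p["Ap"], p.get("TDp", 0.0), p["tau_p"])
                + _exp_phase(t, p["Asc"], p["TDsc"], p["tau_sc"])
            )
        if name == "tri":
            return (
                p["A0"]
                + _exp_phase(t, p["Ac"], 0.0, p["tau_c"])
                + _exp_phase(t, p["Ap"], p["TDp"], p["tau_p"])
                + _exp_phase(t, p["Asc"], p["TDsc"], p["tau_sc"])
            )
        if name == "logistic":
            return p["A0"] + p["Ap"] * expit(p["k"] * (t - p["t50"]))
        raise InvalidParameterError(f"unknown model {name!r}")

    def default_bounds(self, t_end: float = 315.0) -> dict[str, tuple[float, float]]:
        """Wide default box bounds: amplitudes [0, 100] mL·kg⁻¹·min⁻¹,
        delays [0, t_end] s, time constants (0.1, 300] s, logistic rate
        (1e-3, 2] s⁻¹."""
        bounds: dict[str, tuple[float, float]] = {}
        for p in self.free_params:
            if p in _AMPLITUDES:
                bounds[p] = (0.0, 100.0)
            elif p in _DELAYS:
                bounds[p] = (0.0, float(t_end))
            elif p in _TIME_CONSTANTS:
                bounds[p] = (0.1, 300.0)
            elif p == "k":
                bounds[p] = (1e-3, 2.0)
        return bounds

    def validate(self, params: Params) -> Params:
        """Enforce the physiological invariants, naming the offender."""
        p = self.full_params(params)
        for name_ in self.active_parameters:
            v = p[name_]
            if not np.isfinite(v):
                raise InvalidParameterError(f"parameter {name_} is not finite")
            if name_ in _TIME_CONSTANTS or name_ == "k":
                if v <= 0:
                    raise InvalidParameterError(
                        f"parameter {name_} must be strictly positive, got {v}"
                    )
            elif name_ in _AMPLITUDES:
                if v < 0:
                    raise InvalidParameterError(
                        f"parameter {name_} must be non-negative, got {v}"
                    )
            elif name_ in _DELAYS:
                if v < 0:
                    raise InvalidParameterError(
                        f"parameter {name_} must be non-negative, got {v}"
                    )
        if "TDsc" in p and "TDp" in p and not p["TDsc"] > p["TDp"]:
            raise InvalidParameterError(
                f"parameter TDsc must exceed TDp (TDsc={p['TDsc']}, TDp={p['TDp']})"
            )
        return p


MODELS: dict[str, ModelSpec] = {
    "mono_simple": ModelSpec("mono_simple", ("A0", "Ap", "tau_p"), {}),
    "mono_td": ModelSpec("mono_td", ("A0", "Ap", "TDp", "tau_p"), {}),
    "mono_td_fixed_baseline": ModelSpec(
        "mono_td_fixed_baseline", ("Ap", "TDp", "tau_p"), {"A0": 0.0}
    ),
    "bi_td": ModelSpec(
        "bi_td", ("A0", "Ap", "TDp", "tau_p", "Asc", "TDsc", "tau_sc"), {}
    ),
    "bi_fastzero_td": ModelSpec(
        "bi_fastzero_td", ("A0", "Ap", "tau_p", "Asc", "TDsc", "tau_sc"), {"TDp": 0.0}
    ),
    "tri": ModelSpec(
        "tri",
        ("A0", "Ac", "tau_c", "Ap", "TDp", "tau_p", "Asc", "TDsc", "tau_sc"),
        {},
    ),
    "logistic": ModelSpec("logistic", ("A0", "Ap", "k", "t50"), {}),
}

#: direct nesting relations (simple, complex): the complex model recovers
#: the simple one on a subset of its parameter space
_DIRECT_NESTING: set[tuple[str, str]] = {
    ("mono_simple", "mono_td"),        # TDp = 0
    ("mono_td_fixed_baseline", "mono_td"),  # A0 freed
    ("mono_td", "bi_td"),              # Asc = 0
    ("bi_fastzero_td", "bi_td"),       # TDp freed from 0
    ("bi_td", "tri"),                  # Ac = 0
}


def _transitive_closure(pairs: set[tuple[str, str]]) -> set[tuple[str, str]]:
    closure = set(pairs)
    changed = True
    while changed:
        changed = False
        for a, b in list(closure):
            for c, d in list(closure):
                if b == c and (a, d) not in closure:
                    closure.add((a, d))
                    changed = True
    return closure


NESTING: set[tuple[str, str]] = _transitive_closure(_DIRECT_NESTING)


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown model {name!r}; available: {sorted(MODELS)}"
        ) from None


def is_nested(simple: str, complex_: str) -> bool:
    """True if ``simple`` is a declared restriction of ``complex_``."""
    return (simple, complex_) in NESTING


def evaluate_model(spec: ModelSpec, params: Params, t) -> np.ndarray | float:
    """Evaluate a model at time(s) ``t`` with full invariant validation."""
    spec.validate(params)
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise InvalidInputError("time values must be finite")
    out = spec.curve(params, t_arr)
    return float(out) if np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# Derived physiological measures
# ---------------------------------------------------------------------------

def asc_end(Asc: float, TDsc: float, tau_sc: float, t_end: float) -> float:
    """Slow-component amplitude actually realized at exercise end:
    Asc·(1 − e^(−(t_end − TDsc)/τsc)).  The asymptote Asc is generally not
    reached before exercise ends."""
    if tau_sc <= 0:
        raise InvalidParameterError(f"parameter tau_sc must be strictly positive, got {tau_sc}")
    if t_end < TDsc:
        raise InvalidInputError(
            f"t_end ({t_end}) precedes TDsc ({TDsc}): slow phase not started"
        )
    return float(Asc * (1.0 - np.exp(-(t_end - TDsc) / tau_sc)))


def end_vo2(series: BreathSeries, window: float = 60.0) -> float:
    """Mean VO2 over the terminal ``window`` seconds of exercise."""
    if series.span < window:
        raise InsufficientDataError(
            f"series spans {series.span:.1f} s, shorter than the {window} s end window"
        )
    mask = series.time >= series.t_end - window
    return float(series.vo2[mask].mean())


def baseline_a0(rest_series: BreathSeries, window: float = 120.0) -> float:
    """Resting baseline A0: mean VO2 over the final ``window`` seconds of a
    resting recording (2-min average by default)."""
    return end_vo2(rest_series, window=window)


def asc_difference(vo2_end: float, A0: float, Ap: float) -> float:
    """Difference-based slow-component amplitude: end VO2 minus (Ap + A0).
    May be negative; reported as-is."""
    for name, v in (("vo2_end", vo2_end), ("A0", A0), ("Ap", Ap)):
        if not np.isfinite(v):
            raise InvalidInputError(f"{name} must be finite")
    return float(vo2_end - (Ap + A0))
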