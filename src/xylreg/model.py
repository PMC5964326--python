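"""Deterministic ODE model of a GAL-type regulon with configurable feedback wiring.

The regulatory core is the classic Gal4p/Gal80p/Gal3p sequestration network:
Gal4p activates transcription, Gal80p represses Gal4p by stoichiometric
binding, and inducer-bound sensor (Gal3p or an engineered xylose-responsive
variant) de-represses Gal4p by sequestering Gal80p.  Three sensor-expression
architectures are supported:

* ``single_feedback`` — sensor transcribed from the weak, high-basal GAL3
  promoter only (one positive feedback loop);
* ``dual_feedback`` — an additional sensor production term driven by the
  strong, low-basal GAL1 promoter (two interlinked positive loops);
* ``constitutive_sensor`` — sensor made at a fixed Gal4p-independent rate,
  modelling a TEF1 promoter-driven control strain.

The GFP reporter is transcribed from the GAL1/10 promoter and does not decay,
so "fluorescence" downstream always means GFP accumulated up to a readout
time, not a steady state.

Units: time in minutes, protein species in nM, inducer in % w/v, GFP in
arbitrary RFU-equivalents.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import IntegrationError, SteadyStateError

__all__ = [
    "Architecture",
    "RegulonParameters",
    "StateVector",
    "TimeCourse",
    "SteadyStateResult",
    "promoter_activity",
    "inducer_coupling",
    "rhs",
    "simulate",
    "regulatory_steady_state",
    "matched_constitutive_rate",
    "STATE_NAMES",
]

STATE_NAMES = ("G3", "G80", "G4", "C83", "C84", "GFP")

#: indices into the state array
_G3, _G80, _G4, _C83, _C84, _GFP = range(6)


class Architecture(str, enum.Enum):
    """Sensor-expression wiring of the regulon."""

    SINGLE_FEEDBACK = "single_feedback"
    DUAL_FEEDBACK = "dual_feedback"
    CONSTITUTIVE_SENSOR = "constitutive_sensor"

    @classmethod
    def coerce(cls, value: "Architecture | str") -> "Architecture":
        if isinstance(value, Architecture):
            return value
        try:
            return cls(value)
        except ValueError:
            valid = ", ".join(a.value for a in cls)
            raise ValueError(f"unknown architecture {value!r}; valid: {valid}") from None


@dataclass(frozen=True)
class RegulonParameters:
    """Every rate constant and promoter parameter of the regulon model.

    All rates are per minute, concentrations in nM, inducer in % w/v.
    ``kf83`` lumps the inducer-dependent sensor–Gal80p association; its
    dose dependence is applied by :func:`inducer_coupling`.
    """

    # GAL3 promoter (weak, high basal) driving the sensor
    alpha3: float
    beta3: float
    K3: float
    n3: float
    # GAL1 promoter (strong, low basal); drives the second sensor term in
    # the dual architecture and sets the shape of the GFP synthesis term
    alphaG1: float
    betaG1: float
    K1: float
    n1: float
    # GAL80 promoter
    alpha80: float
    beta80: float
    K80: float
    n80: float
    # constitutive Gal4p supply
    alpha4: float
    # sensor--Gal80p binding (lumped, inducer-gated)
    kf83: float
    kr83: float
    # Gal80p--Gal4p binding
    kf84: float
    kr84: float
    # dilution/degradation of every species except GFP
    gamma: float
    # inducer half-saturation of sensor activation, % w/v
    Ks: float
    # GFP synthesis capacity from the GAL1/10 promoter
    betaGFP: float
    # sensor production rate of the constitutive_sensor architecture
    constitutive_rate: float = 0.0
    # "saturating": kf83 * s/(Ks+s);  "linear": kf83 * s/s_ref
    inducer_mode: str = "saturating"
    s_ref: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("inducer_mode",):
                continue
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be a finite number, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be nonnegative, got {v}")
        # gamma = 0 is admitted so the binding-only submodel (production and
        # dilution zeroed) can be exercised; steady-state operations require
        # gamma > 0 and check it themselves
        for name in ("K3", "K1", "K80", "Ks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("n3", "n1", "n80"):
            if getattr(self, name) < 1:
                raise ValueError(f"Hill coefficient {name} must be >= 1")
        if self.inducer_mode not in ("saturating", "linear"):
            raise ValueError(
                f"inducer_mode must be 'saturating' or 'linear', got {self.inducer_mode!r}"
            )
        if self.inducer_mode == "linear" and self.s_ref <= 0:
            raise ValueError("s_ref must be strictly positive in linear inducer mode")

    def replace(self, **changes) -> "RegulonParameters":
        """Return a copy with the given fields changed."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RegulonParameters":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown parameter keys: {', '.join(unknown)}")
        missing = sorted(known - set(d) - {"constitutive_rate", "inducer_mode", "s_ref"})
        if missing:
            raise ValueError(f"missing parameter keys: {', '.join(missing)}")
        return cls(**d)


@dataclass(frozen=True)
class StateVector:
    """Concentrations of the six modelled species (nM; GFP in RFU-equivalents)."""

    G3: float = 0.0
    G80: float = 0.0
    G4: float = 0.0
    C83: float = 0.0
    C84: float = 0.0
    GFP: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"state component {name} must be nonnegative")

    def to_array(self) -> np.ndarray:
        return np.array([self.G3, self.G80, self.G4, self.C83, self.C84, self.GFP])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        return cls(*(float(v) for v in y))

    def with_gfp(self, gfp: float) -> "StateVector":
        return replace(self, GFP=gfp)


ZERO_STATE = StateVector()


@dataclass(frozen=True)
class TimeCourse:
    """An integrated trajectory: times (min) by states (len(times) x 6)."""

    times: np.ndarray
    states: np.ndarray
    parameters: RegulonParameters
    architecture: Architecture
    inducer: float

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states) or len(self.times) < 2:
            raise ValueError("times and states must align with length >= 2")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def species(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def final_state(self) -> StateVector:
        return StateVector.from_array(self.states[-1])


def promoter_activity(G4_free: float, alpha: float, beta: float, K: float, n: float) -> float:
    """Hill-regulated promoter production rate alpha + beta * G4^n / (K^n + G4^n).

    Bounded in [alpha, alpha + beta] and monotone nondecreasing in free Gal4p.
    """
    if G4_free < 0:
        raise ValueError("free Gal4p concentration must be nonnegative")
    if alpha < 0 or beta < 0 or K <= 0 or n < 1:
        raise ValueError("promoter parameters out of domain")
    if G4_free == 0.0:
        return alpha
    # ratio form is safe for large G4^n; guard the log-range so extreme
    # activator levels saturate instead of overflowing
    t = n * (math.log10(K) - math.log10(G4_free))
    if t > 300.0:
        return alpha
    if t < -300.0:
        return alpha + beta
    return alpha + beta / (1.0 + 10.0 ** t)


def inducer_coupling(
    s: float,
    kf83: float,
    Ks: float,
    mode: str = "saturating",
    s_ref: float = 1.0,
) -> float:
    """Effective sensor–Gal80p forward rate at inducer concentration ``s``.

    Default saturating form kf83 * s/(Ks + s): zero without inducer, half
    the lumped constant at s = Ks, approaching kf83 at saturating sugar.
    The linear mode kf83 * s/s_ref is provided for sensitivity analysis.
    """
    if s < 0:
        raise ValueError("inducer concentration must be nonnegative")
    if mode == "saturating":
        return kf83 * s / (Ks + s)
    if mode == "linear":
        return kf83 * s / s_ref
    raise ValueError(f"unknown inducer mode {mode!r}")


def _sensor_production(G4: float, p: RegulonParameters, arch: Architecture) -> float:
    if arch is Architecture.CONSTITUTIVE_SENSOR:
        return p.constitutive_rate
    prod = promoter_activity(G4, p.alpha3, p.beta3, p.K3, p.n3)
    if arch is Architecture.DUAL_FEEDBACK:
        prod += promoter_activity(G4, p.alphaG1, p.betaG1, p.K1, p.n1)
    return prod


def rhs(
    state: StateVector | np.ndarray,
    params: RegulonParameters,
    arch: Architecture | str,
    s: float,
) -> np.ndarray:
    """Time derivative of the six-species state at inducer concentration ``s``."""
    arch = Architecture.coerce(arch)
    y = state.to_array() if isinstance(state, StateVector) else np.asarray(state, float)
    return _rhs_array(y, params, arch, s)


def _rhs_array(y: np.ndarray, p: RegulonParameters, arch: Architecture, s: float) -> np.ndarray:
    G3, G80, G4 = y[_G3], y[_G80], y[_G4]
    C83, C84 = y[_C83], y[_C84]
    # integration can transiently wander a hair below zero; evaluate Hill
    # terms at clipped concentrations to stay in-domain
    G4h = max(G4, 0.0)

    kf_s = inducer_coupling(max(s, 0.0), p.kf83, p.Ks, p.inducer_mode, p.s_ref)
    bind83 = kf_s * G3 * G80
    bind84 = p.kf84 * G80 * G4

    d = np.empty(6)
    d[_G3] = _sensor_production(G4h, p, arch) - bind83 + p.kr83 * C83 - p.gamma * G3
    d[_G80] = (
        promoter_activity(G4h, p.alpha80, p.beta80, p.K80, p.n80)
        - bind83
        + p.kr83 * C83
        - bind84
        + p.kr84 * C84
        - p.gamma * G80
    )
    d[_G4] = p.alpha4 - bind84 + p.kr84 * C84 - p.gamma * G4
    d[_C83] = bind83 - p.kr83 * C83 - p.gamma * C83
    d[_C84] = bind84 - p.kr84 * C84 - p.gamma * C84
    d[_GFP] = p.betaGFP * promoter_activity(G4h, 0.0, 1.0, p.K1, p.n1)
    return d


def simulate(
    params: RegulonParameters,
    arch: Architecture | str,
    s: float,
    initial: StateVector = ZERO_STATE,
    t_end: float = 1080.0,
    n_points: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
) -> TimeCourse:
    """Integrate the model from ``initial`` for ``t_end`` minutes.

    Uses a stiff-capable implicit solver; raises :class:`IntegrationError`
    with the solver diagnostic on failure.  Returned states are clipped of
    sub-tolerance negative excursions; an excursion below ``-1e-6`` nM is
    treated as an integration failure.
    """
    arch = Architecture.coerce(arch)
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if s < 0:
        raise ValueError("inducer concentration must be nonnegative")

    y0 = initial.to_array()
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        lambda t, y: _rhs_array(y, params, arch, s),
        (0.0, t_end),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}", inducer=s)
    states = sol.y.T
    low = states.min()
    if low < -1e-6:
        raise IntegrationError(
            f"integration produced a negative concentration ({low:.3e} nM)", inducer=s
        )
    states = np.clip(states, 0.0, None)
    return TimeCourse(sol.t, states, params, arch, s)


@dataclass(frozen=True)
class SteadyStateResult:
    """A steady state of the five regulatory species (GFP excluded).

    ``attractor`` labels the branch reached from the supplied initial state:
    "induced" when free Gal4p exceeds the GAL1-promoter half-activation
    constant K1, else "uninduced".  In a bistable regime different initial
    states may land on different attractors.
    """

    state: StateVector
    residual_norm: float
    attractor: str


def regulatory_steady_state(
    params: RegulonParameters,
    arch: Architecture | str,
    s: float,
    initial: StateVector = ZERO_STATE,
    t_relax: float = 2e5,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    polish: bool = True,
) -> SteadyStateResult:
    """Steady state of the regulatory subsystem by long-time integration.

    GFP accumulates without bound and is excluded (returned as 0).  The
    integration endpoint is optionally polished by an algebraic root solve
    of the five-species system; non-convergence raises
    :class:`SteadyStateError`.
    """
    arch = Architecture.coerce(arch)
    if params.gamma <= 0:
        raise ValueError("steady states require a positive dilution rate gamma")
    # GFP is excluded from the steady state; silence its unbounded growth
    # during the long relaxation
    relax_params = params.replace(betaGFP=0.0)
    tc = simulate(
        relax_params, arch, s, initial=initial, t_end=t_relax, n_points=50,
        rtol=rtol, atol=atol,
    )
    y = tc.states[-1, :5].copy()

    def f(x: np.ndarray) -> np.ndarray:
        full = np.concatenate([x, [0.0]])
        return _rhs_array(full, params, arch, s)[:5]

    if polish:
        sol = root(f, y, method="hybr", tol=1e-12)
        if sol.success and np.all(sol.x > -1e-9):
            y = np.clip(sol.x, 0.0, None)

    res = f(y)
    scale = np.maximum(np.abs(y), 1.0) * params.gamma
    rel = float(np.max(np.abs(res) / scale))
    if rel > 1e-6:
        raise SteadyStateError(
            f"steady-state residual {rel:.3e} exceeds tolerance after relaxation "
            f"to t = {t_relax:g} min and root polishing"
        )
    state = StateVector(*y, 0.0)
    attractor = "induced" if state.G4 > params.K1 else "uninduced"
    return SteadyStateResult(state, rel, attractor)


def matched_constitutive_rate(params: RegulonParameters, s_high: float = 4.0) -> float:
    """Constitutive sensor production rate matching the dual-feedback induced state.

    Returns gamma times the total sensor pool (free + Gal80p-bound) at the
    dual-feedback steady state under saturating inducer, so that the
    constitutive strain expresses as much sensor without induction as the
    dual-feedback strain does when fully ON.
    """
    ss = regulatory_steady_state(params, Architecture.DUAL_FEEDBACK, s_high)
    total_sensor = ss.state.G3 + ss.state.C83
    return params.gamma * total_sensor
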