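"""Dose-response simulation and the derived induction metrics.

Fluorescence readout is GFP accumulated at a fixed time T after the media
shift (the reporter does not decay, so there is no steady-state fluorescence
to speak of).  The sensitivity factor is the EC50 analogue used for feedback
design comparison: the inducer concentration at which the readout reaches
half its maximum over the tested grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrationError
from .model import (
    Architecture,
    RegulonParameters,
    StateVector,
    ZERO_STATE,
    regulatory_steady_state,
    simulate,
)


def uninduced_state(params: RegulonParameters, arch: "Architecture | str") -> StateVector:
    """Regulatory steady state without inducer (the naive pre-growth state)."""
    return regulatory_steady_state(params, arch, 0.0).state

__all__ = [
    "DoseResponseCurve",
    "SensitivityFactor",
    "HysteresisResult",
    "dose_response",
    "sensitivity_factor",
    "fold_change",
    "hysteresis_protocol",
    "MIN_FOLD_CHANGE",
]

#: below this max/min readout ratio a curve is considered flat and its
#: sensitivity factor undefined
MIN_FOLD_CHANGE = 1.2

#: top two grid readouts within this relative difference => plateau reached
SATURATION_REL_TOL = 0.05


@dataclass(frozen=True)
class DoseResponseCurve:
    """Readout (GFP at time T) over an inducer grid for one architecture."""

    inducer_grid: np.ndarray
    readout: np.ndarray
    readout_time: float
    architecture: Architecture
    history: str = "naive"
    provenance: str = "inline"

    def __post_init__(self) -> None:
        grid = np.asarray(self.inducer_grid, float)
        ro = np.asarray(self.readout, float)
        object.__setattr__(self, "inducer_grid", grid)
        object.__setattr__(self, "readout", ro)
        if len(grid) != len(ro) or len(grid) < 4:
            raise ValueError("grid and readout must align with length >= 4")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("inducer grid must be strictly increasing")
        if np.any(grid < 0) or np.any(ro < 0):
            raise ValueError("concentrations and readouts must be nonnegative")

    def readout_at(self, s: float) -> float:
        idx = np.nonzero(np.isclose(self.inducer_grid, s, rtol=1e-9, atol=1e-15))[0]
        if len(idx) == 0:
            raise KeyError(f"concentration {s!r} not on the grid")
        return float(self.readout[idx[0]])


@dataclass(frozen=True)
class SensitivityFactor:
    """Half-maximal inducer concentration extracted from a dose-response curve.

    ``value`` is NaN and ``defined`` False when the curve is too flat
    (fold change below :data:`MIN_FOLD_CHANGE`) for a half-max crossing to
    mean anything.
    """

    value: float
    attained_max: float
    saturated: bool
    defined: bool = True
    method: str = "piecewise-linear in log10(s)"
    multi_crossing: bool = False


@dataclass(frozen=True)
class HysteresisResult:
    """Paired dose-response curves after inducer-ON vs naive pre-incubation."""

    curve_on: DoseResponseCurve
    curve_off: DoseResponseCurve
    gap: np.ndarray
    summary_gap: float

    def __post_init__(self) -> None:
        if not np.array_equal(self.curve_on.inducer_grid, self.curve_off.inducer_grid):
            raise ValueError("hysteresis curves must share the inducer grid")
        if self.curve_on.readout_time != self.curve_off.readout_time:
            raise ValueError("hysteresis curves must share the readout time")


def dose_response(
    params: RegulonParameters,
    arch: Architecture | str,
    inducer_grid,
    T: float = 1080.0,
    initial: StateVector | None = None,
    history: str = "naive",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> DoseResponseCurve:
    """Simulate GFP accumulated at time T for each concentration on the grid.

    ``initial`` defaults to the uninduced (s = 0) regulatory steady state,
    mimicking cells pre-grown without inducer before the media shift;
    starting from an all-zero state instead would add a spurious free-Gal4p
    burst while Gal80p accumulates.  GFP starts at zero regardless of the
    supplied initial state (fresh reporter accumulation after the shift).
    """
    arch = Architecture.coerce(arch)
    if initial is None:
        initial = uninduced_state(params, arch)
    grid = np.sort(np.asarray(list(inducer_grid), float))
    start = initial.with_gfp(0.0)
    readout = np.empty_like(grid)
    for i, s in enumerate(grid):
        tc = simulate(params, arch, float(s), initial=start, t_end=T, n_points=2,
                      rtol=rtol, atol=atol)
        readout[i] = tc.species("GFP")[-1]
    return DoseResponseCurve(grid, readout, T, arch, history=history)


def sensitivity_factor(curve: DoseResponseCurve) -> SensitivityFactor:
    """Inducer concentration at which the readout first reaches half its maximum.

    The half-maximal level is taken halfway up the curve's rise over the
    grid (min + 0.5 * span), which coincides with 0.5 * max for curves
    induced from a dark baseline and keeps the measure meaningful when the
    uninduced reporter accumulation is not negligible.  The crossing is
    located by piecewise-linear interpolation in log10 concentration over
    the positive-concentration points; any s = 0 point contributes to the
    curve extrema but not to interpolation.  Flat curves (max/min fold
    change < 1.2) yield an undefined result.
    """
    pos = curve.inducer_grid > 0
    if pos.sum() < 1:
        raise ValueError("curve needs at least one positive concentration")
    ro_all = curve.readout
    attained_max = float(ro_all.max())
    top = ro_all[-2:]
    saturated = (
        attained_max > 0
        and abs(top[1] - top[0]) <= SATURATION_REL_TOL * max(abs(top[1]), abs(top[0]))
    )

    lo = float(ro_all.min())
    if attained_max <= 0 or (lo > 0 and attained_max / lo < MIN_FOLD_CHANGE) or (
        lo == 0 and attained_max == 0
    ):
        return SensitivityFactor(math.nan, attained_max, saturated, defined=False)

    s = curve.inducer_grid[pos]
    ro = ro_all[pos]
    half = lo + 0.5 * (attained_max - lo)
    above = ro >= half
    crossings = []
    if above[0]:
        crossings.append(float(s[0]))
    for i in range(len(s) - 1):
        if above[i] != above[i + 1]:
            x0, x1 = math.log10(s[i]), math.log10(s[i + 1])
            y0, y1 = ro[i], ro[i + 1]
            x = x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            crossings.append(10.0 ** x)
    multi = len(crossings) > 1
    if multi:
        warnings.warn("dose-response curve crosses half-max more than once; "
                      "reporting the smallest crossing concentration")
    return SensitivityFactor(
        value=min(crossings),
        attained_max=attained_max,
        saturated=saturated,
        defined=True,
        multi_crossing=multi,
    )


def fold_change(curve: DoseResponseCurve, s_ref: float) -> float:
    """Readout at ``s_ref`` over readout at zero inducer.

    Returns ``inf`` when induction occurs from a zero baseline and ``nan``
    when both readings are zero (no reporter synthesis at all).
    """
    num = curve.readout_at(s_ref)
    den = curve.readout_at(0.0)
    if den == 0.0:
        return math.nan if num == 0.0 else math.inf
    return num / den


def hysteresis_protocol(
    params: RegulonParameters,
    arch: Architecture | str,
    inducer_grid,
    s_pre_high: float = 4.0,
    pre_time: float = 1440.0,
    T: float = 1080.0,
    initial: StateVector | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> HysteresisResult:
    """Pre-incubation protocol probing history dependence of the response.

    Cells are first equilibrated for ``pre_time`` minutes either with
    saturating inducer (``s_pre_high``) or without, mimicking a 24 h
    pre-growth; the resulting regulatory states seed two dose-response runs
    with GFP reset to zero at the media shift.  In a bistable regime the
    pre-induced branch stays high at intermediate concentrations and the
    pointwise gap (ON minus naive readout) opens up.
    """
    arch = Architecture.coerce(arch)
    if pre_time <= 0 or s_pre_high < 0:
        raise ValueError("pre_time must be positive and s_pre_high nonnegative")
    if initial is None:
        initial = uninduced_state(params, arch)
    pre_states = {}
    for label, s_pre in (("on", s_pre_high), ("off", 0.0)):
        tc = simulate(params, arch, s_pre, initial=initial, t_end=pre_time, n_points=2,
                      rtol=rtol, atol=atol)
        pre_states[label] = tc.final_state.with_gfp(0.0)
    curve_on = dose_response(params, arch, inducer_grid, T, initial=pre_states["on"],
                             history=f"pre {s_pre_high:g}%", rtol=rtol, atol=atol)
    curve_off = dose_response(params, arch, inducer_grid, T, initial=pre_states["off"],
                              history="pre 0%", rtol=rtol, atol=atol)
    gap = curve_on.readout - curve_off.readout
    peak = max(curve_on.readout.max(), curve_off.readout.max())
    summary = float(np.mean(gap) / peak) if peak > 0 else 0.0
    return HysteresisResult(curve_on, curve_off, gap, summary)
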