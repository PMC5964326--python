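"""Event-level analysis of induction heterogeneity from flow-cytometry-like data.

Fluorescence per cell is treated as log-normal-like: ON/OFF classification
fits a two-component Gaussian mixture in log10 space; the coefficient of
variation (CV) is computed on the linear scale, the standard cytometry
noise measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .errors import DegenerateSampleError, GridAlignmentError

__all__ = [
    "CytometrySample",
    "BimodalityResult",
    "classify_on_off",
    "coefficient_of_variation",
    "cv_dose_profile",
]

#: components closer than this many pooled log-sds are called unimodal
SEPARATION_MIN = 2.0

#: a component carrying less weight than this is treated as absent
WEIGHT_MIN = 0.01


@dataclass(frozen=True)
class CytometrySample:
    """One cytometry acquisition: fluorescence per event plus metadata."""

    events: np.ndarray
    concentration: float
    architecture: str = "dual_feedback"
    sample_id: str = ""

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, float)
        object.__setattr__(self, "events", ev)
        if ev.ndim != 1 or len(ev) < 1:
            raise ValueError("events must be a nonempty 1-D array")
        if np.any(ev <= 0):
            raise ValueError("events must be strictly positive (log-transformable)")

    @property
    def n(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class BimodalityResult:
    """ON/OFF decomposition of one sample in log10 fluorescence space."""

    threshold: float
    fraction_on: float
    mean_off_log: float
    mean_on_log: float
    sd_off_log: float
    sd_on_log: float
    separation: float
    unimodal: bool


def classify_on_off(
    sample: CytometrySample,
    off_reference: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> BimodalityResult:
    """Split a sample into ON and OFF subpopulations.

    A two-component normal mixture is fitted to log10 events by EM with a
    deterministic median-split initialisation.  The reported threshold is
    the equal-posterior boundary between the components, and events at or
    below it count as OFF (ties resolve conservatively).  When the
    components are closer than 2 pooled log-sds, or one carries under 1%
    of the weight, the sample is flagged unimodal and assigned wholly ON
    or OFF by comparing its median to ``off_reference`` (linear scale,
    required in that case).
    """
    if sample.n < 100:
        raise ValueError("need at least 100 events to classify")
    x = np.log10(sample.events)
    if np.ptp(x) == 0.0:
        raise DegenerateSampleError("all events identical; nothing to classify")

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if len(hi) == 0:  # ties at the median
        lo, hi = x[x < med], x[x >= med]
    means = np.array([[lo.mean()], [hi.mean()]])
    var_floor = max(np.var(x) * 1e-6, 1e-12)
    precisions = 1.0 / np.maximum([[lo.var()], [hi.var()]], var_floor)

    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        max_iter=max_iter,
        tol=tol,
        reg_covar=1e-10,
        means_init=means,
        weights_init=[len(lo) / len(x), len(hi) / len(x)],
        precisions_init=precisions.reshape(2, 1, 1),
        random_state=0,
    )
    gm.fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    m_off, m_on = gm.means_.ravel()[order]
    s_off, s_on = np.sqrt(gm.covariances_.ravel()[order])
    w_off, w_on = gm.weights_.ravel()[order]

    pooled = math.sqrt(0.5 * (s_off**2 + s_on**2))
    separation = (m_on - m_off) / pooled if pooled > 0 else math.inf
    unimodal = separation < SEPARATION_MIN or min(w_off, w_on) < WEIGHT_MIN

    if unimodal:
        if off_reference is None:
            raise ValueError(
                "sample is unimodal; supply off_reference (linear a.u.) to decide ON vs OFF"
            )
        ref = math.log10(off_reference)
        margin = max(3.0 * pooled, 0.3)
        is_on = float(np.median(x)) > ref + margin
        frac = 1.0 if is_on else 0.0
        thr = ref + margin
        return BimodalityResult(10.0**thr, frac, m_off, m_on, s_off, s_on,
                                separation, unimodal=True)

    thr_log = _equal_posterior_boundary(m_off, s_off, w_off, m_on, s_on, w_on)
    frac = float(np.mean(x > thr_log))
    return BimodalityResult(10.0**thr_log, frac, m_off, m_on, s_off, s_on,
                            separation, unimodal=False)


def _equal_posterior_boundary(m0, s0, w0, m1, s1, w1) -> float:
    """Solve w0*N(x;m0,s0) = w1*N(x;m1,s1) for x between the two means."""
    a = 1.0 / (2 * s1**2) - 1.0 / (2 * s0**2)
    b = m0 / s0**2 - m1 / s1**2
    c = m1**2 / (2 * s1**2) - m0**2 / (2 * s0**2) + math.log((w0 * s1) / (w1 * s0))
    if abs(a) < 1e-14:  # equal variances: single linear boundary
        return -c / b
    disc = b * b - 4 * a * c
    if disc < 0:
        return 0.5 * (m0 + m1)
    roots = [(-b + sg * math.sqrt(disc)) / (2 * a) for sg in (1.0, -1.0)]
    inside = [r for r in roots if m0 <= r <= m1]
    return inside[0] if inside else 0.5 * (m0 + m1)


def coefficient_of_variation(sample: CytometrySample) -> float:
    """Sample standard deviation over mean of the raw linear-scale events.

    Uses the n-1 (sample) standard deviation convention.
    """
    if sample.n < 2:
        raise ValueError("need at least 2 events for a CV")
    ev = sample.events
    return float(np.std(ev, ddof=1) / np.mean(ev))


def cv_dose_profile(samples: list[CytometrySample]) -> pd.DataFrame:
    """CV-vs-concentration table, one row per architecture.

    All architectures must have samples at the same concentrations; a
    mismatch raises :class:`GridAlignmentError` listing the missing cells.
    """
    if not samples:
        raise ValueError("no samples supplied")
    table: dict[str, dict[float, float]] = {}
    for smp in samples:
        table.setdefault(smp.architecture, {})[smp.concentration] = (
            coefficient_of_variation(smp)
        )
    all_concs = sorted({c for row in table.values() for c in row})
    missing = [
        (arch, c) for arch, row in table.items() for c in all_concs if c not in row
    ]
    if missing:
        raise GridAlignmentError(missing)
    df = pd.DataFrame(
        {arch: [row[c] for c in all_concs] for arch, row in sorted(table.items())},
        index=pd.Index(all_concs, name="concentration"),
    )
    return df.T
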