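"""Synthetic plate-reader and cytometry data with known ground truth.

Emulates the two assay types the analysis consumes, so the whole pipeline
runs end-to-end without external data:

* plate-reader RFU/OD dose-response series (triplicate readings over the
  published concentration ladders) generated from a Hill-curve truth with
  multiplicative log-normal noise;
* flow-cytometry samples of 10,000 events drawn from a two-component
  (ON/OFF) log-normal mixture whose ON fraction follows a Hill function
  of inducer concentration.

Every generator takes an explicit seed and is byte-deterministic for a
fixed seed.  Generated data never embeds its truth; callers serialise the
truth to a separate sidecar so analysis code cannot accidentally read it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cytometry import CytometrySample
from .hillfit import hill_curve

__all__ = [
    "PlateReaderTruth",
    "CytometryTruth",
    "standard_series",
    "generate_plate_reader",
    "generate_cytometry",
]


def standard_series(tag: str) -> np.ndarray:
    """The published inducer concentration series, in printed (descending) order.

    ``fig3b_gal``: 10-fold galactose dilution ladder 2% down to 2e-6%.
    ``fig3b_xyl``: 10-fold xylose ladder from 8% with the printed 2e-3%
    low endpoint appended.  ``fig4c_xyl``: the xylose series
    4, 3, 2, 1, 0.5, 0.2, 0.1, 0 (% w/v).
    """
    if tag == "fig4c_xyl":
        return np.array([4.0, 3.0, 2.0, 1.0, 0.5, 0.2, 0.1, 0.0])
    if tag == "fig3b_gal":
        return _dilution_ladder(2.0, 2e-6)
    if tag == "fig3b_xyl":
        return _dilution_ladder(8.0, 2e-3)
    raise ValueError(f"unknown series tag {tag!r}; valid: fig3b_gal, fig3b_xyl, fig4c_xyl")


def _dilution_ladder(top: float, bottom: float) -> np.ndarray:
    vals = [top]
    while vals[-1] / 10.0 > bottom * (1 + 1e-9):
        vals.append(vals[-1] / 10.0)
    if not math.isclose(vals[-1], bottom, rel_tol=1e-9):
        vals.append(bottom)
    return np.array(vals)


@dataclass(frozen=True)
class PlateReaderTruth:
    """Ground truth for a synthetic RFU/OD dose-response experiment."""

    F0: float = 10.0
    Fmax: float = 1000.0
    K: float = 0.5
    n: float = 2.0
    noise_cv: float = 0.05        # multiplicative log-normal CV
    replicates: int = 3           # biological triplicates
    series: str = "fig4c_xyl"
    noise_model: str = "lognormal"  # or "additive"

    def __post_init__(self) -> None:
        if self.K <= 0 or self.n <= 0 or self.Fmax < 0 or self.F0 < 0:
            raise ValueError("Hill truth parameters out of domain")
        if self.noise_cv < 0 or self.replicates < 1:
            raise ValueError("noise_cv must be >= 0 and replicates >= 1")
        if self.noise_model not in ("lognormal", "additive"):
            raise ValueError("noise_model must be 'lognormal' or 'additive'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CytometryTruth:
    """Ground truth for synthetic ON/OFF cytometry mixtures."""

    off_log_mean: float = 0.0
    off_log_sd: float = 0.2
    on_log_mean: float = 2.0
    on_log_sd: float = 0.2
    fraction_K: float = 0.5       # ON-fraction Hill midpoint, % w/v
    fraction_n: float = 2.0       # ON-fraction Hill cooperativity
    n_events: int = 10_000
    noise_multiplier: float = 1.0  # scales both log-sds (per-architecture noise)

    def __post_init__(self) -> None:
        if self.off_log_sd <= 0 or self.on_log_sd <= 0:
            raise ValueError("log-sds must be positive")
        if self.fraction_K <= 0 or self.fraction_n <= 0:
            raise ValueError("ON-fraction Hill parameters must be positive")
        if self.n_events < 1 or self.noise_multiplier <= 0:
            raise ValueError("n_events >= 1 and noise_multiplier > 0 required")

    def fraction_on(self, s: float) -> float:
        if s <= 0:
            return 0.0
        r = (s / self.fraction_K) ** self.fraction_n
        return r / (1.0 + r)

    def to_dict(self) -> dict:
        return asdict(self)


def generate_plate_reader(truth: PlateReaderTruth, seed: int) -> pd.DataFrame:
    """Tidy replicate table (concentration, replicate, response) from a Hill truth.

    Readings are F(s) * exp(eps), eps ~ N(0, sigma) with
    sigma = sqrt(ln(1 + cv^2)) so the multiplicative noise has the stated
    CV; the additive mode adds N(0, cv * Fmax) instead.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    concs = standard_series(truth.series)
    rows = []
    for s in concs:
        f = float(hill_curve(s, truth.F0, truth.Fmax, truth.K, truth.n))
        for rep in range(1, truth.replicates + 1):
            if truth.noise_cv == 0:
                val = f
            elif truth.noise_model == "lognormal":
                sigma = math.sqrt(math.log1p(truth.noise_cv**2))
                val = f * math.exp(rng.normal(0.0, sigma))
            else:
                val = max(f + rng.normal(0.0, truth.noise_cv * truth.Fmax), 0.0)
            rows.append((float(s), rep, val))
    return pd.DataFrame(rows, columns=["concentration", "replicate", "response"])


def generate_cytometry(
    truth: CytometryTruth,
    concentrations,
    seed: int,
    architecture: str = "dual_feedback",
) -> list[CytometrySample]:
    """One sample per concentration from the ON/OFF log-normal mixture.

    Per event, component membership is Bernoulli(fraction_on(s)) and the
    fluorescence is a log-normal draw from that component, with both
    log-sds scaled by the architecture's noise multiplier.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for i, s in enumerate(np.asarray(list(concentrations), float)):
        f_on = truth.fraction_on(float(s))
        on = rng.random(truth.n_events) < f_on
        logs = np.where(
            on,
            rng.normal(truth.on_log_mean, truth.on_log_sd * truth.noise_multiplier,
                       truth.n_events),
            rng.normal(truth.off_log_mean, truth.off_log_sd * truth.noise_multiplier,
                       truth.n_events),
        )
        samples.append(
            CytometrySample(
                events=10.0**logs,
                concentration=float(s),
                architecture=architecture,
                sample_id=f"{architecture}_s{i:02d}",
            )
        )
    return samples
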