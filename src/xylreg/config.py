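"""Configuration, parameter files and delimited-text serialisation.

All on-disk formats are plain text: YAML for parameters/configs/summaries
and comma-delimited tables with a single header row for curves, sweeps
and event data.  Floats are written with 12 significant digits so tables
round-trip losslessly at that precision, and every run can be reproduced
byte-identically from its resolved config and seed.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .model import Architecture, RegulonParameters
from .response import DoseResponseCurve
from .sweep import SweepResult

__all__ = [
    "load_params",
    "save_params",
    "default_params",
    "RunConfig",
    "write_table",
    "read_table",
    "curve_to_frame",
    "frame_to_curve",
    "sweep_to_frame",
    "params_digest",
]

FLOAT_FMT = "%.12g"


def default_params() -> RegulonParameters:
    """The shipped default parameter set (versioned package data)."""
    ref = importlib.resources.files("xylreg").joinpath("data/default_params.yaml")
    return _params_from_text(ref.read_text(), source="default_params.yaml")


def load_params(path) -> RegulonParameters:
    """Read a flat key->value YAML parameter file; unknown keys are rejected."""
    return _params_from_text(Path(path).read_text(), source=str(path))


def _params_from_text(text: str, source: str) -> RegulonParameters:
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ConfigError(f"{source}: not valid YAML: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigError(f"{source}: expected a flat mapping of parameter names")
    try:
        return RegulonParameters.from_dict(raw)
    except (ValueError, TypeError) as e:
        raise ConfigError(f"{source}: {e}") from e


def save_params(params: RegulonParameters, path) -> None:
    d = params.to_dict()
    lines = [f"{k}: {v!r}" if isinstance(v, str) else f"{k}: {FLOAT_FMT % v}"
             for k, v in d.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def params_digest(params: RegulonParameters) -> str:
    """Short stable hash identifying a parameter set in output provenance."""
    blob = ",".join(f"{k}={v}" for k, v in sorted(params.to_dict().items()))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run; serialisable and strict.

    Unknown keys in a config file are rejected with the offending key
    named, so typos fail loudly instead of silently using defaults.
    """

    params_file: str | None = None
    architectures: list = field(default_factory=lambda: ["single_feedback", "dual_feedback"])
    series: str = "fig4c_xyl"
    readout_time: float = 1080.0
    pre_time: float = 1440.0
    s_pre_high: float = 4.0
    sweep_points: int = 25
    sweep_lo: float = 0.1
    sweep_hi: float = 1e4
    seed: int = 0
    tol_similar: float = 0.1
    tol_saturate: float = 0.05
    outdir: str = "xylreg_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        known = {f.name for f in fields(cls)}
        for key in raw:
            if key not in known:
                raise ConfigError(f"{path}: unknown config key {key!r}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True, default_flow_style=False)
        )

    def resolve_params(self) -> RegulonParameters:
        if self.params_file is None:
            return default_params()
        return load_params(self.params_file)

    def kf83_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.sweep_lo), np.log10(self.sweep_hi),
                           self.sweep_points)


def write_table(df: pd.DataFrame, path) -> None:
    """Comma-delimited text with one header row and 12-significant-digit floats."""
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def curve_to_frame(curve: DoseResponseCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "concentration": curve.inducer_grid,
            "readout": curve.readout,
            "history": curve.history,
            "architecture": curve.architecture.value,
        }
    )


def frame_to_curve(df: pd.DataFrame, readout_time: float) -> DoseResponseCurve:
    arch = Architecture.coerce(df["architecture"].iloc[0])
    history = str(df["history"].iloc[0])
    order = np.argsort(df["concentration"].to_numpy())
    return DoseResponseCurve(
        inducer_grid=df["concentration"].to_numpy()[order],
        readout=df["readout"].to_numpy()[order],
        readout_time=readout_time,
        architecture=arch,
        history=history,
    )


def sweep_to_frame(sweep: SweepResult, labels=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "kf83": sweep.kf83_values,
            "sf_single": sweep.sf_single,
            "sf_dual": sweep.sf_dual,
            "defined_single": sweep.defined_single,
            "defined_dual": sweep.defined_dual,
            "failed": sweep.failed,
        }
    )
    if labels is not None:
        df["regime"] = list(labels)
    return df
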