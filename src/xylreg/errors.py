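"""Exception types shared across the package."""


class XylregError(Exception):
    """Base class for all package-specific errors."""


class IntegrationError(XylregError):
    """The ODE integrator failed; carries the solver diagnostic message."""

    def __init__(self, message: str, inducer: float | None = None):
        self.inducer = inducer
        if inducer is not None:
            message = f"{message} (inducer = {inducer!r} % w/v)"
        super().__init__(message)


class SteadyStateError(XylregError):
    """Steady-state search did not converge within the documented effort."""


class NoInductionError(XylregError):
    """Dose-response span is indistinguishable from noise; no Hill fit returned."""


class DegenerateSampleError(XylregError):
    """Cytometry sample carries no usable variation (e.g. all events identical)."""


class GridAlignmentError(XylregError):
    """Concentration grids of grouped samples do not align; lists missing cells."""

    def __init__(self, missing: list[tuple[str, float]]):
        self.missing = missing
        cells = ", ".join(f"{arch}@{conc:g}%" for arch, conc in missing)
        super().__init__(f"missing samples for cells: {cells}")


class ConfigError(XylregError):
    """Malformed configuration or parameter file; names the offending key."""
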