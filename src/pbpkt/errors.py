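"""Exception hierarchy shared across the package."""


class PbpktError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PbpktError, ValueError):
    """An input table or record is malformed (missing/unknown keys)."""


class DomainError(PbpktError, ValueError):
    """A parameter value lies outside its physical domain."""


class ConfigurationError(PbpktError, ValueError):
    """A model configuration violates a structural invariant."""


class ConsistencyError(PbpktError, ValueError):
    """Internally inconsistent quantities (e.g. flows not summing to QC)."""


class ComparisonError(PbpktError, ValueError):
    """Two simulation results cannot be compared (grid/name mismatch)."""


class SolverError(PbpktError, RuntimeError):
    """ODE integration failed; carries the last successful time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time
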