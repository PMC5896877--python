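"""Exception hierarchy for icmsmap."""


class IcmsMapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IcmsMapError, ValueError):
    """A simulation or design configuration is invalid."""


class ParameterError(IcmsMapError, ValueError):
    """A stimulation or analysis parameter is out of its valid domain."""


class ChargeSafetyError(IcmsMapError, ValueError):
    """A stimulus would exceed the per-phase charge safety limit."""


class ScheduleError(IcmsMapError, RuntimeError):
    """A trial schedule cannot be constructed or is inconsistent."""


class SchemaError(IcmsMapError, ValueError):
    """A session file does not match the expected column schema."""


class ValidationError(IcmsMapError, ValueError):
    """Row-level invariant violations in session data."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class DegenerateDataError(IcmsMapError, ValueError):
    """Input data are degenerate for the requested computation
    (zero variance, constant sample, all-equal x, ...)."""


class CoverageError(IcmsMapError, ValueError):
    """A resampling stratum (e.g. an amplitude) has no usable observations."""


class DataCompletenessError(IcmsMapError, ValueError):
    """Required measurements (e.g. impedances) are missing for some electrodes."""
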