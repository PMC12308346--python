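"""Exception hierarchy shared across the package."""


class CountersignalError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CountersignalError, ValueError):
    """A configuration value is invalid; the message names the field."""


class DomainError(CountersignalError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DataError(CountersignalError, ValueError):
    """Input data violate a structural contract (duplicates, missing pairs)."""


class AnalysisError(CountersignalError, RuntimeError):
    """A statistical procedure cannot be carried out on these data."""


class DegenerateDataError(AnalysisError):
    """Data are degenerate for the requested statistic (e.g. zero variance)."""
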