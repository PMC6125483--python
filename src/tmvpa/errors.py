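"""Exception hierarchy shared across the pipeline."""


class TmvpaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TmvpaError):
    """A configuration object violates one of its invariants."""


class UnitsError(TmvpaError):
    """An operation received data in the wrong units (µV vs z-scored)."""


class SchemaError(TmvpaError):
    """A required column or channel is missing from the input."""


class ParameterError(TmvpaError):
    """An operation parameter is out of its valid range."""


class InsufficientDataError(TmvpaError):
    """Too few trials/subjects to carry out the requested computation."""


class DegenerateProjectionError(TmvpaError):
    """The quadratic form w'Σw is not positive; no activation pattern exists."""


class PairingError(TmvpaError):
    """Paired samples have mismatched lengths."""


class DesignError(TmvpaError):
    """The experimental design counts are inconsistent."""
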