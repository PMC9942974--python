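"""Exception hierarchy for the XCI-escape pipeline."""


class XCIEscapeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(XCIEscapeError):
    """A tabular input violates its format contract (missing column,
    non-integer or negative count, unknown token, duplicate key)."""


class StructureError(XCIEscapeError):
    """Sample-sheet structure violation (e.g. a twin pair that does not
    map to exactly two individuals)."""


class ConfigError(XCIEscapeError):
    """Invalid configuration value."""


class UndefinedObservationError(XCIEscapeError):
    """An allelic quantity was requested for an observation with zero
    total reads."""


class DomainError(XCIEscapeError):
    """A numeric argument lies outside its mathematical domain."""


class DegenerateDesignError(XCIEscapeError):
    """The regression design is degenerate (all degree-of-skew values
    identical), so the escape model cannot be fitted."""


class DegenerateRescaleError(XCIEscapeError):
    """All residuals are identical; min-max rescaling is undefined."""


class InsufficientSkewedSamplesError(XCIEscapeError):
    """Fewer skewed samples than required to fit the escape model."""
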