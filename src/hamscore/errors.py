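"""Exception hierarchy shared across the package."""


class HamscoreError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HamscoreError, ValueError):
    """A record or configuration value violates an invariant.

    ``field`` names the offending field when known.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class SchemaError(HamscoreError, ValueError):
    """An input file does not match the documented schema."""


class ZeroVarianceError(HamscoreError, ValueError):
    """A statistic is undefined because an input vector is constant."""
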