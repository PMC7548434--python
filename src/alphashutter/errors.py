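"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class AlphaShutterError(Exception):
    """Base class for all package errors."""


class ConfigError(AlphaShutterError):
    """A configuration value is missing, inconsistent, or out of range."""


class DataError(AlphaShutterError):
    """Input data violate a precondition (missing channels, short signals...)."""


class NumericalError(AlphaShutterError):
    """A computation has no defined result (zero resultant, empty cell...)."""


class ZeroResultantError(NumericalError):
    """Circular mean / preferred phase undefined: the vector sum is zero."""


class ThresholdUndefinedError(DataError):
    """Staircase threshold undefined: fewer than three reversals."""
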