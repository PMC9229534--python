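"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (config 2, data 3, numerical 4).
"""


class GaitmyoError(Exception):
    """Base class for all package errors."""


class FormatError(GaitmyoError):
    """A file or directory does not conform to the expected layout/dialect."""


class DataError(GaitmyoError):
    """Parsed data violates an invariant (non-monotone time, bad units, ...)."""


class AlignmentError(DataError):
    """Two streams cannot be placed on a common time base."""


class ConfigError(GaitmyoError):
    """Invalid or unknown configuration keys/values."""


class NumericalError(GaitmyoError):
    """A numerical procedure failed (non-finite loss, degenerate input)."""
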