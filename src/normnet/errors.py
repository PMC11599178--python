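"""Exception hierarchy used throughout normnet.

All errors derive from :class:`NormnetError` so callers can catch the
package's failures in one clause; the subclasses distinguish bad
configuration, malformed files, invalid data values, invalid parameters
and statistically undefined results.
"""


class NormnetError(Exception):
    """Base class for all normnet errors."""


class ConfigError(NormnetError):
    """A configuration file is inconsistent (e.g. unknown channel label)."""


class FormatError(NormnetError):
    """A data file does not match its declared layout/sidecar."""


class ValidationError(NormnetError):
    """A record violates a domain constraint (rating range, self-loop, ...)."""


class ParameterError(NormnetError, ValueError):
    """A function argument is outside its documented domain."""


class UndefinedValueError(NormnetError):
    """A statistic is undefined for the given input (empty denominator,
    zero variance, constant signal)."""
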