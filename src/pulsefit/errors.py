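"""Exception hierarchy with a stable CLI exit-code contract.

Exit codes: 0 success, 2 validation error, 3 insufficient data,
4 configuration error.
"""


class PulsefitError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(PulsefitError):
    """Malformed or inconsistent input data (bad schema, non-monotone time)."""

    exit_code = 2


class InsufficientDataError(PulsefitError):
    """Input is well-formed but too short / too poor to produce a result."""

    exit_code = 3


class ConfigurationError(PulsefitError):
    """Parameters outside their admissible ranges (band beyond Nyquist, ...)."""

    exit_code = 4
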