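"""Exception hierarchy shared across the pipeline.

Validation problems (bad schemas, out-of-range thresholds) map to CLI
exit code 2; numerical problems (non-finite state, undefined logs) map
to exit code 3.
"""


class PaddywebError(Exception):
    """Base class for all package errors."""


class ValidationError(PaddywebError, ValueError):
    """Input data or configuration violates a documented schema/range."""

    exit_code = 2


class ConfigurationError(ValidationError):
    """A required species, column or parameter is missing."""


class DomainError(PaddywebError, ValueError):
    """A value is outside the mathematical domain of an operation."""

    exit_code = 3


class IntegrationError(PaddywebError, RuntimeError):
    """The chemistry integrator produced a non-finite state."""

    exit_code = 3
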