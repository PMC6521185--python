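"""Package exception hierarchy.

ValidationError covers malformed inputs (CLI exit code 2); ComputationError
covers failures inside a statistical routine (CLI exit code 3).
"""


class CodonUseError(Exception):
    """Base class for all package errors."""


class ValidationError(CodonUseError):
    """Input data violates a documented precondition."""


class ComputationError(CodonUseError):
    """A statistic is undefined or an internal consistency check failed."""
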