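"""Exception hierarchy shared across the package.

All user-facing input problems derive from :class:`ValidationError` so the
command-line layer can map them to a single exit code.
"""


class SnptraitError(Exception):
    """Base class for all package errors."""


class ValidationError(SnptraitError):
    """Invalid user input (bad allele symbol, malformed table, bad sex code...)."""


class EmptyLocusError(ValidationError):
    """A computation that needs at least one genotyped sample got none."""


class DegenerateDesignError(ValidationError):
    """The model design matrix cannot support the requested fit.

    Raised when a fixed factor has fewer than two observed levels or the
    design is rank deficient.
    """


class PairingError(ValidationError):
    """A sample lacks either the target or the reference Ct measurement."""
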