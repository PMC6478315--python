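"""Exception hierarchy."""


class MrdockError(Exception):
    """Base class for all package errors."""


class StructureFormatError(MrdockError):
    """A structure file could not be parsed."""


class ValidationError(MrdockError):
    """Input violates a documented precondition or invariant."""


class ParameterError(ValidationError):
    """A required force-field parameter is missing or malformed."""


class DomainError(MrdockError):
    """A numeric argument is outside the mathematical domain of a function."""


class BookkeepingError(MrdockError):
    """Incremental energy bookkeeping drifted beyond the guard tolerance (bug)."""
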