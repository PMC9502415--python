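"""Exception hierarchy.

Every error raised deliberately by this package derives from :class:`PoregateError`,
so callers (and the CLI) can distinguish analysis failures from programming bugs.
"""


class PoregateError(Exception):
    """Base class for all poregate errors."""


class ValidationError(PoregateError):
    """An input object violates a documented invariant."""


class FormatError(PoregateError):
    """A file could not be parsed in its declared format."""


class SelectionSyntaxError(PoregateError):
    """A selection expression could not be parsed."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at token position {position})"
        super().__init__(message)


class RoleLookupError(PoregateError):
    """A role/subunit or chain lookup failed."""


class DegeneracyError(PoregateError):
    """A numerically degenerate input (zero variance, collinear atoms, ...)."""


class NoPathError(PoregateError):
    """Source and sink are not connected in the residue network."""
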