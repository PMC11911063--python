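"""Exception hierarchy shared by all vertemorph modules.

``ValidationError`` covers bad user input (CLI exit code 2);
``IOFormatError`` covers unreadable files (CLI exit code 3).
"""


class VertemorphError(Exception):
    """Base class for all vertemorph errors."""


class ValidationError(VertemorphError, ValueError):
    """Input violates a documented precondition or invariant."""


class SizingError(ValidationError):
    """A phantom spec implies geometry outside the image bounds."""


class FitError(VertemorphError):
    """Curve fitting failed (e.g. every RANSAC sample was degenerate)."""


class BackendError(VertemorphError):
    """A pluggable detector/landmark backend failed or broke its contract."""


class ContractViolationError(BackendError):
    """A backend returned non-finite or out-of-bounds coordinates."""


class IOFormatError(VertemorphError, OSError):
    """A file could not be read or written in a supported format."""


class SchemaError(IOFormatError):
    """An annotation file is missing required fields."""
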