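"""Exception hierarchy.

Every error raised by the library derives from :class:`MannaError` so a CLI or
calling pipeline can catch one type.  Validation problems (bad user input, bad
coordinates, unknown enum values) are :class:`ValidationError`; malformed
result/feature files are :class:`FormatError`; missing external programs are
:class:`AdapterUnavailableError`.
"""


class MannaError(Exception):
    """Base class for all library errors."""


class ValidationError(MannaError):
    """Input violates a documented precondition."""


class NotFoundError(MannaError):
    """A genome, annotation or feature does not exist in the store."""


class UniquenessError(ValidationError):
    """A unique name or key is already taken."""


class FormatError(MannaError):
    """A file does not conform to its declared format."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class AlphabetError(ValidationError):
    """Sequence contains characters outside the accepted alphabet."""


class TranslationError(ValidationError):
    """A CDS cannot be translated (e.g. internal stop codon)."""


class AdapterUnavailableError(MannaError):
    """An external tool adapter is not configured or its executable is missing."""


class ConfigurationError(MannaError):
    """The configuration is incomplete or inconsistent."""


class StoreError(MannaError):
    """The store file is corrupt or cannot be opened."""


class ConflictError(MannaError):
    """The target object changed since the operation was prepared."""
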