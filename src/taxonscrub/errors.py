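"""Exception hierarchy. One bad cell never aborts a batch; these signal
problems with whole inputs (files, schemas, configuration)."""

from __future__ import annotations


class TaxonscrubError(Exception):
    """Base class for all package errors."""


class InputError(TaxonscrubError):
    """A required input file is missing or unreadable."""


class SchemaError(TaxonscrubError):
    """An input table lacks a mandatory column or violates its contract."""


class EmptyInputError(InputError):
    """An input file has no header or no data rows."""


class EmptyChecklistError(InputError):
    """A checklist file yielded zero usable records."""


class ConfigError(TaxonscrubError):
    """The configuration file is malformed or has unknown keys."""


class ValidationError(TaxonscrubError):
    """A suggestion table or correction application failed validation."""

    def __init__(self, message: str, details: list[str] | None = None):
        super().__init__(message)
        self.details = details or []


class ConflictError(ValidationError):
    """A cell slated for correction no longer holds the expected wrong name."""


class OutputError(TaxonscrubError):
    """An output path is unwritable."""


class GenerationError(TaxonscrubError):
    """Synthetic fixture generation could not satisfy its constraints."""
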