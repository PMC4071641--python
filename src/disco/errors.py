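"""Exception hierarchy shared by every subsystem.

Errors carry enough structured context (locator, element, field) for the
CLI to render actionable messages and for tests to assert on causes.
"""

from __future__ import annotations


class DiscoError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(DiscoError):
    """A document (info file, harvest script, source) failed to parse.

    ``element`` names the offending element/key when known.
    """

    def __init__(self, message: str, element: str | None = None):
        super().__init__(message)
        self.element = element


class ValidationError(DiscoError):
    """A structurally valid document violated a semantic invariant."""

    def __init__(self, message: str, location: str | None = None):
        super().__init__(message)
        self.location = location


class ConflictError(DiscoError):
    """State moved underneath the caller (duplicate id, stale changeset,
    concurrent staged version)."""


class NotFoundError(DiscoError):
    """The named resource/version/view does not exist."""


class UsageError(DiscoError):
    """The call itself is malformed (unknown sort key, empty promotion)."""


class FetchError(DiscoError):
    """A source locator could not be retrieved.

    ``reason`` distinguishes ``not_found`` from ``timeout`` / ``other``.
    """

    def __init__(self, message: str, locator: str, reason: str = "other"):
        super().__init__(message)
        self.locator = locator
        self.reason = reason


class ExtractionError(DiscoError):
    """Structural mismatch between a source document and its script —
    the signal that ingestion for this resource is broken."""

    def __init__(self, message: str, locator: str | None = None,
                 selector: str | None = None):
        super().__init__(message)
        self.locator = locator
        self.selector = selector


class IntegrityError(DiscoError):
    """The version store is internally inconsistent (broken delta chain)."""


class GenerationError(DiscoError):
    """A synthetic-evolution event could not be applied."""
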