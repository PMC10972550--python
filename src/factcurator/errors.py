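"""Exception hierarchy shared by every module.

Each error class carries a stable, greppable CLI prefix so the command-line
layer can map failures to exit codes and machine-readable stderr lines.
"""

from __future__ import annotations


class FactCuratorError(Exception):
    """Base class for all domain errors."""

    cli_prefix = "E_ERROR"


class ValidationError(FactCuratorError):
    """Input violates an operation precondition or a model invariant."""

    cli_prefix = "E_VALIDATION"


class ConflictError(ValidationError):
    """A uniqueness constraint would be violated (duplicate id, annotation...)."""

    cli_prefix = "E_VALIDATION"


class DanglingReferenceError(ValidationError):
    """A cross-reference does not resolve inside its fact or repository."""

    cli_prefix = "E_VALIDATION"


class DependencyError(ValidationError):
    """Removal refused because other elements still depend on the target."""

    cli_prefix = "E_VALIDATION"


class ImmutabilityError(ValidationError):
    """Attempted mutation of a released (snapshot) fact or release record."""

    cli_prefix = "E_VALIDATION"


class CurationPermissionError(FactCuratorError):
    """Actor's role does not permit the requested action."""

    cli_prefix = "E_PERMISSION"


class NotFoundError(FactCuratorError):
    """Identifier, element path, draft, task or user does not exist."""

    cli_prefix = "E_NOTFOUND"


class FormatError(FactCuratorError):
    """Malformed identifier string, TSV file or XML document."""

    cli_prefix = "E_FORMAT"


class RegistryError(FormatError):
    """Namespace prefix absent from the loaded registry snapshot."""


class AccessionError(FormatError):
    """Accession does not match its namespace's pattern."""


class SbmlParseError(FormatError):
    """Input is not well-formed XML or not an SBML document."""


class UnsupportedLevelError(FormatError):
    """SBML document is Level 1/2; only Level 3 is accepted."""
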