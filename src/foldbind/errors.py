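"""Exception hierarchy.

All package-specific failures derive from :class:`FoldbindError` so callers
can catch one base class; subclasses mirror distinct failure modes (bad
input files, parameter-coverage problems, degenerate geometry, ...).
"""


class FoldbindError(Exception):
    """Base class for all foldbind errors."""


class InputError(FoldbindError):
    """Unreadable or malformed input (file, record, argument)."""


class EmptyStructureError(InputError):
    """A structure with zero standard residues after preprocessing."""


class ValidationError(FoldbindError):
    """A data table or object violates its invariants."""


class CoverageError(ValidationError):
    """Too many atoms without force-field parameters (wrong naming dialect?)."""


class ScopeError(FoldbindError):
    """An operation was asked for an incompatible scope (e.g. inter on one chain)."""


class UndefinedEnergyError(FoldbindError):
    """No parameterized atom pair exists, so the pair energy is undefined."""


class DegenerateOrientationError(FoldbindError):
    """A patch whose mean normal vanishes cannot be oriented."""


class ProjectionError(FoldbindError):
    """Apex search for the cone projection failed to converge/bracket."""


class GenerationError(FoldbindError):
    """A synthetic-data spec is geometrically or logically infeasible."""


class UndefinedCorrelationError(FoldbindError):
    """Pearson correlation is undefined (zero variance or too few points)."""


class EmptyReportError(FoldbindError):
    """A study was run on an empty or fully-excluded manifest."""
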