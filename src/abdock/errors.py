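"""Exception hierarchy shared across the package."""


class AbdockError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AbdockError):
    """A structure or confidence file could not be parsed."""


class RoleAssignmentError(AbdockError):
    """Chain roles (heavy/light/antigen) could not be assigned."""


class AnnotationError(AbdockError):
    """Residue numbering is inconsistent with the requested CDR scheme."""


class CorrespondenceError(AbdockError):
    """Residue/atom selections do not map 1:1 between two structures."""


class DegeneracyError(AbdockError):
    """A geometric operation received a degenerate input (too few or
    collinear points)."""


class DegeneratePopulationError(AbdockError):
    """A standardization population has zero spread or too few members."""


class PopulationError(AbdockError):
    """Scores from incompatible populations (e.g. different engines or
    modeling tools) were mixed without an explicit scope."""


class IncompleteEvidenceError(AbdockError):
    """A composite score was requested with a missing component."""


class MaskError(AbdockError):
    """A residue-pair mask selected no pairs."""


class TableError(AbdockError):
    """A reference lookup table is missing a required entry."""


class GeometryError(AbdockError):
    """An interface-geometry calculation received unusable coordinates."""


class ConfigError(AbdockError):
    """A benchmark manifest configuration is invalid."""


class SpecError(AbdockError):
    """A synthetic-fixture specification is geometrically infeasible."""
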