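"""Exception hierarchy.

All package errors derive from :class:`ProtonPrepError` so callers (and the
CLI) can catch one base class; the subclasses distinguish user-facing
failure modes: absent plan components, malformed structures, out-of-domain
geometry parameters, and dose-grid geometry mismatches.
"""


class ProtonPrepError(Exception):
    """Base class for all protonprep errors."""


class ComponentAbsentError(ProtonPrepError):
    """A treatment beam lacks a required device (compensator or block)."""


class StructuralError(ProtonPrepError):
    """A file or record is structurally malformed (wrong lengths, bad tags)."""


class DomainError(ProtonPrepError, ValueError):
    """A numeric parameter is outside its physically meaningful domain."""


class GeometryMismatchError(ProtonPrepError):
    """Two dose grids do not share the geometry an operation requires."""


class EmptySolidError(ProtonPrepError):
    """A meshing operation received geometry with no material to extrude."""


class NormalizationError(ProtonPrepError):
    """Dose normalization is impossible (zero dose at the chosen point)."""
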