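"""Exception and warning hierarchy for molprint.

Errors abort an operation; warnings (issued via :mod:`warnings`) flag
conditions a user preparing a physical print should review but that do not
invalidate the geometry.
"""


class MolprintError(Exception):
    """Base class for all molprint errors."""


class EmptyStructureError(MolprintError):
    """No atom records were found where at least one is required."""


class PDBParseError(MolprintError):
    """A PDB record could not be parsed.

    Carries ``line_number`` (1-based) of the offending line.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class MissingRadiusError(MolprintError):
    """Elements without a radius in the active radius set and no fallback."""

    def __init__(self, elements):
        self.elements = sorted(set(elements))
        super().__init__(
            "no radius for element(s) %s and no fallback radius configured"
            % ", ".join(self.elements)
        )


class GeometryError(MolprintError):
    """Input geometry is unusable (e.g. too few trace points for a tube)."""


class PrintabilityError(MolprintError):
    """An operation requiring a watertight mesh received one that is not."""


class LevelSetError(MolprintError):
    """Requested isovalue lies outside the scalar field's value range."""


class UnitError(MolprintError):
    """Mesh unit tags are inconsistent with the requested operation."""


class EmptyResultError(MolprintError):
    """A Boolean operation annihilated its operand (zero-volume result)."""


class RepairError(MolprintError):
    """Mesh repair failed; carries the residual :class:`ManifoldReport`."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class FormatError(MolprintError):
    """A 3D file stream violates its declared format."""


# ---------------------------------------------------------------------------
# warning categories


class PrintabilityWarning(UserWarning):
    """Base category for print-preparation warnings."""


class OpenSurfaceWarning(PrintabilityWarning):
    """Density grid padding may clip atoms; isosurface could be open."""


class OverlapWarning(PrintabilityWarning):
    """Placed assembly copies overlap more than the configured fraction."""


class WallThicknessWarning(PrintabilityWarning):
    """Hollowing wall meets or exceeds the local inradius; solid returned."""


class ThroughHoleWarning(PrintabilityWarning):
    """A magnet socket is deeper than the local wall thickness."""


class ColorLossWarning(PrintabilityWarning):
    """The target format cannot represent per-vertex colors."""
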