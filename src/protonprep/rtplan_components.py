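"""Field-specific device descriptors parsed from DICOM RT Ion Plans.

In a double-scattering proton system each treatment field carries two
patient-specific devices mounted in the snout: an acrylic range compensator
(a milled thickness map shaping the distal dose edge) and a metal aperture
block (a cutout collimating the lateral edges).  The treatment planning
system stores both as projections onto the isocenter plane; to model them at
their physical position in the beam line their lateral dimensions must be
scaled by a projective magnification factor derived from the virtual
source-axis distance (VSAD) and the snout position.

The magnification factors are

    compensator:  (VSAD - SnoutPosition + CompensatorThickness) / VSAD
    aperture:     (VSAD - SnoutPosition) / VSAD

with all lengths in mm.  Thicknesses along the beam axis are physical and
are never scaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from shapely.geometry import Polygon

from .errors import ComponentAbsentError, DomainError, StructuralError

__all__ = [
    "CompensatorMap",
    "ApertureContour",
    "BeamLineGeometry",
    "ParseConfig",
    "parse_beam_components",
    "compensator_mag_factor",
    "aperture_mag_factor",
    "scale_component",
]


@dataclass(frozen=True)
class CompensatorMap:
    """Range compensator thickness map projected onto the isocenter plane.

    Parameters
    ----------
    corner_position : (2,) array, mm
        Isocenter-plane (x, y) coordinates of the first pixel (pixel
        center convention, matching the DICOM CompensatorPosition tag).
    pixel_spacing : (2,) array, mm
        (row, column) spacing.
    thickness : (n_rows, n_cols) array, mm
        Physical thickness along the beam axis.  The plan stores the array
        as dimensionless numbers; here they are interpreted in mm (the
        DICOM convention), with an optional unit scale applied at parse
        time via :class:`ParseConfig`.
    """

    corner_position: np.ndarray
    pixel_spacing: np.ndarray
    thickness: np.ndarray
    material_note: str = "acrylic (PMMA)"

    def __post_init__(self) -> None:
        object.__setattr__(self, "corner_position", np.asarray(self.corner_position, float))
        object.__setattr__(self, "pixel_spacing", np.asarray(self.pixel_spacing, float))
        object.__setattr__(self, "thickness", np.asarray(self.thickness, float))
        if self.corner_position.shape != (2,):
            raise StructuralError("corner_position must be a 2-vector")
        if self.pixel_spacing.shape != (2,) or np.any(self.pixel_spacing <= 0):
            raise StructuralError("pixel_spacing must be a positive 2-vector")
        if self.thickness.ndim != 2:
            raise StructuralError("thickness must be a 2D array")
        if np.any(self.thickness < 0):
            raise StructuralError("thickness values must be >= 0")

    @property
    def n_rows(self) -> int:
        return self.thickness.shape[0]

    @property
    def n_cols(self) -> int:
        return self.thickness.shape[1]


@dataclass(frozen=True)
class ApertureContour:
    """Aperture cutout perimeter (isocenter projection) plus block extent.

    ``vertices`` is an ordered, implicitly closed (x, y) polygon in mm.
    ``outer_diameter`` is the circle bounding the physical block; it is not
    an RT Plan attribute, so it comes from configuration or is inferred
    from the contour extent.
    """

    vertices: np.ndarray
    outer_diameter: float
    thickness: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", np.asarray(self.vertices, float))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise StructuralError("vertices must be an (n >= 3, 2) array")
        if not float(self.outer_diameter) > 0:
            raise DomainError("outer_diameter must be > 0")
        if not float(self.thickness) > 0:
            raise DomainError("aperture thickness must be > 0")
        if not Polygon(self.vertices).is_simple:
            raise StructuralError("aperture contour is self-intersecting")
        radii = np.hypot(self.vertices[:, 0], self.vertices[:, 1])
        if np.any(radii > self.outer_diameter / 2 + 1e-9):
            raise StructuralError("contour vertices extend outside the outer circle")

    def as_polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class BeamLineGeometry:
    """Beam-line distances entering the magnification factors.

    ``vsad`` is the virtual source-axis distance (300A,030A);
    ``snout_position`` (300A,030D) is the snout's distance setting along
    the beam axis; ``aperture_thickness`` carries tag (300A,0100);
    ``compensator_thickness_extent`` is the compensator's maximum physical
    thickness along the beam axis.
    """

    vsad: float
    snout_position: float
    aperture_thickness: float
    compensator_thickness_extent: float
    gantry_angle: float = 0.0

    def __post_init__(self) -> None:
        if not self.vsad > self.snout_position:
            raise DomainError("vsad must exceed snout_position")
        if self.snout_position < 0:
            raise DomainError("snout_position must be >= 0")
        if self.aperture_thickness < 0 or self.compensator_thickness_extent < 0:
            raise DomainError("thicknesses must be >= 0")


@dataclass(frozen=True)
class ParseConfig:
    """Knobs for plan interpretation that the DICOM file does not pin down.

    thickness_unit_scale
        Multiplier applied to the stored compensator thickness numbers to
        obtain mm.  Default 1.0 (values already in mm).
    eq1_thickness
        Which physical thickness enters the compensator magnification:
        ``"compensator"`` uses the compensator's thickness extent (the
        default — the factor is named after the compensator),
        ``"aperture"`` uses the block thickness tag (300A,0100).
    aperture_outer_diameter
        Outer circle of the block, mm.  ``None`` infers it as twice the
        largest contour vertex radius plus ``aperture_margin``.
    """

    thickness_unit_scale: float = 1.0
    eq1_thickness: Literal["compensator", "aperture"] = "compensator"
    aperture_outer_diameter: float | None = None
    aperture_margin: float = 25.0


def _first_control_point(beam) -> object:
    cps = getattr(beam, "IonControlPointSequence", None) or getattr(
        beam, "ControlPointSequence", None
    )
    if not cps:
        raise StructuralError(f"beam {beam.BeamNumber} has no control point sequence")
    return cps[0]


def parse_beam_components(
    rtplan, config: ParseConfig | None = None
) -> list[tuple[CompensatorMap, ApertureContour, BeamLineGeometry]]:
    """Extract (compensator, aperture, geometry) for every ion beam of a plan.

    Parameters
    ----------
    rtplan : pydicom.Dataset
        An RT (Ion) Plan dataset, e.g. from ``pydicom.dcmread``.
    config : ParseConfig, optional
        Interpretation options; defaults are documented on the class.

    Returns
    -------
    list of (CompensatorMap, ApertureContour, BeamLineGeometry)
        One tuple per beam, in plan order.

    Raises
    ------
    ComponentAbsentError
        If a beam lacks a compensator or block sequence.
    StructuralError
        If array lengths disagree with the declared shape.
    """
    config = config or ParseConfig()
    modality = getattr(rtplan, "Modality", None)
    if modality not in ("RTPLAN", "RTIONPLAN"):
        raise StructuralError(f"not an RT Plan (modality {modality!r})")
    beams = getattr(rtplan, "IonBeamSequence", None) or getattr(rtplan, "BeamSequence", None)
    if not beams:
        raise StructuralError("plan contains no ion beam sequence")

    out = []
    for beam in beams:
        beam_id = getattr(beam, "BeamName", None) or f"#{beam.BeamNumber}"

        comps = getattr(beam, "IonRangeCompensatorSequence", None) or getattr(
            beam, "CompensatorSequence", None
        )
        if not comps:
            raise ComponentAbsentError(f"beam {beam_id}: compensator sequence absent")
        if len(comps) > 1:
            warnings.warn(f"beam {beam_id}: {len(comps)} compensators; using the first")
        comp_ds = comps[0]
        n_rows = int(comp_ds.CompensatorRows)
        n_cols = int(comp_ds.CompensatorColumns)
        raw = np.asarray(comp_ds.CompensatorThicknessData, float)
        if raw.size != n_rows * n_cols:
            raise StructuralError(
                f"beam {beam_id}: thickness data length {raw.size} != "
                f"{n_rows}x{n_cols}"
            )
        comp = CompensatorMap(
            corner_position=np.asarray(comp_ds.CompensatorPosition, float),
            pixel_spacing=np.asarray(comp_ds.CompensatorPixelSpacing, float),
            thickness=raw.reshape(n_rows, n_cols) * config.thickness_unit_scale,
        )

        blocks = getattr(beam, "IonBlockSequence", None) or getattr(
            beam, "BlockSequence", None
        )
        if not blocks:
            raise ComponentAbsentError(f"beam {beam_id}: block sequence absent")
        if len(blocks) > 1:
            warnings.warn(f"beam {beam_id}: {len(blocks)} blocks; using the first")
        block_ds = blocks[0]
        n_pts = int(block_ds.BlockNumberOfPoints)
        flat = np.asarray(block_ds.BlockData, float)
        if flat.size != 2 * n_pts:
            raise StructuralError(
                f"beam {beam_id}: block data length {flat.size} != 2x{n_pts}"
            )
        vertices = flat.reshape(n_pts, 2)
        if config.aperture_outer_diameter is not None:
            outer = float(config.aperture_outer_diameter)
        else:
            outer = 2.0 * (float(np.hypot(*vertices.T).max()) + config.aperture_margin)
        aperture = ApertureContour(
            vertices=vertices,
            outer_diameter=outer,
            thickness=float(block_ds.BlockThickness),
        )

        vsad_val = np.atleast_1d(np.asarray(beam.VirtualSourceAxisDistances, float))
        cp0 = _first_control_point(beam)
        geom = BeamLineGeometry(
            vsad=float(vsad_val.mean()),
            snout_position=float(cp0.SnoutPosition),
            aperture_thickness=float(block_ds.BlockThickness),
            compensator_thickness_extent=float(comp.thickness.max()),
            gantry_angle=float(getattr(cp0, "GantryAngle", 0.0)),
        )
        out.append((comp, aperture, geom))
    return out


def compensator_mag_factor(geom: BeamLineGeometry, config: ParseConfig | None = None) -> float:
    """Projective magnification of the compensator at its beam-line position.

    Returns ``(vsad - snout_position + thickness) / vsad`` where the
    thickness term is chosen by ``config.eq1_thickness`` (compensator
    thickness extent by default).
    """
    config = config or ParseConfig()
    if geom.vsad <= 0:
        raise DomainError("vsad must be > 0")
    t = (
        geom.compensator_thickness_extent
        if config.eq1_thickness == "compensator"
        else geom.aperture_thickness
    )
    mag = (geom.vsad - geom.snout_position + t) / geom.vsad
    if mag <= 0:
        raise DomainError("magnification factor must be > 0")
    return mag


def aperture_mag_factor(geom: BeamLineGeometry) -> float:
    """Projective magnification of the aperture: ``(vsad - snout) / vsad``."""
    if geom.vsad <= 0:
        raise DomainError("vsad must be > 0")
    if geom.snout_position >= geom.vsad:
        raise DomainError("snout_position must be < vsad")
    return (geom.vsad - geom.snout_position) / geom.vsad


def scale_component(component, mag: float):
    """Scale a device's lateral (isocenter-plane) dimensions by ``mag``.

    Thickness along the beam axis is a physical property of the device and
    is left untouched; only in-plane lengths (corner position, pixel
    spacing, contour vertices, outer diameter) are multiplied.
    """
    if not mag > 0:
        raise DomainError("magnification must be > 0")
    if isinstance(component, CompensatorMap):
        return replace(
            component,
            corner_position=component.corner_position * mag,
            pixel_spacing=component.pixel_spacing * mag,
        )
    if isinstance(component, ApertureContour):
        return replace(
            component,
            vertices=component.vertices * mag,
            outer_diameter=component.outer_diameter * mag,
        )
    raise TypeError(f"cannot scale object of type {type(component).__name__}")
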