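"""Dose-grid containers, Geant4 scorer ingestion, and DICOM RT Dose I/O.

A :class:`DoseGrid` mirrors the DICOM RT Dose data model: a 3D array of
stored values (slice, row, column) whose physical dose in Gy is the stored
value times the Dose Grid Scaling factor, positioned in patient (LPS)
coordinates by Image Position, Pixel Spacing and the Grid Frame Offset
Vector.  Geant4 scorers index the same grid linearly by "copyid"; the
mixed-radix decomposition of copyids into (x, y, z) voxel indices is
configurable because scorer nesting order varies between setups.

Monte Carlo output is in arbitrary units (dose per simulated primaries),
so comparison against a treatment planning system requires normalization:
the grid scaling is multiplied by the ratio of TPS to MC dose at a chosen
point (conventionally the isocenter), leaving stored values untouched.
A median filter suppresses the MC statistical noise before comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, RTDoseStorage
from scipy import ndimage

from .errors import (
    DomainError,
    GeometryMismatchError,
    NormalizationError,
    StructuralError,
)

__all__ = [
    "DoseGrid",
    "CopyIdRecord",
    "copyids_to_dose_array",
    "read_copyid_records",
    "write_copyid_records",
    "write_rtdose",
    "read_rtdose",
    "normalize_to_reference",
    "median_filter_dose",
    "sum_fields",
    "rotate_volume",
]


@dataclass
class DoseGrid:
    """A 3D dose grid with RT Dose geometry.

    values
        Stored values, shape (n_slices, n_rows, n_cols).  Physical dose in
        Gy at a voxel is ``values * grid_scaling``.
    image_position
        Patient (LPS) coordinates in mm of the center of voxel (0, 0, 0).
    pixel_spacing
        (row, column) spacing in mm; rows advance along patient y, columns
        along patient x.
    frame_offsets
        Per-slice offsets in mm from image_position along patient z;
        ``frame_offsets[0] == 0`` and strictly increasing.
    """

    values: np.ndarray
    grid_scaling: float
    image_position: np.ndarray
    pixel_spacing: np.ndarray
    frame_offsets: np.ndarray
    series_description: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.image_position = np.asarray(self.image_position, float)
        self.pixel_spacing = np.asarray(self.pixel_spacing, float)
        self.frame_offsets = np.asarray(self.frame_offsets, float)
        if self.values.ndim != 3:
            raise StructuralError("values must be (slices, rows, cols)")
        if len(self.frame_offsets) != self.values.shape[0]:
            raise StructuralError("frame_offsets length must equal slice count")
        if len(self.frame_offsets) and abs(self.frame_offsets[0]) > 1e-9:
            raise StructuralError("frame_offsets[0] must be 0")
        if np.any(np.diff(self.frame_offsets) <= 0):
            raise StructuralError("frame_offsets must be strictly increasing")
        if not self.grid_scaling > 0:
            raise DomainError("grid_scaling must be > 0")

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def physical(self) -> np.ndarray:
        """Dose in Gy (float64)."""
        return self.values.astype(np.float64) * self.grid_scaling

    def world_to_continuous_index(self, points: np.ndarray) -> np.ndarray:
        """Patient mm (x, y, z) -> fractional (slice, row, col) indices.

        Slice lookup interpolates within the frame-offset vector so
        non-uniform slice spacing is handled.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        col = (pts[:, 0] - self.image_position[0]) / self.pixel_spacing[1]
        row = (pts[:, 1] - self.image_position[1]) / self.pixel_spacing[0]
        z = pts[:, 2] - self.image_position[2]
        sl = np.interp(z, self.frame_offsets, np.arange(len(self.frame_offsets)))
        # np.interp clamps; recover out-of-range positions linearly at ends
        dz0 = self.frame_offsets[1] - self.frame_offsets[0] if len(self.frame_offsets) > 1 else 1.0
        dz1 = (
            self.frame_offsets[-1] - self.frame_offsets[-2]
            if len(self.frame_offsets) > 1
            else 1.0
        )
        below = z < self.frame_offsets[0]
        above = z > self.frame_offsets[-1]
        sl = np.where(below, (z - self.frame_offsets[0]) / dz0, sl)
        sl = np.where(above, len(self.frame_offsets) - 1 + (z - self.frame_offsets[-1]) / dz1, sl)
        return np.column_stack([sl, row, col])

    def voxel_centers_mm(self):
        """(x, y, z) 1D coordinate arrays of voxel centers, patient mm."""
        n_sl, n_row, n_col = self.shape
        x = self.image_position[0] + np.arange(n_col) * self.pixel_spacing[1]
        y = self.image_position[1] + np.arange(n_row) * self.pixel_spacing[0]
        z = self.image_position[2] + self.frame_offsets
        return x, y, z

    def sample(self, points: np.ndarray, outside: float = np.nan) -> np.ndarray:
        """Trilinear physical-dose samples at patient-mm points."""
        idx = self.world_to_continuous_index(points)
        eps = 1e-9
        inside = (
            (idx[:, 0] >= -eps)
            & (idx[:, 0] <= self.shape[0] - 1 + eps)
            & (idx[:, 1] >= -eps)
            & (idx[:, 1] <= self.shape[1] - 1 + eps)
            & (idx[:, 2] >= -eps)
            & (idx[:, 2] <= self.shape[2] - 1 + eps)
        )
        out = np.full(len(idx), outside, float)
        if inside.any():
            out[inside] = ndimage.map_coordinates(
                self.physical(), idx[inside].T, order=1, mode="nearest"
            )
        return out

    def same_geometry(self, other: "DoseGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.image_position, other.image_position, atol=tol)
            and np.allclose(self.pixel_spacing, other.pixel_spacing, atol=tol)
            and np.allclose(self.frame_offsets, other.frame_offsets, atol=tol)
        )


@dataclass(frozen=True)
class CopyIdRecord:
    """One Geant4 scorer record: linear voxel id and its scored dose."""

    copyid: int
    dose: float

    def __post_init__(self) -> None:
        if self.copyid < 0:
            raise DomainError("copyid must be non-negative")


_ORDERINGS = ("xyz", "xzy", "yxz", "yzx", "zxy", "zyx")


def _decompose(copyids: np.ndarray, dims: tuple[int, int, int], ordering: str):
    """copyid -> (x, y, z) indices; first axis letter varies fastest."""
    if ordering not in _ORDERINGS:
        raise DomainError(f"ordering must be one of {_ORDERINGS}")
    n = {"x": dims[0], "y": dims[1], "z": dims[2]}
    axes = list(ordering)
    rem = copyids
    idx = {}
    for ax in axes:
        idx[ax] = rem % n[ax]
        rem = rem // n[ax]
    return idx["x"], idx["y"], idx["z"]


def copyids_to_dose_array(
    records,
    dims: tuple[int, int, int],
    ordering: str = "xyz",
    *,
    grid_scaling: float = 1.0,
    image_position=(0.0, 0.0, 0.0),
    pixel_spacing=(1.0, 1.0),
    slice_spacing: float = 1.0,
    series_description: str = "Geant4 import",
) -> DoseGrid:
    """Scatter (copyid, dose) records into a 3D dose grid.

    ``dims`` is (n_x, n_y, n_z); the stored array has shape (n_z, n_y, n_x).
    ``ordering`` names the scorer nesting with the fastest-varying axis
    first (default ``"xyz"``: copyid = x + n_x*(y + n_y*z)).  Repeated
    copyids accumulate by summation, so multi-run outputs can be merged;
    total dose is conserved.
    """
    n_x, n_y, n_z = (int(d) for d in dims)
    if min(n_x, n_y, n_z) <= 0:
        raise DomainError("dims must be positive")
    recs = list(records)
    arr = np.zeros((n_z, n_y, n_x), np.float64)
    if not recs:
        warnings.warn("no scorer records: returning an all-zero grid")
    else:
        ids = np.array([r.copyid for r in recs], np.int64)
        doses = np.array([r.dose for r in recs], np.float64)
        bad = np.flatnonzero((ids < 0) | (ids >= n_x * n_y * n_z))
        if bad.size:
            raise IndexError(
                f"record {bad[0]}: copyid {ids[bad[0]]} outside grid of "
                f"{n_x * n_y * n_z} voxels"
            )
        x, y, z = _decompose(ids, (n_x, n_y, n_z), ordering)
        np.add.at(arr, (z, y, x), doses)
    return DoseGrid(
        values=arr,
        grid_scaling=grid_scaling,
        image_position=np.asarray(image_position, float),
        pixel_spacing=np.asarray(pixel_spacing, float),
        frame_offsets=np.arange(n_z) * float(slice_spacing),
        series_description=series_description,
    )


def read_copyid_records(source) -> list[CopyIdRecord]:
    """Read delimited ``copyid,dose`` text (``#`` comments, blank lines ok)."""
    records = []
    with open(source) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise StructuralError(f"{source}:{ln}: expected 'copyid,dose'")
            records.append(CopyIdRecord(int(parts[0]), float(parts[1])))
    return records


def write_copyid_records(records, destination) -> None:
    with open(destination, "w") as fh:
        fh.write("# copyid,dose\n")
        for r in records:
            fh.write(f"{r.copyid},{r.dose!r}\n")


# ---------------------------------------------------------------------------
# DICOM RT Dose
# ---------------------------------------------------------------------------

_UINT32_MAX = np.iinfo(np.uint32).max


def write_rtdose(grid: DoseGrid, destination, *, float_storage: bool = False) -> None:
    """Serialize a dose grid as a DICOM RT Dose file.

    Stored pixels are 32-bit unsigned integers with an auto-computed Dose
    Grid Scaling (the RT Dose convention); ``float_storage=True`` keeps
    the values bit-exact in a 32-bit float pixel matrix instead.
    Populates modality RTDOSE, Image Position, Rows/Columns, Pixel
    Spacing, Number of Frames (= slice count) and the Grid Frame Offset
    Vector (per-slice z offsets from Image Position).
    """
    n_frames, n_rows, n_cols = grid.shape

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = RTDoseStorage
    file_meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = RTDoseStorage
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.SeriesDescription = grid.series_description
    ds.PatientName = ""
    ds.PatientID = ""
    ds.ImagePositionPatient = [float(v) for v in grid.image_position]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.Rows = n_rows
    ds.Columns = n_cols
    ds.NumberOfFrames = n_frames
    ds.PixelSpacing = [float(grid.pixel_spacing[0]), float(grid.pixel_spacing[1])]
    ds.GridFrameOffsetVector = [float(v) for v in grid.frame_offsets]
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"

    physical = grid.physical()
    if float_storage:
        ds.BitsAllocated = 32
        ds.DoseGridScaling = 1.0
        ds.FloatPixelData = physical.astype(np.float32).tobytes()
    else:
        max_dose = float(physical.max())
        scaling = max_dose / _UINT32_MAX if max_dose > 0 else 1.0
        stored = np.round(physical / scaling).astype(np.uint32)
        ds.BitsAllocated = 32
        ds.BitsStored = 32
        ds.HighBit = 31
        ds.PixelRepresentation = 0
        ds.DoseGridScaling = scaling
        ds.PixelData = stored.tobytes()

    ds.save_as(destination, enforce_file_format=True)


def read_rtdose(source) -> DoseGrid:
    """Load a DICOM RT Dose file into a :class:`DoseGrid`."""
    ds = pydicom.dcmread(source)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise StructuralError(f"not an RT Dose file (modality {getattr(ds, 'Modality', None)!r})")
    if "GridFrameOffsetVector" not in ds:
        raise StructuralError("RT Dose file lacks a Grid Frame Offset Vector")
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    shape = (n_frames, int(ds.Rows), int(ds.Columns))
    if "FloatPixelData" in ds:
        values = np.frombuffer(ds.FloatPixelData, np.float32).reshape(shape).copy()
    else:
        values = ds.pixel_array.reshape(shape).copy()
    return DoseGrid(
        values=values,
        grid_scaling=float(getattr(ds, "DoseGridScaling", 1.0)),
        image_position=np.asarray(ds.ImagePositionPatient, float),
        pixel_spacing=np.asarray(ds.PixelSpacing, float),
        frame_offsets=np.asarray(ds.GridFrameOffsetVector, float),
        series_description=str(getattr(ds, "SeriesDescription", "")),
    )


# ---------------------------------------------------------------------------
# dose operations
# ---------------------------------------------------------------------------


def normalize_to_reference(mc: DoseGrid, ref: DoseGrid, point) -> DoseGrid:
    """Rescale MC dose so it equals the reference dose at ``point``.

    Only the grid scaling changes (multiplied by ref/mc dose at the
    point); stored values are untouched, which makes the operation exact
    and idempotent.
    """
    point = np.asarray(point, float)
    mc_dose = float(mc.sample(point[None, :])[0])
    ref_dose = float(ref.sample(point[None, :])[0])
    if np.isnan(mc_dose) or np.isnan(ref_dose):
        raise IndexError("normalization point lies outside a grid")
    if mc_dose <= 0:
        raise NormalizationError("MC dose is zero at the normalization point")
    return replace(mc, grid_scaling=mc.grid_scaling * ref_dose / mc_dose)


def median_filter_dose(grid: DoseGrid, kernel: int | tuple[int, int, int] = 3) -> DoseGrid:
    """Median-filter the stored dose values (MC statistical-noise removal).

    ``kernel`` is the odd window size per (slice, row, col) axis; edges use
    nearest-value padding.  The filter is non-expansive (output range
    within input range) and leaves all geometry metadata unchanged.
    """
    if np.isscalar(kernel):
        kernel = (int(kernel),) * 3
    kernel = tuple(int(k) for k in kernel)
    if any(k % 2 == 0 or k < 1 for k in kernel):
        raise DomainError("kernel sizes must be odd and >= 1")
    if any(k > s for k, s in zip(kernel, grid.shape)):
        raise DomainError("kernel exceeds grid dimensions")
    filtered = ndimage.median_filter(grid.values, size=kernel, mode="nearest")
    return replace(grid, values=filtered)


def resample_to_geometry(grid: DoseGrid, target: DoseGrid, outside: float = 0.0) -> DoseGrid:
    """Trilinearly resample a grid's physical dose onto ``target``'s lattice."""
    x, y, z = target.voxel_centers_mm()
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    dose = grid.sample(pts, outside=np.nan)
    dose = np.where(np.isnan(dose), outside, dose).reshape(target.shape)
    return DoseGrid(
        values=dose,
        grid_scaling=1.0,
        image_position=target.image_position.copy(),
        pixel_spacing=target.pixel_spacing.copy(),
        frame_offsets=target.frame_offsets.copy(),
        series_description=grid.series_description,
    )


def sum_fields(grids, resample: bool = False) -> DoseGrid:
    """Voxelwise sum of physical doses (the composite multi-field dose).

    With ``resample=True`` every grid after the first is trilinearly
    resampled onto the first grid's geometry.  The output stores physical
    dose directly (grid_scaling 1), preserving full dynamic range.
    """
    grids = list(grids)
    if not grids:
        raise DomainError("need at least one grid")
    base = grids[0]
    total = base.physical()
    for g in grids[1:]:
        if g.same_geometry(base):
            total = total + g.physical()
        elif resample:
            total = total + resample_to_geometry(g, base).physical()
        else:
            raise GeometryMismatchError("grids differ in geometry; pass resample=True")
    return DoseGrid(
        values=total,
        grid_scaling=1.0,
        image_position=base.image_position.copy(),
        pixel_spacing=base.pixel_spacing.copy(),
        frame_offsets=base.frame_offsets.copy(),
        series_description="composite dose",
    )


_AXIS_VECTORS = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0])}


def rotate_volume(
    grid: DoseGrid,
    angle_deg: float,
    axis: str = "z",
    center=None,
    fill_value: float = 0.0,
) -> DoseGrid:
    """Resample a volume under rigid rotation about a patient axis.

    Rotating the static volume by the gantry angle (instead of rotating
    the source) keeps the beam along a fixed axis in simulation space.
    Trilinear interpolation; voxels rotated in from outside the original
    field of view take ``fill_value`` (use -1000 for CT volumes in HU,
    i.e. air; 0 is appropriate for dose).  Requires uniform slice spacing.
    """
    if axis not in _AXIS_VECTORS:
        raise DomainError("axis must be 'x', 'y' or 'z'")
    if not np.isfinite(angle_deg):
        raise DomainError("angle must be finite")
    offsets = grid.frame_offsets
    if len(offsets) > 1 and not np.allclose(np.diff(offsets), offsets[1] - offsets[0]):
        raise DomainError("rotation requires uniform slice spacing")

    x, y, z = grid.voxel_centers_mm()
    if center is None:
        center = np.array([x.mean(), y.mean(), z.mean()])
    center = np.asarray(center, float)

    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    k = _AXIS_VECTORS[axis]
    kx = np.array(
        [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]]
    )
    rot = np.eye(3) * c + s * kx + (1 - c) * np.outer(k, k)

    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    # output voxel at p samples the input at R^-1 (p - center) + center
    src = (pts - center) @ rot + center  # rot is orthogonal: R^-1 = R^T; p @ R == R^T p
    idx = grid.world_to_continuous_index(src)
    # snap sub-micro-index numerical overshoot back onto the boundary so a
    # nominally identical lattice (0, 90, 360 degrees...) is not filled
    for a, n in enumerate(grid.shape):
        col = idx[:, a]
        idx[:, a] = np.where((col > -1e-6) & (col < 0), 0.0, col)
        idx[:, a] = np.where((idx[:, a] > n - 1) & (idx[:, a] < n - 1 + 1e-6), n - 1, idx[:, a])
    vals = ndimage.map_coordinates(
        grid.values.astype(np.float64), idx.T, order=1, mode="constant", cval=fill_value
    ).reshape(grid.shape)
    return replace(grid, values=vals)
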