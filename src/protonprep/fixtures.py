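"""Deterministic synthetic inputs for every pipeline stage.

Nothing here claims anatomical realism: the generators produce the *data
shapes* the pipeline consumes — an RT Ion Plan with a compensator
thickness map and a block contour, paired reference/evaluation dose grids
with controlled perturbations, and Geant4-style scorer records — so that
parsing, meshing, reconstruction and comparison can all be exercised
without any clinical export or simulation run.

Default magnitudes are chosen to resemble a thorax-phantom proton case:
a ~200 x 200 x 120 mm dose volume at 2 mm spacing with a ~30 mm diameter
Gaussian target, a compensator of a few cm of acrylic at 2.5 mm milling
resolution, and a beam line with VSAD 2000 mm and snout position 300 mm.
The evaluation grid perturbations (rigid shift, global scale,
multiplicative Gaussian noise truncated at zero) emulate the disagreement
modes seen between a TPS and a Monte Carlo recalculation: setup/geometry
offsets, output-factor differences, and MC statistical noise.

Every generator is a pure function of its spec (seed included): repeated
calls produce byte-identical files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Literal

import numpy as np
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .dose_io import CopyIdRecord, DoseGrid

__all__ = ["FixtureSpec", "make_synthetic_rtplan", "make_dose_pair", "make_copyid_records"]

RT_ION_PLAN_STORAGE = "1.2.840.10008.5.1.4.1.1.481.8"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic case.

    Compensator families: ``flat`` (uniform slab), ``ramp`` (linear wedge)
    and ``gauss`` (a Gaussian bump on a base slab, the typical shape that
    pulls dose around a target).  Aperture families: ``circle``,
    ``square`` and ``star`` cutouts.  Dose phantoms: ``uniform``,
    ``ramp`` (linear along x) and ``gauss`` (spherical target).
    """

    seed: int = 0
    n_beams: int = 1
    # compensator
    comp_rows: int = 20
    comp_cols: int = 20
    comp_spacing: float = 2.5  # mm
    comp_family: Literal["flat", "ramp", "gauss"] = "gauss"
    comp_base_thickness: float = 20.0  # mm
    comp_bump_thickness: float = 30.0  # mm extra at the bump center
    # aperture
    aperture_family: Literal["circle", "square", "star"] = "circle"
    aperture_cutout_size: float = 40.0  # mm (diameter / side / outer star dia)
    aperture_outer_diameter: float = 100.0  # mm
    aperture_thickness: float = 50.0  # mm
    # beam line
    vsad: float = 2000.0  # mm
    snout_position: float = 300.0  # mm
    gantry_angle: float = 0.0  # degrees
    # dose phantom
    dose_shape: tuple[int, int, int] = (60, 100, 100)  # (slices, rows, cols)
    dose_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # (dz, drow, dcol) mm
    dose_family: Literal["uniform", "ramp", "gauss"] = "gauss"
    target_sigma: float = 15.0  # mm; ~30 mm diameter target at FWHM/2 scale
    prescription_dose: float = 2.0  # Gy at the target center
    # evaluation-grid perturbation
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, z)
    dose_scale: float = 1.0
    noise_pct: float = 0.0  # sigma of multiplicative Gaussian noise, percent


def _rng(spec: FixtureSpec, salt: str) -> np.random.Generator:
    h = hashlib.sha256(f"{spec.seed}:{salt}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little"))


def _deterministic_uid(spec: FixtureSpec, salt: str) -> str:
    h = hashlib.sha256(f"{spec.seed}:{salt}".encode()).hexdigest()
    return "2.25." + str(int(h[:30], 16))


def compensator_thickness(spec: FixtureSpec, beam: int = 0) -> np.ndarray:
    """Thickness map (mm) of the requested family; strictly positive."""
    rows, cols = spec.comp_rows, spec.comp_cols
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if spec.comp_family == "flat":
        t = np.full((rows, cols), spec.comp_base_thickness, float)
    elif spec.comp_family == "ramp":
        t = spec.comp_base_thickness + spec.comp_bump_thickness * jj / max(cols - 1, 1)
    else:  # gauss
        r2 = ((ii - (rows - 1) / 2) ** 2 + (jj - (cols - 1) / 2) ** 2) * spec.comp_spacing**2
        sigma = 0.25 * min(rows, cols) * spec.comp_spacing
        t = spec.comp_base_thickness + spec.comp_bump_thickness * np.exp(-r2 / (2 * sigma**2))
    # tiny deterministic per-beam variation so multi-beam plans differ
    rng = _rng(spec, f"comp{beam}")
    t = t + rng.uniform(0, 0.5, size=t.shape).round(3)
    return np.round(t, 3)


def aperture_vertices(spec: FixtureSpec, beam: int = 0) -> np.ndarray:
    """Cutout polygon (mm, isocenter plane) for the requested family."""
    if spec.aperture_family == "square":
        s = spec.aperture_cutout_size / 2.0
        return np.array([[-s, -s], [s, -s], [s, s], [-s, s]], float)
    n = 32 if spec.aperture_family == "circle" else 10
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r_out = spec.aperture_cutout_size / 2.0
    if spec.aperture_family == "circle":
        r = np.full(n, r_out)
    else:  # star: alternating outer/inner radii
        r = np.where(np.arange(n) % 2 == 0, r_out, 0.45 * r_out)
    return np.round(np.column_stack([r * np.cos(ang), r * np.sin(ang)]), 4)


def make_synthetic_rtplan(spec: FixtureSpec, destination) -> None:
    """Write a minimal, standards-shaped RT Ion Plan DICOM file.

    Each beam carries an ion range compensator (thickness map + corner
    position + pixel spacing), an ion block (cutout contour + thickness)
    and the beam-line distances (VSAD; snout position and gantry angle on
    the first control point).  All UIDs and dates are derived from the
    spec, so identical specs produce byte-identical files.
    """
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = RT_ION_PLAN_STORAGE
    file_meta.MediaStorageSOPInstanceUID = _deterministic_uid(spec, "sop")
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    file_meta.ImplementationClassUID = "2.25.1919510953"

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = RT_ION_PLAN_STORAGE
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.PatientName = "Synthetic^Phantom"
    ds.PatientID = f"SYN{spec.seed:06d}"
    ds.StudyInstanceUID = _deterministic_uid(spec, "study")
    ds.SeriesInstanceUID = _deterministic_uid(spec, "series")
    ds.StudyDate = "20180101"
    ds.StudyTime = "000000"
    ds.RTPlanLabel = "synthetic"
    ds.RTPlanDate = "20180101"
    ds.RTPlanTime = "000000"

    beams = []
    for b in range(spec.n_beams):
        beam = Dataset()
        beam.BeamNumber = b + 1
        beam.BeamName = f"Field{b + 1}"
        beam.BeamType = "STATIC"
        beam.RadiationType = "PROTON"
        beam.TreatmentMachineName = "DS-PROTON"
        beam.VirtualSourceAxisDistances = [spec.vsad, spec.vsad]
        beam.NumberOfRangeShifters = 0
        beam.NumberOfBoli = 0

        t = compensator_thickness(spec, b)
        comp = Dataset()
        comp.CompensatorNumber = 1
        comp.CompensatorRows = t.shape[0]
        comp.CompensatorColumns = t.shape[1]
        comp.CompensatorPixelSpacing = [spec.comp_spacing, spec.comp_spacing]
        comp.CompensatorPosition = [
            -(t.shape[1] - 1) / 2.0 * spec.comp_spacing,
            -(t.shape[0] - 1) / 2.0 * spec.comp_spacing,
        ]
        comp.CompensatorThicknessData = [float(v) for v in t.ravel()]
        beam.NumberOfCompensators = 1
        beam.IonRangeCompensatorSequence = [comp]

        verts = aperture_vertices(spec, b)
        block = Dataset()
        block.BlockNumber = 1
        block.BlockType = "APERTURE"
        block.BlockDivergence = "ABSENT"
        block.BlockNumberOfPoints = len(verts)
        block.BlockData = [float(v) for v in verts.ravel()]
        block.BlockThickness = spec.aperture_thickness
        beam.NumberOfBlocks = 1
        beam.IonBlockSequence = [block]

        cp = Dataset()
        cp.ControlPointIndex = 0
        cp.SnoutPosition = spec.snout_position
        cp.GantryAngle = spec.gantry_angle
        cp.IsocenterPosition = [0.0, 0.0, 0.0]
        beam.NumberOfControlPoints = 1
        beam.IonControlPointSequence = [cp]
        beams.append(beam)
    ds.IonBeamSequence = beams

    ds.save_as(destination, enforce_file_format=True)


def _phantom_field(spec: FixtureSpec):
    """Analytic dose field D(x, y, z) in Gy as a callable on mm points."""
    n_sl, n_row, n_col = spec.dose_shape
    dz, drow, dcol = spec.dose_spacing
    center = np.array(
        [(n_col - 1) / 2 * dcol, (n_row - 1) / 2 * drow, (n_sl - 1) / 2 * dz]
    )
    if spec.dose_family == "uniform":
        return lambda pts: np.full(len(pts), spec.prescription_dose)
    if spec.dose_family == "ramp":
        x_max = (n_col - 1) * dcol

        def ramp(pts):
            return spec.prescription_dose * (0.1 + 0.9 * pts[:, 0] / x_max)

        return ramp

    def gauss(pts):
        r2 = ((pts - center) ** 2).sum(axis=1)
        return spec.prescription_dose * np.exp(-r2 / (2 * spec.target_sigma**2))

    return gauss


def _grid_points(spec: FixtureSpec) -> np.ndarray:
    n_sl, n_row, n_col = spec.dose_shape
    dz, drow, dcol = spec.dose_spacing
    x = np.arange(n_col) * dcol
    y = np.arange(n_row) * drow
    z = np.arange(n_sl) * dz
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


def make_dose_pair(spec: FixtureSpec) -> tuple[DoseGrid, DoseGrid]:
    """Reference grid plus a perturbed evaluation grid.

    The evaluation dose is the *analytic* phantom field re-evaluated at
    positions displaced by ``-shift_mm`` (equivalent to rigidly shifting
    the distribution by ``+shift_mm``), scaled by ``dose_scale``, then
    degraded with multiplicative Gaussian noise of ``noise_pct`` percent
    truncated at zero.  Using the analytic field avoids interpolation
    error, so closed-form gamma expectations hold exactly.
    """
    field_fn = _phantom_field(spec)
    pts = _grid_points(spec)
    n_sl, n_row, n_col = spec.dose_shape
    dz, drow, dcol = spec.dose_spacing

    ref_vals = field_fn(pts).reshape(spec.dose_shape)
    shift = np.asarray(spec.shift_mm, float)
    eval_vals = spec.dose_scale * field_fn(pts - shift[None, :]).reshape(spec.dose_shape)
    if spec.noise_pct > 0:
        rng = _rng(spec, "noise")
        factor = 1.0 + spec.noise_pct / 100.0 * rng.standard_normal(eval_vals.shape)
        eval_vals = np.maximum(eval_vals * factor, 0.0)

    def grid(vals, desc):
        return DoseGrid(
            values=vals,
            grid_scaling=1.0,
            image_position=np.zeros(3),
            pixel_spacing=np.array([drow, dcol]),
            frame_offsets=np.arange(n_sl) * dz,
            series_description=desc,
        )

    return grid(ref_vals, "synthetic reference (TPS stand-in)"), grid(
        eval_vals, "synthetic evaluation (MC stand-in)"
    )


def make_copyid_records(grid: DoseGrid, ordering: str = "xyz") -> list[CopyIdRecord]:
    """Emit one scorer record per nonzero voxel (inverse of reconstruction).

    ``copyids_to_dose_array(make_copyid_records(g), ...)`` reproduces the
    grid's stored values exactly.
    """
    n_sl, n_row, n_col = grid.shape
    n = {"x": n_col, "y": n_row, "z": n_sl}
    strides = {}
    mult = 1
    for ax in ordering:
        strides[ax] = mult
        mult *= n[ax]
    records = []
    vals = grid.values
    for sl, row, col in zip(*np.nonzero(vals)):
        cid = int(col) * strides["x"] + int(row) * strides["y"] + int(sl) * strides["z"]
        records.append(CopyIdRecord(cid, float(vals[sl, row, col])))
    return records
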