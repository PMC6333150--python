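# Methods

`protonprep` implements the data-handling workflow that surrounds a Monte
Carlo dose engine in a double-scattering proton clinic: exporting each
treatment field's patient-specific hardware into simulation-ready solid
models, and bringing the simulated dose back into the clinic's comparison
toolchain. The Monte Carlo transport itself (TOPAS/Geant4) is out of
scope; this package produces its geometry inputs and consumes its scored
outputs.

## Beam-line projection model

A double-scattering field is shaped by two devices mounted in the snout:
an acrylic range compensator (a milled 2D thickness map that conforms the
distal dose edge to the target) and a brass/steel aperture block (a cutout
that collimates the lateral edges). The planning system describes both as
projections onto the isocenter plane. Treating the beam as diverging from
a virtual point source at distance VSAD upstream of isocenter, a device
whose upstream face sits at distance *d* from isocenter must be shrunk
laterally by (VSAD − *d*)/VSAD.

For the aperture, *d* is the snout position, giving

    mag_aperture = (VSAD − SnoutPosition) / VSAD .

The compensator sits downstream of the aperture; its position differs
from the snout setting by a thickness term, giving

    mag_compensator = (VSAD − SnoutPosition + T) / VSAD .

Which physical thickness *T* denotes is genuinely ambiguous in clinical
plan exports (the block-thickness tag rides along with the compensator
geometry): the default here is the compensator's own maximum physical
thickness, with `ParseConfig.eq1_thickness="aperture"` selecting the
block-thickness tag instead. For typical geometries (VSAD ≈ 2 m,
thicknesses ≤ 7 cm) the two choices differ by ≤ 1% in the factor.

Only lateral lengths are scaled; thickness along the beam axis is a
physical property of the milled device and is never magnified.
Conventions: isocenter-plane coordinates are the DICOM beam-limiting-
device frame in mm, x along columns, y along rows; the compensator corner
position refers to the first pixel's **center** (DICOM
CompensatorPosition semantics); thickness values are interpreted in mm,
with `ParseConfig.thickness_unit_scale` available if a plan stores them
in other units.

## Solid meshing

The compensator is meshed as a **stepped voxel solid**: each pixel with
positive thickness becomes a rectangular column from the base plane to
its thickness. This matches the 3D-array route of the original Matlab
workflow and makes the enclosed volume exactly Σ thickness × pixel area,
which the tests exploit as an analytic oracle (agreement required to
0.1%, achieved to ~1e-10 relative). A smooth interpolated top surface is
deliberately not offered.

The aperture is rasterized on a square grid spanning the block's outer
circle: a cell is material iff its center is inside the circle (≤, so
boundary centers count) and strictly outside the cutout polygon (boundary
points count as cut out). The outer-circle diameter is not an RT Plan
attribute; it comes from configuration, or is inferred as the contour's
maximal radius plus a 25 mm margin, doubled. Raster resolution defaults
to 1 mm; at that resolution the raster area of a 100 mm block with a
40 mm square cutout matches πR² − s² to ~0.1%.

Watertightness is treated strictly: every edge of every produced mesh
must border exactly two faces. Two constructions make this non-trivial:

* **Vertical T-junctions.** Where columns of different heights meet at a
  grid node, wall faces are subdivided at every height level present at
  that node, and each wall is triangulated between its two vertical
  vertex chains, so chords match edge-for-edge.
* **Pinch points.** Cells touching only diagonally (checkerboard
  rasters, saddle configurations in height maps) would put four faces on
  one edge if vertices were shared. Vertex identity is therefore keyed by
  (node, z-level, edge-connected component of the cells still solid at
  that level): diagonal-only neighbours receive coincident but
  combinatorially distinct vertices. The surface remains strictly
  two-manifold while being geometrically identical.

`clean_mesh` replaces the interactive mesh-repair step (Netfabb) of the
original workflow: duplicate-vertex merging, degenerate-face removal, and
zero-deformation decimation that re-triangulates maximal coplanar regions
after dropping vertices that are facet-interior or collinear on a
straight crease. Every sub-step is validated — if it would break
watertightness (it would for checkerboard pinch vertices) or change the
volume by more than 1e-6 relative, it is rolled back with a warning.
Facets whose boundary has more than one loop (the aperture's annular top
face) are left untouched rather than risk T-junctions. The operation is
idempotent. STL output (binary or ASCII) is in mm; the convention is
stamped into the binary header text since STL itself is unitless.

## Dose model and Monte Carlo ingestion

`DoseGrid` mirrors the DICOM RT Dose object: stored values of shape
(slice, row, column), physical dose = stored × Dose Grid Scaling,
positioned by Image Position (center of voxel (0,0,0), patient LPS, mm),
Pixel Spacing (row, column) and the Grid Frame Offset Vector (per-slice z
offsets, first entry 0, strictly increasing). Files are written with
32-bit unsigned stored pixels and an auto-computed scaling spanning the
full dynamic range (quantization ≤ 0.5 × scaling ≈ 2e-10 of the maximum
dose); float storage is available behind a flag for bit-exact round
trips.

Geant4 scorers index voxels by a linear copy number. The decomposition
into (x, y, z) is mixed-radix with a configurable nesting order, default
x-fastest (copyid = x + n_x·(y + n_y·z)), because scorer layouts vary;
the order used is a logged configuration item in every run manifest.
Repeated copyids accumulate by summation so multi-run outputs can be
merged; the total dose is conserved to summation order.

MC output is in arbitrary per-primary units while TPS dose is in Gy, so
comparison requires one calibration point: `normalize_to_reference`
multiplies the grid scaling by (reference dose)/(MC dose) at a chosen
point, conventionally the isocenter. Stored values are untouched, which
makes the operation exact at the point and idempotent. MC statistical
noise is suppressed with a median filter (default 3×3×3, odd sizes per
axis, nearest-value edge padding) — median rather than mean because it
removes isolated outlier voxels without blurring gradients, and it is
non-expansive. Composite dose is the voxelwise sum of per-field grids,
with optional trilinear resampling onto the first grid's geometry.
Gantry angles are handled by rigidly rotating the static volume about a
patient axis (trilinear resampling, configurable fill for voxels rotated
in from outside; use −1000 for CT volumes in HU) rather than rotating
the source.

## Gamma analysis

For each reference voxel r at or above the low-dose threshold,

    γ(r) = min over e of sqrt( |x_e − x_r|²/δ² + (D_e − D_r)²/ΔD² ),

with δ the DTA criterion (mm) and ΔD the dose criterion as a fraction of
the normalization dose — the reference maximum in global mode (the
default, as in film-audit practice) or D_r in local mode. The low-dose
threshold is always taken against the global reference maximum.
Evaluation dose is interpolated trilinearly; the minimization runs over a
lattice of step δ/10 within a ball of radius 2δ. The truncation is
decision-safe: any candidate beyond 2δ contributes ≥ 2 from the spatial
term alone, so every γ ≤ 1 (indeed ≤ 2) is attained inside the ball.
Candidates are visited in order of increasing distance with a running
per-voxel lower bound (an offset at distance d cannot improve a voxel
whose current best is below d²/δ²), which prunes most of the search
without changing any result — the test suite verifies bit-level agreement
with an exhaustive no-pruning search. Defaults follow the package's
target use case: 7% / 5 mm with a 10% threshold. γ ≤ 1 is passing
(boundary inclusive); sub-threshold voxels are NaN in the map, flagged in
an explicit exclusion mask, and excluded from the pass-rate denominator.

A plane selector (axial/coronal/sagittal + index) restricts both the
evaluated voxels and the search offsets to the plane — a true 2D gamma,
as used for film-plane comparisons. Supporting tools: trilinear line
profiles between patient-mm points; signed dose-difference histograms in
percent of the normalization dose, truncated symmetrically (default
±20%) with out-of-window voxels tallied separately; and marching-squares
isodose contours returned in patient mm.

## Synthetic data: what it emulates and what it does not

The fixtures module generates every input the pipeline consumes, as pure
functions of a spec + seed (byte-identical on repetition):

* **RT Ion Plans** with the tag layout the parser reads (compensator
  rows/columns/spacing/position/thickness data, block contour and
  thickness, VSAD, snout position and gantry angle on the first control
  point). Deterministic UIDs are derived from the seed.
* **Dose pairs**: an analytic phantom field (uniform, linear ramp, or a
  spherical Gaussian target) evaluated on a DICOM-geometry lattice, plus
  an evaluation grid derived from the *same analytic field* under a
  rigid shift, a global scale factor, and multiplicative Gaussian noise
  truncated at zero. Re-evaluating the analytic field (rather than
  interpolating the reference grid) means closed-form gamma expectations
  hold without interpolation artefacts.
* **Scorer records**: the exact inverse of the copyid reconstruction.

Default magnitudes resemble a thorax-phantom proton case: 100×100×60
voxels at 2 mm, a Gaussian target with σ = 15 mm (≈30 mm diameter at
half-maximum), 2 Gy at the target center, a 20-cm-diameter block of
50 mm thickness, a compensator of 20 mm base + 30 mm bump at 2.5 mm
milling resolution, VSAD 2000 mm, snout position 300 mm. The spatial
perturbation model is rigid and the noise is voxel-independent; real
TPS-vs-MC disagreement also contains range errors, heterogeneity-driven
local deformations and correlated noise, so passing tests demonstrate
correctness of the *comparison machinery*, not clinical agreement of any
particular beam model. Several tests and the acceptance script use
smaller lattices (e.g. 16×16×8 or 17×17×9 at 3 mm) — chosen so
exhaustive brute-force searches remain tractable while still spanning
several DTA lengths around the target.

## Numerical choices and edge cases

* Heights are rounded to 1e-9 mm for vertex-level identity; merge
  tolerance for vertex deduplication is 1e-6 mm (far below milling
  precision, far above float noise).
* Gamma candidates falling outside the evaluation grid are not
  candidates; a reference voxel with no candidates gets γ = ∞. The grid
  boundary therefore depresses pass rates for shifts comparable to the
  margin — interior voxels carry the closed-form guarantees.
* `map_coordinates` constant-mode fill treats a coordinate 1e-16 below
  zero as fully outside; rotation therefore snaps sub-micro-index
  overshoot back onto the boundary so 0°/90°/360° rotations are exact.
* Ties: γ = 1 passes; a raster cell center exactly on the outer circle
  is material; exactly on the cutout polygon is cut out.
* Degenerate inputs raise typed errors (`EmptySolidError`,
  `ComponentAbsentError`, `GeometryMismatchError`, ...) rather than
  producing empty artifacts; an empty scorer record list yields an
  all-zero grid with a warning (a legitimate "no dose scored" outcome).
* Multiple compensators/blocks on one beam: the first is used, with a
  warning.

## Known limitations

* No CSG/boolean mesh operations; the aperture model is a straight
  extrusion (no divergence-matched tapered edges).
* No DVH computation, film-dosimetry registration, CT-series I/O or
  HU-to-material conversion.
* `rotate_volume` requires uniform slice spacing.
* The gamma search lattice (δ/10) bounds the reported γ from above by
  the lattice discretization; pass/fail decisions at the γ = 1 boundary
  inherit that granularity. The exhaustive-search tests pin the engine
  to its specification on the same lattice.
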