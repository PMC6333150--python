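# protonprep

Tooling for double-scattering proton therapy Monte Carlo workflows: turn
the patient-specific hardware of a treatment plan into simulation-ready
solid models, and turn Monte Carlo output back into clinic-comparable
DICOM dose with quantitative comparison against the planning system.

In a double-scattering system every treatment field carries two
patient-specific devices: an acrylic **range compensator** (a milled
thickness map conforming the distal dose edge to the target) and a metal
**aperture block** (a cutout collimating the lateral edges). Monte Carlo
engines such as TOPAS/Geant4 can import these as STL solids — but the
planning system exports them only as DICOM RT Plan tags, projected onto
the isocenter plane. And once the simulation has run, its scored dose
(linear "copyid" records in arbitrary per-primary units) has to be
reconstructed, normalized and compared against the TPS dose before it
means anything clinically. `protonprep` covers both directions:

* **Plan → geometry.** Parse compensator and block from an RT Ion Plan,
  scale them from the isocenter projection to their beam-line position
  with the projective magnification factors

  *mag*<sub>comp</sub> = (VSAD − SnoutPosition + *T*) / VSAD  and
  *mag*<sub>aper</sub> = (VSAD − SnoutPosition) / VSAD,

  then mesh them as watertight STL solids (stepped voxel extrusion for
  the compensator; outer-circle-minus-cutout rasterization for the
  aperture), with zero-deformation cleanup built in.
* **Simulation → comparison.** Reconstruct 3D dose from copyid records,
  write/read DICOM RT Dose with the full geometry tag set, normalize MC
  dose to the TPS at a point (isocenter), median-filter MC noise, sum
  fields into a composite, and compare: gamma index (2D planes or full
  3D; γ(r) = min<sub>e</sub> √(|x<sub>e</sub>−x<sub>r</sub>|²/δ² +
  (D<sub>e</sub>−D<sub>r</sub>)²/ΔD²), pass = γ ≤ 1), line profiles,
  truncated dose-difference histograms, and isodose contours.

The Monte Carlo transport itself is out of scope; this package prepares
its inputs and consumes its outputs. A fixtures module generates every
input synthetically (plans, dose pairs, scorer records), so the whole
pipeline runs and tests without clinical data.

## Worked example

Generate a synthetic case and run the stages from the shell (every
command is also a library function):

```bash
$ protonprep fixtures --seed 7 -o demo/
fixtures written to demo

$ protonprep make-compensator demo/rtplan.dcm -o demo/comp.stl
beam 0: mag 0.8751, volume 59349.7 mm^3 -> demo/comp.stl

$ protonprep make-aperture demo/rtplan.dcm --resolution 1.0 -o demo/aper.stl
beam 0: mag 0.8500, volume 185200.0 mm^3 -> demo/aper.stl

$ protonprep gamma demo/ref_dose.dcm demo/eval_dose.dcm --dd 7 --dta 5 --threshold 10
gamma pass rate: 100.00% (17592/17592)
```

The magnification factors follow from the synthetic beam line (VSAD
2000 mm, snout position 300 mm, ~50 mm compensator): the compensator is
scaled by 0.8751, the aperture by 0.8500, before extrusion. The mesh
volumes are exact voxel/raster sums (4 × 4 cm compensator columns;
a 10-cm block annulus extruded 50 mm). The unperturbed dose pair agrees
voxel-for-voxel, so all 17 592 voxels above the 10% threshold pass.

A perturbed evaluation grid (6 mm shift + 2% noise against a 5 mm DTA)
shows the comparison doing real work:

```bash
$ protonprep fixtures --spec demo/spec.json -o demo_shift/
$ protonprep gamma demo_shift/ref_dose.dcm demo_shift/eval_dose.dcm --dd 7 --dta 5 --threshold 10
gamma pass rate: 95.07% (16725/17592)
```

`protonprep full-run --spec spec.json -o run/` chains everything —
plan → STL pair → scorer records → RT Dose → normalization → median
filter → gamma + profile — and writes `run/manifest.json` recording
every resolved default (copyid ordering, filter kernel, gamma mode).

See `docs/methods.md` for the models, conventions and numerical choices.

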