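"""Quantitative comparison of two dose distributions.

The central tool is the gamma index, which blends a dose-difference
criterion (percent of a normalization dose) with a distance-to-agreement
(DTA) criterion in mm.  For a reference voxel r,

    gamma(r) = min over evaluation positions e of
               sqrt( |x_e - x_r|^2 / dta^2  +  (D_e - D_r)^2 / dD^2 )

where dD is the dose criterion times the normalization dose (global mode:
the reference grid's maximum; local mode: the reference dose at r).
Voxels below a low-dose threshold are excluded from evaluation, and
gamma <= 1 counts as passing.

The evaluation dose is interpolated trilinearly and the minimization runs
over a lattice with step dta/10 inside a ball of radius 2*dta.  Truncating
the search at 2*dta cannot change any pass/fail decision: a candidate
farther than 2*dta contributes at least sqrt((2*dta)^2/dta^2) = 2 from the
spatial term alone, so any gamma <= 1 is always attained inside the ball.
Candidates are visited in order of increasing distance with a running
lower bound, which prunes the search without changing its result.

Also provided: line profiles, signed dose-difference histograms (percent
of normalization dose, truncated symmetrically) and marching-squares
isodose contours — the standard plane-by-plane inspection kit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage import measure

from .dose_io import DoseGrid
from .errors import DomainError, GeometryMismatchError

__all__ = [
    "GammaParams",
    "GammaResult",
    "Profile",
    "gamma_index",
    "extract_profile",
    "dose_difference_histogram",
    "extract_isodose",
]


@dataclass(frozen=True)
class GammaParams:
    """Gamma-analysis criteria.

    Defaults follow common practice for film-audit style comparisons:
    7% dose difference, 5 mm DTA, 10% low-dose threshold, global
    normalization to the reference maximum.
    """

    dose_criterion: float = 7.0  # percent of normalization dose
    dta_criterion: float = 5.0  # mm
    low_dose_threshold: float = 10.0  # percent of normalization dose
    normalization: Literal["global", "local"] = "global"
    search_radius_factor: float = 2.0  # search cap, multiples of dta
    search_step_factor: float = 0.1  # lattice step, multiples of dta

    def __post_init__(self) -> None:
        if self.dose_criterion <= 0 or self.dta_criterion <= 0:
            raise DomainError("criteria must be > 0")
        if not 0 <= self.low_dose_threshold < 100:
            raise DomainError("threshold must be in [0, 100)")
        if self.search_radius_factor <= 0 or self.search_step_factor <= 0:
            raise DomainError("search factors must be > 0")


@dataclass
class GammaResult:
    """Gamma map plus pass-rate bookkeeping.

    ``gamma_map`` has the reference's shape (or the selected plane's);
    voxels excluded by the low-dose threshold hold NaN and are flagged in
    ``excluded`` so the pass-rate denominator stays auditable.
    """

    gamma_map: np.ndarray
    excluded: np.ndarray
    pass_rate: float
    n_evaluated: int
    n_passing: int


_PLANE_AXIS = {"axial": 0, "coronal": 1, "sagittal": 2}


def _plane_mask(shape, plane) -> np.ndarray:
    mask = np.zeros(shape, bool)
    if plane is None:
        mask[:] = True
        return mask
    name, index = plane
    if name not in _PLANE_AXIS:
        raise DomainError("plane must be ('axial'|'coronal'|'sagittal', index)")
    sl = [slice(None)] * 3
    sl[_PLANE_AXIS[name]] = int(index)
    mask[tuple(sl)] = True
    return mask


def _search_offsets(params: GammaParams, plane_axis: int | None) -> np.ndarray:
    """Lattice offsets (mm) within the search ball, sorted by distance.

    For 2D (in-plane) analyses the offsets are restricted to the plane.
    """
    step = params.dta_criterion * params.search_step_factor
    radius = params.dta_criterion * params.search_radius_factor
    n = int(np.floor(radius / step))
    axis_offsets = np.arange(-n, n + 1) * step
    # offsets in (x, y, z) patient axes; plane axes: slice->z, row->y, col->x
    ax = {0: "z", 1: "y", 2: "x"}.get(plane_axis)
    ox = axis_offsets if ax != "x" else np.array([0.0])
    oy = axis_offsets if ax != "y" else np.array([0.0])
    oz = axis_offsets if ax != "z" else np.array([0.0])
    gx, gy, gz = np.meshgrid(ox, oy, oz, indexing="ij")
    offsets = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    dist = np.linalg.norm(offsets, axis=1)
    keep = dist <= radius + 1e-9
    offsets, dist = offsets[keep], dist[keep]
    order = np.argsort(dist, kind="stable")
    return offsets[order], dist[order]


def gamma_index(
    ref: DoseGrid,
    eval_grid: DoseGrid,
    params: GammaParams | None = None,
    plane: tuple[str, int] | None = None,
) -> GammaResult:
    """Gamma map of an evaluation dose against a reference dose.

    ``plane`` restricts the analysis to a single axial / coronal /
    sagittal slice: only that slice's reference voxels are evaluated and
    the DTA search is confined to the plane (a true 2D gamma, as used for
    film-plane comparisons).  Without a plane the search is 3D.

    Evaluation positions falling outside the evaluation grid are not
    candidates.  Reference voxels below the low-dose threshold are
    excluded from the map (NaN) and from the pass-rate denominator.
    """
    params = params or GammaParams()
    ref_dose = ref.physical()
    norm = float(ref_dose.max())
    if norm <= 0:
        raise DomainError("reference maximum dose is zero")

    # the low-dose threshold is always taken against the global reference
    # maximum, regardless of the dose-difference normalization mode
    mask = _plane_mask(ref.shape, plane)
    threshold_mask = ref_dose >= params.low_dose_threshold / 100.0 * norm
    eval_mask = mask & threshold_mask
    if not eval_mask.any():
        raise DomainError("no reference voxel above the low-dose threshold")

    # world coordinates of evaluated reference voxels
    x, y, z = ref.voxel_centers_mm()
    sl_i, row_i, col_i = np.nonzero(eval_mask)
    pts = np.column_stack([x[col_i], y[row_i], z[sl_i]])
    d_ref = ref_dose[sl_i, row_i, col_i]

    if params.normalization == "global":
        delta_d = params.dose_criterion / 100.0 * norm * np.ones_like(d_ref)
    else:
        delta_d = params.dose_criterion / 100.0 * d_ref

    plane_axis = _PLANE_AXIS[plane[0]] if plane is not None else None
    offsets, dist = _search_offsets(params, plane_axis)
    dta2 = params.dta_criterion**2

    best = np.full(len(pts), np.inf)
    for off, d in zip(offsets, dist):
        spatial = d * d / dta2
        # lower-bound pruning: farther offsets cannot improve voxels whose
        # current best is already below the pure spatial term
        active = best > spatial
        if not active.any():
            break
        d_eval = eval_grid.sample(pts[active] + off, outside=np.nan)
        valid = ~np.isnan(d_eval)
        if not valid.any():
            continue
        g2 = spatial + ((d_eval[valid] - d_ref[active][valid]) / delta_d[active][valid]) ** 2
        idx = np.flatnonzero(active)[valid]
        best[idx] = np.minimum(best[idx], g2)

    gamma = np.sqrt(best)
    gamma_map = np.full(ref.shape, np.nan)
    gamma_map[sl_i, row_i, col_i] = gamma
    if plane is not None:
        sel = [slice(None)] * 3
        sel[plane_axis] = plane[1]
        gamma_map = gamma_map[tuple(sel)]
        excluded = ~eval_mask[tuple(sel)]
    else:
        excluded = ~eval_mask

    finite = np.isfinite(gamma)
    n_eval = int(finite.sum())
    n_pass = int((gamma[finite] <= 1.0).sum())
    pass_rate = 100.0 * n_pass / n_eval if n_eval else float("nan")
    return GammaResult(
        gamma_map=gamma_map,
        excluded=excluded,
        pass_rate=pass_rate,
        n_evaluated=n_eval,
        n_passing=n_pass,
    )


@dataclass
class Profile:
    """Dose sampled along a straight segment in patient coordinates."""

    positions: np.ndarray  # mm from the start point
    values: np.ndarray  # Gy
    endpoints: tuple[np.ndarray, np.ndarray]


def extract_profile(grid: DoseGrid, start, end, n_samples: int = 100) -> Profile:
    """Trilinear dose profile between two patient-mm points."""
    if n_samples < 2:
        raise DomainError("n_samples must be >= 2")
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    frac = np.linspace(0.0, 1.0, n_samples)
    pts = start[None, :] + frac[:, None] * (end - start)[None, :]
    vals = grid.sample(pts, outside=np.nan)
    if np.isnan(vals).any():
        raise IndexError("profile segment leaves the dose grid")
    return Profile(
        positions=frac * float(np.linalg.norm(end - start)),
        values=vals,
        endpoints=(start, end),
    )


def dose_difference_histogram(
    ref: DoseGrid,
    eval_grid: DoseGrid,
    truncation: float = 20.0,
    n_bins: int = 80,
    normalization_dose: float | None = None,
):
    """Histogram of signed eval-minus-ref differences, percent of norm dose.

    Differences are binned over [-truncation, +truncation]; voxels outside
    that window are tallied separately (the display convention of
    truncating the histogram tails rather than clipping them into the edge
    bins).  Returns ``(bin_edges, counts, n_underflow, n_overflow)``.
    """
    if not ref.same_geometry(eval_grid):
        raise GeometryMismatchError("histogram requires identical grid geometry")
    norm = normalization_dose if normalization_dose is not None else float(ref.physical().max())
    if norm <= 0:
        raise DomainError("normalization dose must be > 0")
    diff_pct = (eval_grid.physical() - ref.physical()).ravel() / norm * 100.0
    edges = np.linspace(-truncation, truncation, n_bins + 1)
    inside = (diff_pct >= -truncation) & (diff_pct <= truncation)
    counts, _ = np.histogram(diff_pct[inside], bins=edges)
    n_under = int((diff_pct < -truncation).sum())
    n_over = int((diff_pct > truncation).sum())
    return edges, counts, n_under, n_over


def extract_isodose(grid: DoseGrid, plane: tuple[str, int], levels) -> dict[float, list[np.ndarray]]:
    """Marching-squares isodose contours of one plane, in patient mm.

    Returns, per requested physical dose level, a list of polylines as
    (n, 2) arrays of the plane's in-plane patient coordinates — (x, y)
    for axial, (x, z) for coronal, (y, z) for sagittal.  Levels above the
    slice maximum simply yield no contours.
    """
    name, index = plane
    if name not in _PLANE_AXIS:
        raise DomainError("plane must be ('axial'|'coronal'|'sagittal', index)")
    axis = _PLANE_AXIS[name]
    sel = [slice(None)] * 3
    sel[axis] = int(index)
    slab = grid.physical()[tuple(sel)]

    x, y, z = grid.voxel_centers_mm()
    # slab axes after slicing: axial -> (row=y, col=x); coronal -> (slice=z,
    # col=x); sagittal -> (slice=z, row=y)
    axis0, axis1 = {
        0: (y, x),
        1: (z, x),
        2: (z, y),
    }[axis]

    out: dict[float, list[np.ndarray]] = {}
    for level in levels:
        if level <= 0:
            raise DomainError("isodose levels must be positive")
        polylines = []
        if slab.min() <= level <= slab.max():
            for contour in measure.find_contours(slab, level):
                a = np.interp(contour[:, 0], np.arange(len(axis0)), axis0)
                b = np.interp(contour[:, 1], np.arange(len(axis1)), axis1)
                polylines.append(np.column_stack([b, a]))
        out[float(level)] = polylines
    return out
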