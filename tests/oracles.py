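"""Independent reference implementations used only to check the package.

Everything here is deliberately written from scratch against the
definitions (exhaustive search, nested loops, closed forms) rather than
calling into the package's own code paths, so a test comparing the two
is a genuine dual-route check.
"""

from __future__ import annotations

import struct

import numpy as np


def trilinear(volume: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Manual trilinear interpolation at fractional (i, j, k) indices.

    Out-of-bounds points return NaN.
    """
    idx = np.asarray(idx, float)
    shape = np.array(volume.shape)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
    out = np.full(len(idx), np.nan)
    if not inside.any():
        return out
    p = idx[inside]
    lo = np.floor(p).astype(int)
    lo = np.minimum(lo, shape - 2)
    lo = np.maximum(lo, 0)
    f = p - lo
    acc = np.zeros(len(p))
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = (
                    (f[:, 0] if di else 1 - f[:, 0])
                    * (f[:, 1] if dj else 1 - f[:, 1])
                    * (f[:, 2] if dk else 1 - f[:, 2])
                )
                acc += w * volume[lo[:, 0] + di, lo[:, 1] + dj, lo[:, 2] + dk]
    out[inside] = acc
    return out


def brute_force_gamma(ref, eval_grid, params, chunk: int = 8) -> np.ndarray:
    """Exhaustive fine-lattice gamma search (no pruning, no early exit).

    Every lattice offset (step = dta * search_step_factor) in the ball of
    radius dta * search_radius_factor is evaluated for every reference
    voxel at or above the threshold; voxels are processed in chunks purely
    to bound memory.  Returns a gamma map with NaN below the threshold.
    """
    ref_dose = ref.physical()
    eval_dose = eval_grid.physical()
    norm = ref_dose.max()
    thr = params.low_dose_threshold / 100.0 * norm

    step = params.dta_criterion * params.search_step_factor
    radius = params.dta_criterion * params.search_radius_factor
    n = int(np.floor(radius / step))
    axis = np.arange(-n, n + 1) * step
    ox, oy, oz = np.meshgrid(axis, axis, axis, indexing="ij")
    offs = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    offs = offs[np.linalg.norm(offs, axis=1) <= radius + 1e-9]
    spatial2 = (np.linalg.norm(offs, axis=1) ** 2) / params.dta_criterion**2

    xr, yr, zr = ref.voxel_centers_mm()
    xe, ye, ze = eval_grid.voxel_centers_mm()
    gamma = np.full(ref.shape, np.nan)
    sl_i, row_i, col_i = np.nonzero(ref_dose >= thr)
    points = np.column_stack([xr[col_i], yr[row_i], zr[sl_i]])
    d_refs = ref_dose[sl_i, row_i, col_i]
    if params.normalization == "global":
        dds = np.full(len(d_refs), params.dose_criterion / 100.0 * norm)
    else:
        dds = params.dose_criterion / 100.0 * d_refs

    for start in range(0, len(points), chunk):
        p = points[start : start + chunk]
        d_r = d_refs[start : start + chunk]
        dd = dds[start : start + chunk]
        cand = p[:, None, :] + offs[None, :, :]  # (chunk, n_off, 3)
        flat = cand.reshape(-1, 3)
        idx = np.column_stack(
            [
                (flat[:, 2] - ze[0]) / (ze[1] - ze[0]),
                (flat[:, 1] - ye[0]) / (ye[1] - ye[0]),
                (flat[:, 0] - xe[0]) / (xe[1] - xe[0]),
            ]
        )
        d_e = trilinear(eval_dose, idx).reshape(len(p), -1)
        g2 = spatial2[None, :] + ((d_e - d_r[:, None]) / dd[:, None]) ** 2
        g2 = np.where(np.isnan(g2), np.inf, g2)
        g = np.sqrt(g2.min(axis=1))
        gamma[sl_i[start : start + chunk], row_i[start : start + chunk], col_i[start : start + chunk]] = g
    return gamma


def copyid_lookup_table(dims: tuple[int, int, int], ordering: str) -> dict[int, tuple[int, int, int]]:
    """Nested-loop enumeration of copyid -> (x, y, z), slowest axis outermost."""
    n = {"x": dims[0], "y": dims[1], "z": dims[2]}
    fast, mid, slow = ordering  # fastest-varying axis first
    table = {}
    cid = 0
    for ks in range(n[slow]):
        for km in range(n[mid]):
            for kf in range(n[fast]):
                coords = {fast: kf, mid: km, slow: ks}
                table[cid] = (coords["x"], coords["y"], coords["z"])
                cid += 1
    return table


def brute_force_median(volume: np.ndarray, kernel: tuple[int, int, int]) -> np.ndarray:
    """Median filter by explicit neighbourhood collection with edge clamping."""
    out = np.empty_like(volume, float)
    r = [k // 2 for k in kernel]
    shape = volume.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                vals = []
                for di in range(-r[0], r[0] + 1):
                    for dj in range(-r[1], r[1] + 1):
                        for dk in range(-r[2], r[2] + 1):
                            a = min(max(i + di, 0), shape[0] - 1)
                            b = min(max(j + dj, 0), shape[1] - 1)
                            c = min(max(k + dk, 0), shape[2] - 1)
                            vals.append(volume[a, b, c])
                out[i, j, k] = np.median(vals)
    return out


def read_binary_stl(path) -> tuple[np.ndarray, int]:
    """Minimal independent binary STL reader: (triangle vertices, count)."""
    with open(path, "rb") as fh:
        fh.read(80)
        (count,) = struct.unpack("<I", fh.read(4))
        tris = np.empty((count, 3, 3))
        for t in range(count):
            data = struct.unpack("<12fH", fh.read(50))
            tris[t] = np.array(data[3:12]).reshape(3, 3)
    return tris, count


def read_ascii_stl(path) -> np.ndarray:
    """Minimal independent ASCII STL reader returning triangle vertices."""
    tris = []
    current: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if parts and parts[0] == "vertex":
                current.append([float(v) for v in parts[1:4]])
                if len(current) == 3:
                    tris.append(current)
                    current = []
    return np.asarray(tris)


def stl_volume(tris: np.ndarray) -> float:
    """Signed volume from triangle soup via the divergence theorem."""
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)
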