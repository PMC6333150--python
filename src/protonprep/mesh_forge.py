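"""Watertight solid meshing of compensator heightmaps and aperture rasters.

A compensator is meshed as a stepped (voxelized) solid: each pixel of the
thickness map becomes a rectangular column from the base plane to its
thickness, and only exterior faces are emitted.  An aperture is rasterized
(inside the block's outer circle, outside the cutout polygon) and the
occupied cells are extruded to the block thickness with the same machinery.

Manifoldness at diagonal contacts
---------------------------------
Two occupied cells that touch only at a corner must not share mesh edges,
or the shared vertical edge would carry four faces.  Vertices are therefore
keyed by (grid node, connected group of occupied cells around that node):
edge-adjacent cells share vertices, diagonal-only neighbours get coincident
but combinatorially distinct copies.  Every produced mesh is watertight in
the strict sense (every edge borders exactly two faces).

The cleanup pass (`clean_mesh`) replaces the external mesh-repair step of
the original Matlab/Netfabb workflow: it merges duplicate vertices, drops
degenerate faces and re-triangulates maximal coplanar regions, all under a
zero-deformation guarantee — any sub-step that would change the enclosed
volume or break watertightness is rolled back with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
import trimesh

from .errors import DomainError, EmptySolidError, StructuralError
from .rtplan_components import ApertureContour, CompensatorMap

__all__ = [
    "RasterGrid",
    "heightmap_to_solid",
    "rasterize_aperture",
    "raster_to_solid",
    "clean_mesh",
    "write_stl",
    "read_stl",
]

#: STL files are unitless; all meshes produced here are in mm (DICOM
#: convention).  The note is embedded in binary STL headers.
STL_UNIT_NOTE = "protonprep: units mm"


@dataclass(frozen=True)
class RasterGrid:
    """Binary occupancy grid of an aperture block, ready for extrusion."""

    occupancy: np.ndarray  # (n_rows, n_cols) of {0,1}
    pixel_spacing: float  # mm per cell (square cells)
    origin: np.ndarray  # (x, y) of cell (0, 0) center, mm
    extrusion_thickness: float  # mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "occupancy", np.asarray(self.occupancy, bool))
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        if self.occupancy.ndim != 2:
            raise StructuralError("occupancy must be 2D")
        if not self.pixel_spacing > 0 or not self.extrusion_thickness > 0:
            raise DomainError("pixel_spacing and extrusion_thickness must be > 0")


# ---------------------------------------------------------------------------
# core extrusion
# ---------------------------------------------------------------------------


def _extrude_heightmap(
    heights: np.ndarray,
    spacing_row: float,
    spacing_col: float,
    origin_xy: np.ndarray,
) -> trimesh.Trimesh:
    """Mesh the solid under a per-cell height field (0 height = empty).

    ``origin_xy`` is the (x, y) of the *center* of cell (0, 0); x runs along
    columns, y along rows.  Returns a watertight mesh with outward normals.

    Wall faces between cells of different heights are subdivided at every
    height level present at their end nodes, so that vertical edges of
    neighbouring walls meet chord-for-chord (no T-junctions); each wall is
    then triangulated between its two vertical vertex chains.
    """
    h = np.asarray(heights, float)
    n_rows, n_cols = h.shape
    occ = h > 0
    if not occ.any():
        raise EmptySolidError("height field has no positive cells")

    # Node lattice: node (i, j) at the lower corner of cell (i, j).
    x0 = origin_xy[0] - spacing_col / 2.0
    y0 = origin_xy[1] - spacing_row / 2.0

    cell_id = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)

    def incident_cells(i: int, j: int) -> list[tuple[int, int]]:
        out = []
        for di in (-1, 0):
            for dj in (-1, 0):
                a, b = i + di, j + dj
                if 0 <= a < n_rows and 0 <= b < n_cols and occ[a, b]:
                    out.append((a, b))
        return out

    def group_at_level(i: int, j: int, ci: int, cj: int, z: float) -> int:
        """Vertex group at node (i, j), level z, for incident cell (ci, cj).

        Cells still solid at level z (height >= z) are partitioned into
        edge-connected groups around the node; diagonal-only contacts
        fall into different groups and therefore get coincident but
        combinatorially distinct vertices, which keeps pinch points
        (checkerboards, saddles) strictly two-manifold.
        """
        cells = [c for c in incident_cells(i, j) if h[c] >= z - 1e-9]
        parent = {c: c for c in cells}

        def find(c):
            while parent[c] != c:
                parent[c] = parent[parent[c]]
                c = parent[c]
            return c

        for a in cells:
            for b in cells:
                if abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1:
                    parent[find(a)] = find(b)
        root = find((ci, cj))
        return min(int(cell_id[c]) for c in cells if find(c) == root)

    def node_levels(i: int, j: int) -> list[float]:
        """Sorted distinct z-levels (base + incident cell heights) at a node."""
        levels = {0.0}
        for a, b in incident_cells(i, j):
            levels.add(round(float(h[a, b]), 9))
        return sorted(levels)

    vertices: list[tuple[float, float, float]] = []
    vindex: dict[tuple[int, int, int, float], int] = {}

    def vid(i: int, j: int, group: int, z: float) -> int:
        key = (i, j, group, round(z, 9))
        idx = vindex.get(key)
        if idx is None:
            idx = len(vertices)
            vindex[key] = idx
            vertices.append((x0 + j * spacing_col, y0 + i * spacing_row, z))
        return idx

    faces: list[tuple[int, int, int]] = []

    def quad(a: int, b: int, c: int, d: int) -> None:
        faces.append((a, b, c))
        faces.append((a, c, d))

    def wall(na, nb, cell, z_lo: float, z_hi: float) -> None:
        """Outward wall between z_lo..z_hi along grid edge na->nb.

        Vertex chains on each side include all node levels inside the
        span; triangulation advances whichever chain has the lower next
        level (both chains share first and last z).  ``cell`` is the
        owning (taller) cell, used to resolve vertex groups per level.
        """
        za = [z_lo] + [
            lv for lv in node_levels(*na) if z_lo + 1e-9 < lv < z_hi - 1e-9
        ] + [z_hi]
        zb = [z_lo] + [
            lv for lv in node_levels(*nb) if z_lo + 1e-9 < lv < z_hi - 1e-9
        ] + [z_hi]
        ca = [vid(*na, group_at_level(*na, *cell, z), z) for z in za]
        cb = [vid(*nb, group_at_level(*nb, *cell, z), z) for z in zb]
        i_a = i_b = 0
        while i_a < len(ca) - 1 or i_b < len(cb) - 1:
            if i_b < len(cb) - 1 and (i_a == len(ca) - 1 or zb[i_b + 1] <= za[i_a + 1]):
                faces.append((ca[i_a], cb[i_b], cb[i_b + 1]))
                i_b += 1
            else:
                faces.append((ca[i_a], cb[i_b], ca[i_a + 1]))
                i_a += 1

    for i in range(n_rows):
        for j in range(n_cols):
            if not occ[i, j]:
                continue
            z = round(float(h[i, j]), 9)
            cell = (i, j)
            nodes = ((i, j), (i, j + 1), (i + 1, j + 1), (i + 1, j))
            # top face (+z outward): CCW seen from above
            t = [vid(*nd, group_at_level(*nd, *cell, z), z) for nd in nodes]
            quad(t[0], t[1], t[2], t[3])
            # bottom face (-z outward)
            b = [vid(*nd, group_at_level(*nd, *cell, 0.0), 0.0) for nd in nodes]
            quad(b[0], b[3], b[2], b[1])
            # walls, emitted by the taller cell; node order makes the
            # normal ((nb - na) x +z) point away from this cell
            for di, dj, na, nb in (
                (-1, 0, (i, j), (i, j + 1)),  # -y side
                (1, 0, (i + 1, j + 1), (i + 1, j)),  # +y side
                (0, -1, (i + 1, j), (i, j)),  # -x side
                (0, 1, (i, j + 1), (i + 1, j + 1)),  # +x side
            ):
                a2, b2 = i + di, j + dj
                inside = 0 <= a2 < n_rows and 0 <= b2 < n_cols and occ[a2, b2]
                zn = round(float(h[a2, b2]), 9) if inside else 0.0
                if zn >= z:
                    continue
                wall(na, nb, cell, zn, z)

    return trimesh.Trimesh(
        vertices=np.asarray(vertices, float),
        faces=np.asarray(faces, np.int64),
        process=False,
    )


def heightmap_to_solid(comp: CompensatorMap) -> trimesh.Trimesh:
    """Mesh a compensator thickness map as a stepped watertight solid.

    The footprint is the set of pixels with positive thickness; the top
    surface is piecewise constant per pixel (voxelized, not interpolated),
    so the enclosed volume equals the analytic sum thickness x pixel area.
    """
    if not (comp.thickness > 0).any():
        raise EmptySolidError("compensator thickness map is all zero")
    mesh = _extrude_heightmap(
        comp.thickness,
        spacing_row=float(comp.pixel_spacing[0]),
        spacing_col=float(comp.pixel_spacing[1]),
        origin_xy=np.array([comp.corner_position[0], comp.corner_position[1]]),
    )
    return mesh


def rasterize_aperture(ap: ApertureContour, resolution: float) -> RasterGrid:
    """Rasterize the aperture block: outer circle minus cutout polygon.

    A cell center c is occupied iff ``|c| <= outer_diameter/2`` and c lies
    strictly outside the cutout polygon (boundary points count as cut out).
    The grid spans the outer circle's bounding square.
    """
    radius = ap.outer_diameter / 2.0
    if not 0 < resolution < radius:
        raise DomainError("resolution must be in (0, outer radius)")
    n = int(np.ceil(ap.outer_diameter / resolution))
    # cell centers, symmetric about the origin
    coords = (np.arange(n) - (n - 1) / 2.0) * resolution
    xx, yy = np.meshgrid(coords, coords)  # yy: rows (y), xx: cols (x)
    in_circle = np.hypot(xx, yy) <= radius
    poly = ap.as_polygon()
    in_cutout = shapely.intersects_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    occupancy = in_circle & ~in_cutout
    if not occupancy.any():
        raise EmptySolidError("cutout covers the whole block: empty aperture")
    return RasterGrid(
        occupancy=occupancy,
        pixel_spacing=resolution,
        origin=np.array([coords[0], coords[0]]),
        extrusion_thickness=ap.thickness,
    )


def raster_to_solid(grid: RasterGrid) -> trimesh.Trimesh:
    """Extrude the occupied cells of a raster to a watertight solid."""
    if not grid.occupancy.any():
        raise EmptySolidError("raster grid has no occupied cells")
    return _extrude_heightmap(
        grid.occupancy.astype(float) * grid.extrusion_thickness,
        spacing_row=grid.pixel_spacing,
        spacing_col=grid.pixel_spacing,
        origin_xy=grid.origin,
    )


# ---------------------------------------------------------------------------
# cleanup / zero-deformation decimation
# ---------------------------------------------------------------------------


def _edge_count_watertight(mesh: trimesh.Trimesh) -> bool:
    """Strict watertightness: every edge borders exactly two faces."""
    if len(mesh.faces) == 0:
        return False
    edges = np.sort(mesh.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool((counts == 2).all())


def _coplanar_facets(mesh: trimesh.Trimesh, normal_tol: float = 1e-8) -> list[np.ndarray]:
    """Maximal connected groups of coplanar faces (singletons included)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(mesh.faces)
    adj = mesh.face_adjacency
    if len(adj) == 0:
        return [np.array([i]) for i in range(n)]
    normals = mesh.face_normals
    same = (np.abs(np.einsum("ij,ij->i", normals[adj[:, 0]], normals[adj[:, 1]]) - 1.0)
            < normal_tol)
    # also require the planes to coincide, not only be parallel
    d0 = np.einsum("ij,ij->i", normals[adj[:, 0]], mesh.triangles_center[adj[:, 0]])
    d1 = np.einsum("ij,ij->i", normals[adj[:, 0]], mesh.triangles_center[adj[:, 1]])
    same &= np.abs(d0 - d1) < 1e-6
    pairs = adj[same]
    g = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(g, directed=False)
    return [np.flatnonzero(labels == k) for k in range(n_comp)]


def _boundary_loops(face_subset: np.ndarray, faces: np.ndarray) -> list[list[int]] | None:
    """Ordered boundary vertex loops of a face subset; None if ill-formed."""
    edges = {}
    for f in faces[face_subset]:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            if key in edges:
                edges[key] = None  # interior edge
            else:
                edges[key] = (a, b)  # remember orientation
    boundary = [v for v in edges.values() if v is not None]
    if not boundary:
        return None
    nxt = {}
    for a, b in boundary:
        if a in nxt:
            return None  # non-manifold boundary
        nxt[a] = b
    loops = []
    seen: set[int] = set()
    for start in list(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start:
            if cur in seen or cur not in nxt:
                return None
            loop.append(cur)
            seen.add(cur)
            cur = nxt[cur]
        loops.append(loop)
    return loops


def _ear_clip(points2d: np.ndarray) -> list[tuple[int, int, int]] | None:
    """Triangulate a simple CCW polygon by ear clipping; None on failure."""
    n = len(points2d)
    if n < 3:
        return None
    idx = list(range(n))
    tris: list[tuple[int, int, int]] = []

    def cross(o, a, b):
        return (points2d[a] - points2d[o])[0] * (points2d[b] - points2d[o])[1] - (
            points2d[a] - points2d[o]
        )[1] * (points2d[b] - points2d[o])[0]

    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 10 * n * n:
            return None
        clipped = False
        for k in range(len(idx)):
            p, c, q = idx[k - 1], idx[k], idx[(k + 1) % len(idx)]
            if cross(p, c, q) <= 1e-12:
                continue  # reflex or degenerate corner
            # no other polygon vertex may lie inside triangle p-c-q
            ok = True
            for other in idx:
                if other in (p, c, q):
                    continue
                if (
                    cross(p, c, other) >= -1e-12
                    and cross(c, q, other) >= -1e-12
                    and cross(q, p, other) >= -1e-12
                ):
                    ok = False
                    break
            if ok:
                tris.append((p, c, q))
                idx.pop(k)
                clipped = True
                break
        if not clipped:
            return None
    tris.append(tuple(idx))
    return tris


def _retriangulate_facets(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Re-triangulate maximal coplanar regions with fewer triangles.

    Vertices that are interior to a planar region, or collinear along a
    straight crease between exactly two regions, are dropped; each region's
    outer boundary is then ear-clipped.  Regions with holes or irregular
    boundaries are left untouched.  The caller validates volume and
    watertightness and rolls back on any change.
    """
    facets = _coplanar_facets(mesh)
    faces = mesh.faces
    verts = mesh.vertices

    facet_of_face = np.empty(len(faces), dtype=int)
    for fi, fset in enumerate(facets):
        facet_of_face[fset] = fi

    # facets incident to each vertex
    v_facets: dict[int, set[int]] = {}
    for face_i, f in enumerate(faces):
        for v in f:
            v_facets.setdefault(int(v), set()).add(int(facet_of_face[face_i]))

    loops_per_facet: dict[int, list[list[int]]] = {}
    processable = np.zeros(len(facets), dtype=bool)
    for fi, fset in enumerate(facets):
        if len(fset) == 1:
            continue
        loops = _boundary_loops(fset, faces)
        if loops is not None and len(loops) == 1:
            loops_per_facet[fi] = loops
            processable[fi] = True

    # A vertex may be dropped iff every incident facet is processable and
    # it is collinear with its neighbours on every boundary loop it sits on
    # (interior vertices of a facet appear on no loop of that facet).
    on_loop: dict[int, list[tuple[int, int, int]]] = {}  # vertex -> (facet, prev, next)
    loop_members: dict[int, set[int]] = {}
    for fi, loops in loops_per_facet.items():
        loop = loops[0]
        loop_members[fi] = set(loop)
        m = len(loop)
        for k, v in enumerate(loop):
            on_loop.setdefault(v, []).append((fi, loop[k - 1], loop[(k + 1) % m]))

    def collinear(p, c, q) -> bool:
        u = verts[c] - verts[p]
        w = verts[q] - verts[c]
        return float(np.linalg.norm(np.cross(u, w))) < 1e-9 * max(
            1.0, float(np.linalg.norm(u)) * float(np.linalg.norm(w))
        )

    drop = set()
    for v, fset in v_facets.items():
        if not all(processable[fi] for fi in fset):
            continue
        entries = on_loop.get(v, [])
        if all(collinear(p, v, q) for (_, p, q) in entries):
            drop.add(v)

    new_faces: list[tuple[int, int, int]] = []
    for fi, fset in enumerate(facets):
        if not processable[fi]:
            new_faces.extend(map(tuple, faces[fset]))
            continue
        loop = [v for v in loops_per_facet[fi][0] if v not in drop]
        if len(loop) < 3:
            new_faces.extend(map(tuple, faces[fset]))
            continue
        normal = mesh.face_normals[fset[0]]
        # 2D basis in the facet plane
        a = np.cross(normal, [1.0, 0.0, 0.0])
        if np.linalg.norm(a) < 1e-6:
            a = np.cross(normal, [0.0, 1.0, 0.0])
        a /= np.linalg.norm(a)
        b = np.cross(normal, a)
        pts2 = np.column_stack([verts[loop] @ a, verts[loop] @ b])
        # orient CCW in the (a, b) frame
        area2 = np.sum(pts2[:, 0] * np.roll(pts2[:, 1], -1) - np.roll(pts2[:, 0], -1) * pts2[:, 1])
        if area2 < 0:
            loop = loop[::-1]
            pts2 = pts2[::-1]
        tris = _ear_clip(pts2)
        if tris is None:
            new_faces.extend(map(tuple, faces[fset]))
            continue
        for t in tris:
            tri = (loop[t[0]], loop[t[1]], loop[t[2]])
            # restore outward orientation
            e1 = verts[tri[1]] - verts[tri[0]]
            e2 = verts[tri[2]] - verts[tri[0]]
            if np.dot(np.cross(e1, e2), normal) < 0:
                tri = (tri[0], tri[2], tri[1])
            new_faces.append(tri)

    out = trimesh.Trimesh(vertices=verts.copy(), faces=np.asarray(new_faces), process=False)
    out.remove_unreferenced_vertices()
    return out


def clean_mesh(mesh: trimesh.Trimesh, merge_tolerance: float = 1e-6) -> trimesh.Trimesh:
    """Merge duplicates, drop degenerate faces, decimate coplanar regions.

    Every sub-step is validated: if merging vertices or re-triangulating
    would break strict watertightness or change the enclosed volume by more
    than 1e-6 relative, that step is skipped with a warning (this protects
    e.g. checkerboard apertures whose diagonal contacts rely on coincident
    but distinct vertices).
    """
    was_watertight = _edge_count_watertight(mesh)
    ref_volume = float(mesh.volume)
    current = mesh.copy()

    # 1. merge duplicate vertices within tolerance
    trial = current.copy()
    trial.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=max(
        0, int(round(-np.log10(max(merge_tolerance, 1e-12))))
    ))
    if was_watertight and not _edge_count_watertight(trial):
        warnings.warn("vertex merge would break watertightness; skipped")
    else:
        current = trial

    # 2. drop zero-area faces
    trial = current.copy()
    areas = trial.area_faces
    trial.update_faces(areas > 1e-12)
    trial.remove_unreferenced_vertices()
    if was_watertight and not _edge_count_watertight(trial):
        warnings.warn("degenerate-face removal would break watertightness; skipped")
    else:
        current = trial

    # 3. zero-deformation coplanar decimation
    if _edge_count_watertight(current):
        trial = _retriangulate_facets(current)
        vol_ok = abs(float(trial.volume) - ref_volume) <= 1e-6 * max(abs(ref_volume), 1e-12)
        if _edge_count_watertight(trial) and vol_ok and len(trial.faces) <= len(current.faces):
            current = trial
        else:
            warnings.warn("coplanar decimation rejected (volume or topology changed)")

    return current


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------


def write_stl(mesh: trimesh.Trimesh, destination, format: str = "binary") -> None:
    """Serialize a mesh as STL (``binary`` or ``ascii``), units mm.

    Binary files follow the standard layout: 80-byte header, little-endian
    uint32 triangle count, then 50 bytes per triangle.
    """
    if format not in ("binary", "ascii"):
        raise DomainError(f"unknown STL format {format!r}")
    if format == "binary":
        data = trimesh.exchange.stl.export_stl(mesh)
        # stamp the unit convention into the spare header bytes
        note = STL_UNIT_NOTE.encode()[:80]
        data = note + b"\0" * (80 - len(note)) + data[80:]
    else:
        data = trimesh.exchange.stl.export_stl_ascii(mesh).encode()
    mode = "wb"
    with open(destination, mode) as fh:
        fh.write(data)


def read_stl(source) -> trimesh.Trimesh:
    """Load an STL file (either flavour) without destructive processing."""
    mesh = trimesh.load(source, file_type="stl", process=False)
    return mesh
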