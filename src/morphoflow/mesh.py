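"""Planar polygonal cell meshes and topological surgery.

The mesh is the geometric substrate of all morphometrics: cells are simple,
positively oriented polygons sharing tricellular vertices, with a symmetric
neighbor adjacency.  Axis convention throughout: x is the proximal-distal
(PD) axis, y the anterior-posterior (AP) axis.

Two kinds of mesh exist in practice:

* *topological* meshes carry per-cell vertex loops (``loops`` is set) and
  support surgery (T1 neighbor exchanges, T2 extrusions, rosette merges);
* *measured* meshes, reconstructed from label images, carry centroids,
  adjacency and tricellular-vertex incidence but no polygon loops — enough
  for triangulation-based elongation measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon


__all__ = [
    "CellMesh",
    "make_cell_mesh",
    "apply_pure_shear",
    "apply_t1",
    "remove_cell",
    "merge_vertices",
    "t1_candidate_edges",
]


def _polygon_area_centroid(pts: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed shoelace area and area centroid of a closed polygon (N,2)."""
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-300:
        return 0.0, pts.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return float(a), np.array([cx, cy])


@dataclass
class CellMesh:
    """A planar cell packing at one time point.

    Parameters
    ----------
    cell_ids : (C,) int array of persistent cell identifiers.
    centroids : (C,2) float array, polygon area centroids.
    vertex_positions : (V,2) float array of (tricellular) vertex positions.
    vertex_cells : per-vertex frozenset of incident cell ids.
    vertex_interior : (V,) bool; True when the vertex touches no tissue
        boundary edge (triangles are only built at interior vertices).
    adjacency : set of ``(a, b)`` tuples with ``a < b``.
    loops : per-cell CCW vertex-index loops, or None for measured meshes.
    frame_time : hours APF (or unitless for static meshes).
    """

    cell_ids: np.ndarray
    centroids: np.ndarray
    vertex_positions: np.ndarray
    vertex_cells: list[frozenset]
    vertex_interior: np.ndarray
    adjacency: set[tuple[int, int]]
    loops: list[list[int]] | None = None
    frame_time: float = 0.0
    _areas: np.ndarray | None = field(default=None, repr=False, compare=False)

    # ------------------------------------------------------------------
    @classmethod
    def from_loops(
        cls,
        cell_ids,
        loops: list[list[int]],
        vertex_positions: np.ndarray,
        frame_time: float = 0.0,
    ) -> "CellMesh":
        """Build a topological mesh; derives centroids, adjacency, incidence.

        Loops are re-oriented CCW (positive area) if needed.
        """
        cell_ids = np.asarray(cell_ids, dtype=np.int64)
        vertex_positions = np.asarray(vertex_positions, dtype=float)
        n_v = len(vertex_positions)
        centroids = np.empty((len(cell_ids), 2))
        areas = np.empty(len(cell_ids))
        oriented: list[list[int]] = []
        edge_cells: dict[tuple[int, int], list[int]] = {}
        vcells: list[set] = [set() for _ in range(n_v)]
        for i, (cid, loop) in enumerate(zip(cell_ids, loops)):
            pts = vertex_positions[loop]
            a, c = _polygon_area_centroid(pts)
            if a < 0:
                loop = loop[::-1]
                a = -a
            if a <= 0:
                raise ValueError(f"cell {cid} has non-positive area")
            oriented.append(list(loop))
            centroids[i] = c
            areas[i] = a
            for k in range(len(loop)):
                u, v = loop[k], loop[(k + 1) % len(loop)]
                edge_cells.setdefault((min(u, v), max(u, v)), []).append(int(cid))
                vcells[u].add(int(cid))
        adjacency: set[tuple[int, int]] = set()
        boundary_vertex = np.zeros(n_v, dtype=bool)
        for (u, v), cs in edge_cells.items():
            if len(cs) == 2:
                a_, b_ = sorted(cs)
                if a_ != b_:
                    adjacency.add((a_, b_))
            elif len(cs) == 1:
                boundary_vertex[u] = True
                boundary_vertex[v] = True
            else:  # >2 cells on one edge: non-manifold
                raise ValueError("non-manifold edge shared by >2 cells")
        used = np.array([len(s) > 0 for s in vcells])
        interior = used & ~boundary_vertex
        return cls(
            cell_ids=cell_ids,
            centroids=centroids,
            vertex_positions=vertex_positions,
            vertex_cells=[frozenset(s) for s in vcells],
            vertex_interior=interior,
            adjacency=adjacency,
            loops=oriented,
            frame_time=frame_time,
            _areas=areas,
        )

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def polygons(self) -> list[np.ndarray]:
        """Per-cell polygon coordinates (CCW). Requires loops."""
        if self.loops is None:
            raise ValueError("mesh has no polygon loops (measured mesh)")
        return [self.vertex_positions[l] for l in self.loops]

    def areas(self) -> np.ndarray:
        if self._areas is not None:
            return self._areas
        if self.loops is None:
            raise ValueError("mesh has no polygon loops (measured mesh)")
        ar = np.array([_polygon_area_centroid(p)[0] for p in self.polygons()])
        self._areas = ar
        return ar

    def total_area(self) -> float:
        return float(self.areas().sum())

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) over all mesh coordinates."""
        pts = self.vertex_positions if self.loops is not None else self.centroids
        xmin, ymin = pts.min(axis=0)
        xmax, ymax = pts.max(axis=0)
        return float(xmin), float(ymin), float(xmax), float(ymax)

    def index_of(self, cid: int) -> int:
        idx = np.nonzero(self.cell_ids == cid)[0]
        if len(idx) == 0:
            raise KeyError(f"no cell id {cid}")
        return int(idx[0])

    def neighbors(self, cid: int) -> set[int]:
        out = set()
        for a, b in self.adjacency:
            if a == cid:
                out.add(b)
            elif b == cid:
                out.add(a)
        return out

    def clone(self) -> "CellMesh":
        return CellMesh(
            cell_ids=self.cell_ids.copy(),
            centroids=self.centroids.copy(),
            vertex_positions=self.vertex_positions.copy(),
            vertex_cells=list(self.vertex_cells),
            vertex_interior=self.vertex_interior.copy(),
            adjacency=set(self.adjacency),
            loops=None if self.loops is None else [list(l) for l in self.loops],
            frame_time=self.frame_time,
            _areas=None if self._areas is None else self._areas.copy(),
        )

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        for a, b in self.adjacency:
            if a == b:
                raise ValueError("adjacency must be irreflexive")
        if self.loops is not None:
            ar = self.areas()
            if np.any(ar <= 0):
                raise ValueError("non-positive cell area")
            xmin, ymin, xmax, ymax = self.bounds()
            if ar.sum() > (xmax - xmin) * (ymax - ymin) * (1 + 1e-9):
                raise ValueError("cell areas exceed bounding box area")
            for a, b in self.adjacency:
                shared = set(self.loops[self.index_of(a)]) & set(
                    self.loops[self.index_of(b)]
                )
                if not shared:
                    raise ValueError(f"adjacent pair {(a, b)} shares no vertex")


# ----------------------------------------------------------------------
# Generation: perturbed hexagonal Voronoi tessellation
# ----------------------------------------------------------------------

def make_cell_mesh(
    n_cells: int, disorder: float, seed: int, frame_time: float = 0.0
) -> CellMesh:
    """Voronoi tessellation of a jittered hexagonal lattice, clipped to a box.

    At ``disorder=0`` every interior cell is a regular hexagon, so every
    triangle of the centroid triangulation is equilateral (isotropic tissue).
    ``disorder`` scales a uniform per-site jitter up to ~half the lattice
    spacing. Deterministic for fixed ``seed``.
    """
    if n_cells < 4:
        raise ValueError("n_cells must be >= 4")
    if not 0.0 <= disorder <= 1.0:
        raise ValueError("disorder must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nx = int(np.ceil(np.sqrt(n_cells)))
    ny = int(np.ceil(n_cells / nx))
    dy = np.sqrt(3.0) / 2.0
    guard = 3
    rows = np.arange(-guard, ny + guard)
    cols = np.arange(-guard, nx + guard)
    cc, rr = np.meshgrid(cols, rows)
    xs = cc + 0.5 * (np.abs(rr) % 2)
    ys = rr * dy
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    rr_flat, cc_flat = rr.ravel(), cc.ravel()
    # kept cells: first n_cells sites of the core grid in row-major order
    core = (rr_flat >= 0) & (rr_flat < ny) & (cc_flat >= 0) & (cc_flat < nx)
    order = np.lexsort((cc_flat, rr_flat))
    kept_idx = order[core[order]][:n_cells]
    kept_mask = np.zeros(len(pts), dtype=bool)
    kept_mask[kept_idx] = True

    jitter = disorder * 0.49 * rng.uniform(-1.0, 1.0, size=pts.shape)
    pts_j = pts + jitter

    vor = Voronoi(pts_j)

    # re-index only the Voronoi vertices that kept cells use
    vmap: dict[int, int] = {}
    final_pts: list[np.ndarray] = []
    loops: list[list[int]] = []
    for site in kept_idx:
        region = vor.regions[vor.point_region[site]]
        if -1 in region:
            raise RuntimeError("unbounded Voronoi region despite guard ring")
        loop = []
        for vid in region:
            if vid not in vmap:
                vmap[vid] = len(final_pts)
                final_pts.append(vor.vertices[vid])
            loop.append(vmap[vid])
        loops.append(loop)

    mesh = CellMesh.from_loops(
        cell_ids=np.arange(n_cells),
        loops=loops,
        vertex_positions=np.array(final_pts),
        frame_time=frame_time,
    )
    return mesh


# ----------------------------------------------------------------------
# Affine deformation
# ----------------------------------------------------------------------

def apply_pure_shear(mesh: CellMesh, s: float) -> CellMesh:
    """Area-preserving pure shear: (x, y) -> (x e^s, y e^-s).

    Topology is untouched; the map has unit determinant so every polygon
    area (and the tissue area) is exactly conserved.
    """
    scale = np.array([np.exp(s), np.exp(-s)])
    out = mesh.clone()
    out.vertex_positions = out.vertex_positions * scale
    out.centroids = out.centroids * scale  # affine maps commute with centroids
    return out


# ----------------------------------------------------------------------
# Topological surgery
# ----------------------------------------------------------------------

def _edge_map(mesh: CellMesh) -> dict[tuple[int, int], list[int]]:
    """Undirected vertex-pair edge -> list of incident cell *indices*."""
    emap: dict[tuple[int, int], list[int]] = {}
    for i, loop in enumerate(mesh.loops):
        for k in range(len(loop)):
            u, v = loop[k], loop[(k + 1) % len(loop)]
            emap.setdefault((min(u, v), max(u, v)), []).append(i)
    return emap


def t1_candidate_edges(mesh: CellMesh) -> list[tuple[int, int]]:
    """Interior edges eligible for a T1 swap.

    Both endpoints must be interior threefold vertices, the quartet
    (two edge cells + two flanking cells) must be four distinct cells,
    and the flanking pair must not already be adjacent.
    """
    emap = _edge_map(mesh)
    vcells = mesh.vertex_cells
    out = []
    for (u, v), cs in emap.items():
        if len(cs) != 2:
            continue
        if not (mesh.vertex_interior[u] and mesh.vertex_interior[v]):
            continue
        if len(vcells[u]) != 3 or len(vcells[v]) != 3:
            continue
        c1 = int(mesh.cell_ids[cs[0]])
        c2 = int(mesh.cell_ids[cs[1]])
        a_set = vcells[u] - {c1, c2}
        b_set = vcells[v] - {c1, c2}
        if len(a_set) != 1 or len(b_set) != 1:
            continue
        a, b = next(iter(a_set)), next(iter(b_set))
        if a == b:
            continue
        if (min(a, b), max(a, b)) in mesh.adjacency:
            continue
        out.append((u, v))
    return sorted(out)


def _insert_after(loop: list[int], anchor: int, new: int) -> list[int]:
    i = loop.index(anchor)
    return loop[: i + 1] + [new] + loop[i + 1 :]


def _insert_before(loop: list[int], anchor: int, new: int) -> list[int]:
    i = loop.index(anchor)
    return loop[:i] + [new] + loop[i:]


def apply_t1(mesh: CellMesh, edge: tuple[int, int]) -> CellMesh:
    """T1 neighbor exchange on the edge (v1, v2).

    The shared contact of cells (C, D) is collapsed to its midpoint and
    re-opened, perpendicular to the old edge and at the pre-collapse
    length, between the flanking cells (A, B) of the quartet.  Vertex
    indices are reused: v1 becomes the {A,B,C} vertex, v2 the {A,B,D}
    vertex.  Returns a new mesh; raises ValueError for ineligible edges
    or if the surgery would create an invalid polygon.
    """
    v1, v2 = edge
    vcells = mesh.vertex_cells
    if len(vcells[v1]) != 3 or len(vcells[v2]) != 3:
        raise ValueError("T1 requires threefold endpoints")
    shared = vcells[v1] & vcells[v2]
    if len(shared) != 2:
        raise ValueError("edge is not shared by exactly two cells")
    c_id, d_id = sorted(shared)
    a_set = vcells[v1] - shared
    b_set = vcells[v2] - shared
    if len(a_set) != 1 or len(b_set) != 1:
        raise ValueError("edge endpoints lack flanking cells")
    a_id, b_id = next(iter(a_set)), next(iter(b_set))
    if a_id == b_id:
        raise ValueError("degenerate quartet")

    out = mesh.clone()
    p1, p2 = out.vertex_positions[v1], out.vertex_positions[v2]
    mid = 0.5 * (p1 + p2)
    ell = float(np.hypot(*(p2 - p1)))
    t = (p2 - p1) / max(ell, 1e-300)
    n = np.array([-t[1], t[0]])
    c_cent = out.centroids[out.index_of(c_id)]
    if np.dot(c_cent - mid, n) < 0:
        n = -n
    # v1 sits on C's side, v2 on D's side, separated by the old edge length
    out.vertex_positions[v1] = mid + 0.5 * ell * n
    out.vertex_positions[v2] = mid - 0.5 * ell * n

    ic, id_, ia, ib = (out.index_of(x) for x in (c_id, d_id, a_id, b_id))
    loops = out.loops
    loops[ic] = [v for v in loops[ic] if v != v2]
    loops[id_] = [v for v in loops[id_] if v != v1]

    def _choose_insert(ci: int, anchor: int, new: int) -> list[int]:
        for cand in (_insert_after(loops[ci], anchor, new),
                     _insert_before(loops[ci], anchor, new)):
            a, _ = _polygon_area_centroid(out.vertex_positions[cand])
            if a > 0 and Polygon(out.vertex_positions[cand]).is_valid:
                return cand
        raise ValueError("T1 surgery produced an invalid polygon")

    loops[ia] = _choose_insert(ia, v1, v2)
    loops[ib] = _choose_insert(ib, v2, v1)

    rebuilt = CellMesh.from_loops(
        out.cell_ids, loops, out.vertex_positions, frame_time=out.frame_time
    )
    # sanity: the intended adjacency change happened
    if (min(a_id, b_id), max(a_id, b_id)) not in rebuilt.adjacency:
        raise ValueError("T1 failed to create the new contact")
    if (min(c_id, d_id), max(c_id, d_id)) in rebuilt.adjacency:
        raise ValueError("T1 failed to remove the old contact")
    return rebuilt


def remove_cell(mesh: CellMesh, cid: int, residue: float = 0.02) -> CellMesh:
    """T2 extrusion: delete a cell, contracting its footprint to a point.

    The dying cell's vertices stay in the neighbors' loops but are pulled
    to within ``residue`` of the centroid, leaving a vanishing gap rather
    than fusing the neighbors at one high-order vertex (so an extrusion
    never masquerades as a rosette).
    """
    ci = mesh.index_of(cid)
    out = mesh.clone()
    dying = set(out.loops[ci])
    c = out.centroids[ci]
    for v in dying:
        out.vertex_positions[v] = c + residue * (out.vertex_positions[v] - c)
    new_loops = [l for i, l in enumerate(out.loops) if i != ci]
    new_ids = np.array([int(x) for i, x in enumerate(out.cell_ids) if i != ci])
    return CellMesh.from_loops(new_ids, new_loops, out.vertex_positions,
                               frame_time=out.frame_time)


def shrink_cell(mesh: CellMesh, cid: int, factor: float) -> CellMesh:
    """Pull a cell's vertices toward its centroid (pre-extrusion shrinkage)."""
    ci = mesh.index_of(cid)
    out = mesh.clone()
    c = out.centroids[ci]
    for v in set(out.loops[ci]):
        p = out.vertex_positions[v]
        out.vertex_positions[v] = c + factor * (p - c)
    return CellMesh.from_loops(out.cell_ids, out.loops, out.vertex_positions,
                               frame_time=out.frame_time)


def merge_vertices(mesh: CellMesh, keep: int, absorb: int) -> CellMesh:
    """Merge vertex ``absorb`` into ``keep`` (rosette formation).

    Every loop containing both drops ``absorb``; loops containing only
    ``absorb`` have it replaced by ``keep``.  The kept vertex moves to the
    midpoint.  Raises if the vertices do not share an edge.
    """
    emap = _edge_map(mesh)
    if (min(keep, absorb), max(keep, absorb)) not in emap:
        raise ValueError("vertices to merge must share an edge")
    out = mesh.clone()
    out.vertex_positions[keep] = 0.5 * (
        out.vertex_positions[keep] + out.vertex_positions[absorb]
    )
    new_loops = []
    for loop in out.loops:
        if absorb in loop:
            if keep in loop:
                loop = [v for v in loop if v != absorb]
            else:
                loop = [keep if v == absorb else v for v in loop]
        if len(loop) < 3:
            raise ValueError("vertex merge would degenerate a polygon")
        new_loops.append(loop)
    return CellMesh.from_loops(out.cell_ids, new_loops, out.vertex_positions,
                               frame_time=out.frame_time)
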