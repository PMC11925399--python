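"""Closed polygonal cell shells: connectivity, per-cell geometry, volume.

A shell is a closed orientable polygonal 2-manifold whose faces are cells.
Each cell stores an ordered (outward-winding) cycle of vertex indices.
Bonds, cell adjacency and the triangle fan decomposition are derived from
the cell cycles and cached on construction.

Units are dimensionless model units: lengths in units of sqrt(A0), so a
cell at its preferred area has area 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path


class ShellError(ValueError):
    """Raised for invalid or degenerate shell geometry/topology."""


def fast_cross(a, b):
    """Row-wise 3D cross product without np.cross's axis plumbing overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def scatter_add(target, idx, values):
    """target[idx] += values via bincount (much faster than np.add.at)."""
    n = len(target)
    if values.ndim == 1:
        target += np.bincount(idx, weights=values, minlength=n)
        return target
    for k in range(values.shape[1]):
        target[:, k] += np.bincount(idx, weights=values[:, k], minlength=n)
    return target


# ---------------------------------------------------------------------------
# core data structures
# ---------------------------------------------------------------------------


class CellularShell:
    """Closed polygonal surface made of cells sharing vertices and bonds.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex positions.
    cells : sequence of int sequences
        Per-cell ordered cyclic vertex lists.  A consistent outward
        winding is expected (``validate_shell`` checks it).

    Derived attributes (rebuilt whenever connectivity changes):

    - ``bonds`` : (B, 2) int array of vertex pairs, ``bonds[:, 0] < bonds[:, 1]``
    - ``bond_cells`` : (B, 2) int array, the cells sharing each bond
      (second entry is -1 for boundary bonds of non-closed input)
    - ``cell_neighbors`` : list of int arrays, cells sharing a bond with c
    """

    def __init__(self, vertices, cells):
        self.vertices = np.asarray(vertices, dtype=float).copy()
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ShellError("vertices must be an (N, 3) array")
        self.cells = [np.asarray(c, dtype=np.int64) for c in cells]
        for i, c in enumerate(self.cells):
            if len(c) < 3:
                raise ShellError(f"cell {i} has fewer than 3 vertices")
            if len(set(c.tolist())) != len(c):
                raise ShellError(f"cell {i} repeats a vertex")
        self._rebuild_connectivity()

    # -- connectivity -------------------------------------------------------

    def _rebuild_connectivity(self):
        n_cells = len(self.cells)
        # flat cell->vertex arrays for vectorized geometry
        self.cell_sizes = np.array([len(c) for c in self.cells], dtype=np.int64)
        self.cell_ptr = np.concatenate([[0], np.cumsum(self.cell_sizes)])
        flat = np.concatenate(self.cells) if n_cells else np.empty(0, np.int64)
        self.cell_vert_flat = flat
        # fan triangles: (cell, v_a, v_b) with v_b the cyclic successor of v_a
        self.tri_cell = np.repeat(np.arange(n_cells), self.cell_sizes)
        self.tri_a = flat
        nxt = flat.copy()
        prv = flat.copy()
        for c0, c1 in zip(self.cell_ptr[:-1], self.cell_ptr[1:]):
            nxt[c0:c1] = np.roll(flat[c0:c1], -1)
            prv[c0:c1] = np.roll(flat[c0:c1], 1)
        self.tri_b = nxt
        self.tri_prev = prv

        # undirected bonds from the directed cell edges
        lo = np.minimum(flat, nxt)
        hi = np.maximum(flat, nxt)
        keyed = lo * (self.vertices.shape[0] + 1) + hi
        bonds_key, inv, counts = np.unique(keyed, return_inverse=True,
                                           return_counts=True)
        if np.any(counts > 2):
            raise ShellError("a bond is shared by more than 2 cells")
        B = len(bonds_key)
        order = np.argsort(inv, kind="stable")
        bond_cells = np.full((B, 2), -1, dtype=np.int64)
        sorted_inv = inv[order]
        sorted_cells = self.tri_cell[order]
        starts = np.searchsorted(sorted_inv, np.arange(B))
        bond_cells[:, 0] = sorted_cells[starts]
        second = counts == 2
        bond_cells[second, 1] = sorted_cells[starts[second] + 1]
        nv = self.vertices.shape[0] + 1
        bonds = np.column_stack([bonds_key // nv, bonds_key % nv])
        self.bonds = bonds
        self.bond_cells = bond_cells
        self._edge_index = {(int(a), int(b)): i
                            for i, (a, b) in enumerate(bonds)}

        nbrs: list[list[int]] = [[] for _ in range(n_cells)]
        for c0, c1 in bond_cells:
            if c1 >= 0:
                nbrs[c0].append(int(c1))
                nbrs[c1].append(int(c0))
        self.cell_neighbors = [np.array(sorted(set(x)), dtype=np.int64) for x in nbrs]

        # incident cells per vertex
        n_verts = len(self.vertices)
        vorder = np.argsort(flat, kind="stable")
        vstarts = np.searchsorted(flat[vorder], np.arange(n_verts + 1))
        self.vertex_cells = [self.tri_cell[vorder[vstarts[v]:vstarts[v + 1]]]
                             for v in range(n_verts)]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def bond_index(self, a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        return self._edge_index[key]

    def bond_lengths(self) -> np.ndarray:
        d = self.vertices[self.bonds[:, 0]] - self.vertices[self.bonds[:, 1]]
        return np.linalg.norm(d, axis=1)

    def is_closed(self) -> bool:
        return bool(np.all(self.bond_cells[:, 1] >= 0))

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_bonds + self.n_cells

    def copy(self) -> "CellularShell":
        return CellularShell(self.vertices.copy(), [c.copy() for c in self.cells])

    def ordered_vertex_ring(self, v: int) -> np.ndarray:
        """Cells incident to vertex ``v`` in cyclic order around it.

        The order follows each cell's winding: inside cell c the vertex v
        is preceded by some vertex p; the bond (p, v) leads to the next
        cell in the ring.  On a closed consistently wound shell this
        traverses every incident cell exactly once.
        """
        inc = self.vertex_cells[v]
        if len(inc) == 0:
            raise ShellError(f"vertex {v} has no incident cells")
        succ = {}
        for ci in inc:
            cyc = self.cells[ci]
            k = int(np.where(cyc == v)[0][0])
            p = int(cyc[(k - 1) % len(cyc)])
            bi = self.bond_index(p, v)
            c0, c1 = self.bond_cells[bi]
            other = c1 if c0 == ci else c0
            if other < 0:
                raise ShellError(f"vertex {v} touches a boundary bond")
            succ[int(ci)] = int(other)
        ring = [int(inc[0])]
        while True:
            nxt = succ[ring[-1]]
            if nxt == ring[0]:
                break
            if nxt in ring or len(ring) > len(inc):
                raise ShellError(f"inconsistent cell ring at vertex {v}")
            ring.append(nxt)
        if len(ring) != len(inc):
            raise ShellError(f"cell ring at vertex {v} does not close")
        return np.array(ring, dtype=np.int64)


@dataclass
class CellGeometry:
    """Geometry of one cell: center, fan triangles, area, frame."""

    cell_id: int
    center: np.ndarray          # (3,)
    area: float
    perimeter: float
    normal: np.ndarray          # (3,) unit outward
    e1: np.ndarray              # (3,) unit, in tangent plane
    e2: np.ndarray              # (3,) unit, = normal x e1
    tri_areas: np.ndarray       # (m,)
    tri_normals: np.ndarray     # (m, 3) unit


@dataclass
class ShellGeometry:
    """Vectorized geometry for all cells of a shell at a fixed instant."""

    centers: np.ndarray         # (C, 3)
    areas: np.ndarray           # (C,)
    perimeters: np.ndarray      # (C,)
    normals: np.ndarray         # (C, 3) unit
    e1: np.ndarray              # (C, 3)
    e2: np.ndarray              # (C, 3)
    volume: float
    tri_cross: np.ndarray = field(repr=False, default=None)  # (T, 3) raw u x w
    tri_areas: np.ndarray = field(repr=False, default=None)  # (T,)


# ---------------------------------------------------------------------------
# geometry computations
# ---------------------------------------------------------------------------


def _frames_from_normals(normals, ref_e1=None):
    """Orthonormal right-handed tangent frames for given unit normals.

    If ``ref_e1`` is given, each frame's first axis is the projection of the
    reference axis into the tangent plane (used for frame continuity);
    otherwise a fixed global seed axis is used per cell.
    """
    n = np.atleast_2d(normals)
    if ref_e1 is None:
        seed = np.tile(np.array([1.0, 0.0, 0.0]), (len(n), 1))
        bad = np.abs(n @ np.array([1.0, 0.0, 0.0])) > 0.9
        seed[bad] = np.array([0.0, 1.0, 0.0])
    else:
        seed = np.atleast_2d(ref_e1)
    e1 = seed - (np.sum(seed * n, axis=1, keepdims=True)) * n
    nrm = np.linalg.norm(e1, axis=1, keepdims=True)
    if np.any(nrm < 1e-12):
        raise ShellError("degenerate tangent frame (reference parallel to normal)")
    e1 = e1 / nrm
    e2 = np.cross(n, e1)
    return e1, e2


def compute_geometry(shell: CellularShell, ref_e1: np.ndarray | None = None) -> ShellGeometry:
    """All per-cell geometric quantities plus the enclosed volume, vectorized."""
    V = shell.vertices
    C = shell.n_cells
    centers = np.zeros((C, 3))
    scatter_add(centers, shell.tri_cell, V[shell.tri_a])
    centers /= shell.cell_sizes[:, None]

    rc = centers[shell.tri_cell]
    u = V[shell.tri_a] - rc
    w = V[shell.tri_b] - rc
    cross = fast_cross(u, w)
    tri_areas = 0.5 * np.sqrt(np.einsum("ij,ij->i", cross, cross))
    areas = np.zeros(C)
    scatter_add(areas, shell.tri_cell, tri_areas)
    if np.any(areas <= 0):
        bad = int(np.argmin(areas))
        raise ShellError(f"degenerate cell {bad}: zero total triangle area")

    # area-weighted mean of unit triangle normals ~ sum of raw cross products
    nsum = np.zeros((C, 3))
    scatter_add(nsum, shell.tri_cell, cross)
    norms = np.linalg.norm(nsum, axis=1, keepdims=True)
    if np.any(norms < 1e-14):
        bad = int(np.argmin(norms.ravel()))
        raise ShellError(f"degenerate cell {bad}: vanishing normal")
    normals = nsum / norms

    edge = V[shell.tri_b] - V[shell.tri_a]
    elen = np.sqrt(np.einsum("ij,ij->i", edge, edge))
    perims = np.zeros(C)
    scatter_add(perims, shell.tri_cell, elen)

    volume = float(np.einsum("ij,ij->", rc, cross) / 6.0)
    e1, e2 = _frames_from_normals(normals, ref_e1)
    return ShellGeometry(centers, areas, perims, normals, e1, e2, volume,
                         tri_cross=cross, tri_areas=tri_areas)


def build_cell_geometry(shell: CellularShell, cell_id: int) -> CellGeometry:
    """Geometry of a single cell: center, fan areas, outward normal, frame.

    The center is the arithmetic mean of the cell's vertices; the area is
    the sum of the fan triangle areas; the normal is the area-weighted mean
    of the fan triangle normals, renormalized.
    """
    cyc = shell.cells[cell_id]
    P = shell.vertices[cyc]
    center = P.mean(axis=0)
    u = P - center
    w = np.roll(P, -1, axis=0) - center
    cross = np.cross(u, w)
    tri_areas = 0.5 * np.linalg.norm(cross, axis=1)
    area = float(tri_areas.sum())
    if area <= 0:
        raise ShellError(f"degenerate cell {cell_id}: zero total triangle area")
    nsum = cross.sum(axis=0)
    nn = np.linalg.norm(nsum)
    if nn < 1e-14:
        raise ShellError(f"degenerate cell {cell_id}: vanishing normal")
    normal = nsum / nn
    with np.errstate(invalid="ignore"):
        tri_normals = np.where(tri_areas[:, None] > 0,
                               cross / (2 * tri_areas[:, None] + 1e-300), 0.0)
    perimeter = float(np.linalg.norm(np.roll(P, -1, axis=0) - P, axis=1).sum())
    e1, e2 = _frames_from_normals(normal[None, :])
    return CellGeometry(cell_id, center, area, perimeter, normal,
                        e1[0], e2[0], tri_areas, tri_normals)


def enclosed_volume(shell: CellularShell) -> float:
    """Signed volume enclosed by the shell (positive for outward winding).

    Computed as a sum of signed tetrahedra from the origin over all fan
    triangles; for a closed surface the result is translation invariant.
    """
    if not shell.is_closed():
        raise ShellError("enclosed_volume requires a closed shell")
    return compute_geometry(shell).volume


def volume_gradient(shell: CellularShell, geom: ShellGeometry | None = None) -> np.ndarray:
    """dV/dR_i per vertex, for the same fan-tetrahedra volume formula."""
    V = shell.vertices
    if geom is None:
        geom = compute_geometry(shell)
    rc = geom.centers[shell.tri_cell]
    ra = V[shell.tri_a]
    rb = V[shell.tri_b]
    G = np.zeros_like(V)
    scatter_add(G, shell.tri_a, fast_cross(rb, rc) / 6.0)
    scatter_add(G, shell.tri_b, fast_cross(rc, ra) / 6.0)
    # center term, distributed over the cell's vertices
    gc = np.zeros((shell.n_cells, 3))
    scatter_add(gc, shell.tri_cell, fast_cross(ra, rb) / 6.0)
    gc /= shell.cell_sizes[:, None]
    scatter_add(G, shell.cell_vert_flat, gc[shell.tri_cell])
    return G


def dihedral_angle(shell: CellularShell, bond) -> float:
    """Angle in [0, pi] between the unit normals of the two cells on a bond."""
    bi = bond if np.isscalar(bond) else shell.bond_index(*bond)
    c0, c1 = shell.bond_cells[bi]
    if c1 < 0:
        raise ShellError(f"bond {bi} is a boundary bond")
    n0 = build_cell_geometry(shell, int(c0)).normal
    n1 = build_cell_geometry(shell, int(c1)).normal
    return float(np.arccos(np.clip(n0 @ n1, -1.0, 1.0)))


def graph_distances(shell: CellularShell, source_cells) -> np.ndarray:
    """BFS distance of every cell from the nearest source on the adjacency graph."""
    sources = np.atleast_1d(np.asarray(list(source_cells), dtype=np.int64))
    if sources.size == 0:
        raise ShellError("graph_distances requires at least one source cell")
    C = shell.n_cells
    rows, cols = [], []
    for c0, c1 in shell.bond_cells:
        if c1 >= 0:
            rows += [int(c0), int(c1)]
            cols += [int(c1), int(c0)]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(C, C))
    dist = shortest_path(adj, method="D", unweighted=True, indices=sources)
    d = dist.min(axis=0) if dist.ndim == 2 else dist
    return d.astype(np.int64)


def tangent_project(vector, geometry: CellGeometry) -> np.ndarray:
    """In-plane components of a 3D vector in the cell's tangent frame."""
    v = np.asarray(vector, dtype=float)
    v_t = v - (v @ geometry.normal) * geometry.normal
    return np.array([v_t @ geometry.e1, v_t @ geometry.e2])


@dataclass
class ShellDiagnostics:
    closed: bool
    euler_characteristic: int
    oriented: bool
    volume: float
    messages: list[str]

    @property
    def ok(self) -> bool:
        return self.closed and self.euler_characteristic == 2 \
            and self.oriented and self.volume > 0


def validate_shell(shell: CellularShell, strict: bool = False) -> ShellDiagnostics:
    """Check closure, Euler characteristic, winding consistency, volume sign.

    Winding consistency: each shared bond must be traversed in opposite
    directions by its two cells (so all normals agree on a side).
    """
    msgs = []
    closed = shell.is_closed()
    if not closed:
        n_open = int(np.sum(shell.bond_cells[:, 1] < 0))
        msgs.append(f"{n_open} boundary bond(s): shell is not closed")
    chi = shell.euler_characteristic()
    if chi != 2:
        msgs.append(f"Euler characteristic {chi} != 2")

    # directed-edge orientation check
    directed: dict[tuple[int, int], int] = {}
    oriented = True
    for cyc in shell.cells:
        for a, b in zip(cyc, np.roll(cyc, -1)):
            directed[(int(a), int(b))] = directed.get((int(a), int(b)), 0) + 1
    for (a, b), cnt in directed.items():
        if cnt > 1 or (closed and (b, a) not in directed):
            oriented = False
            msgs.append(f"inconsistent winding at directed edge ({a}, {b})")
            break

    volume = compute_geometry(shell).volume if closed else float("nan")
    if closed and volume <= 0:
        msgs.append(f"non-positive enclosed volume {volume:.3g}")
    diag = ShellDiagnostics(closed, chi, oriented, volume, msgs)
    if strict and not diag.ok:
        raise ShellError("; ".join(msgs) or "invalid shell")
    return diag
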