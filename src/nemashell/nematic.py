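"""Tangent-plane unit nematic field on a cellular shell.

Representation
--------------
Each cell carries a headless orientation (fiber axis) in its own tangent
frame.  We store the doubled-angle pair ``Q = (cos 2psi, sin 2psi)``; the
corresponding 2x2 traceless symmetric tensor is ``[[Q1, Q2], [Q2, -Q1]]``.
The unit-magnitude convention is ``|Q| = 1`` (i.e. Frobenius norm sqrt(2)
of the matrix); all couplings are defined under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from nemashell.shell import CellularShell, ShellGeometry, ShellError, scatter_add

_TWO_PI = 2.0 * np.pi


class NematicError(ValueError):
    pass


@dataclass
class NematicField:
    """Per-cell unit nematic with alignment parameters.

    Attributes
    ----------
    q : (C, 2) float array
        Doubled-angle components (cos 2psi, sin 2psi) in each cell's
        tangent frame; unit norm per row.
    tau_q : float
        Neighbor-alignment timescale (> 0).
    alpha : float
        Morphogen-gradient coupling strength (>= 0).
    singular : (C,) bool array or None
        Cells marked as forced singularities by a generator (informational).
    """

    q: np.ndarray
    tau_q: float = 1.0
    alpha: float = 0.0
    singular: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.tau_q <= 0:
            raise NematicError("tau_q must be positive")
        if self.alpha < 0:
            raise NematicError("alpha must be non-negative")

    @property
    def angles(self) -> np.ndarray:
        """Fiber-axis angle psi in each cell's tangent frame, in [0, pi)."""
        return (0.5 * np.arctan2(self.q[:, 1], self.q[:, 0])) % np.pi

    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.q, axis=1)

    def check_unit(self, tol: float = 1e-6):
        err = np.abs(self.norms() - 1.0).max()
        if err > tol:
            raise NematicError(f"nematic field is not unit-norm (max dev {err:.2e})")

    def copy(self) -> "NematicField":
        return NematicField(self.q.copy(), self.tau_q, self.alpha,
                            None if self.singular is None else self.singular.copy())


def angles_to_q(psi) -> np.ndarray:
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    return np.column_stack([np.cos(2 * psi), np.sin(2 * psi)])


# ---------------------------------------------------------------------------
# minimal-rotation transport
# ---------------------------------------------------------------------------


def minimal_rotation_apply(n0, n1, v):
    """Rotate vector(s) v by the minimal rotation taking unit n0 onto unit n1.

    The rotation axis is n0 x n1.  Raises for antipodal normals, where the
    minimal rotation is undefined.  All arguments broadcast along axis 0.
    """
    n0 = np.atleast_2d(np.asarray(n0, float))
    n1 = np.atleast_2d(np.asarray(n1, float))
    v = np.atleast_2d(np.asarray(v, float))
    c = np.sum(n0 * n1, axis=1)
    if np.any(c < -1.0 + 1e-12):
        raise NematicError("antipodal normals: minimal rotation undefined")
    k = np.cross(n0, n1)
    # Rodrigues with sin(theta) k_hat = k and the (1-cos)/sin^2 = 1/(1+cos) form
    kv = np.cross(k, v)
    kdv = np.sum(k * v, axis=1, keepdims=True)
    denom = (1.0 + c)[:, None]
    return v * c[:, None] + kv + k * (kdv / denom)


def transport_nematic(q, frame_old, frame_new):
    """Transport a nematic (doubled-angle pair) between tangent frames.

    ``frame_old``/``frame_new`` are (e1, e2, n) triples of unit 3-vectors.
    The director is rotated by the minimal rotation taking the old normal
    onto the new one, then re-expressed in the new frame.  Norm-preserving.
    """
    e1o, e2o, no = (np.asarray(a, float) for a in frame_old)
    e1n, e2n, nn = (np.asarray(a, float) for a in frame_new)
    q = np.asarray(q, float)
    single = q.ndim == 1
    q2 = np.atleast_2d(q)
    psi = 0.5 * np.arctan2(q2[:, 1], q2[:, 0])
    d = np.cos(psi)[:, None] * np.atleast_2d(e1o) + np.sin(psi)[:, None] * np.atleast_2d(e2o)
    d_new = minimal_rotation_apply(np.atleast_2d(no), np.atleast_2d(nn), d)
    a = np.sum(d_new * np.atleast_2d(e1n), axis=1)
    b = np.sum(d_new * np.atleast_2d(e2n), axis=1)
    psi_new = np.arctan2(b, a)
    norm = np.linalg.norm(q2, axis=1)
    out = np.column_stack([np.cos(2 * psi_new), np.sin(2 * psi_new)]) * norm[:, None]
    return out[0] if single else out


def transport_frames(old_normals, old_e1, new_normals, tolerant: bool = False):
    """Update tangent frames after the surface moved (minimal rotation).

    Returns (e1, e2) orthonormalized against the new normals.  Keeping the
    nematic components fixed in these transported frames realizes the
    convect-and-corotate rule for the field.  With ``tolerant=True``,
    cells whose normal flipped to (near-)antipodal — possible across a
    topology surgery — get a fresh arbitrary frame instead of an error.
    """
    n0 = np.asarray(old_normals, float)
    n1 = np.asarray(new_normals, float)
    bad = np.sum(n0 * n1, axis=1) < -1.0 + 1e-9
    if np.any(bad):
        if not tolerant:
            raise NematicError("antipodal normals: minimal rotation undefined")
        n0 = n0.copy()
        n0[bad] = n1[bad]
    e1 = minimal_rotation_apply(n0, n1, old_e1)
    e1 = e1 - np.sum(e1 * n1, axis=1, keepdims=True) * n1
    nrm = np.linalg.norm(e1, axis=1, keepdims=True)
    low = nrm[:, 0] < 1e-12
    if np.any(low):
        if not tolerant:
            raise NematicError("degenerate transported frame")
        from nemashell.shell import _frames_from_normals
        f1, _ = _frames_from_normals(n1[low])
        e1[low] = f1
        nrm[low] = 1.0
    e1 = e1 / nrm
    e2 = np.cross(n1, e1)
    return e1, e2


# ---------------------------------------------------------------------------
# neighbor alignment and gradient coupling
# ---------------------------------------------------------------------------


def _bond_transport_angles(shell: CellularShell, geom: ShellGeometry):
    """For each bond (c0, c1): doubled-angle offsets for transporting
    orientations c1->c0 and c0->c1.

    Transporting an orientation with doubled angle ``2psi`` from cell a to
    cell b amounts to ``2psi + off_ab`` in b's frame, because the minimal
    rotation is a frame isometry.  Returns (pairs, off_01, off_10) where
    off_01 transports from pairs[:,1] into pairs[:,0]'s frame.
    """
    inner = shell.bond_cells[:, 1] >= 0
    pairs = shell.bond_cells[inner]
    c0, c1 = pairs[:, 0], pairs[:, 1]

    def offset(src, dst):
        # angle of transported src-e1 in dst frame, and of src frame handedness
        e1t = minimal_rotation_apply(geom.normals[src], geom.normals[dst], geom.e1[src])
        a = np.sum(e1t * geom.e1[dst], axis=1)
        b = np.sum(e1t * geom.e2[dst], axis=1)
        return 2.0 * np.arctan2(b, a)

    return pairs, offset(c1, c0), offset(c0, c1)


def neighbor_average_all(shell: CellularShell, geom: ShellGeometry,
                         field: NematicField) -> np.ndarray:
    """Mean of transported neighbor nematics for every cell (not renormalized)."""
    q = field.q
    theta = np.arctan2(q[:, 1], q[:, 0])  # doubled angle
    mag = np.linalg.norm(q, axis=1)
    pairs, off01, off10 = _bond_transport_angles(shell, geom)
    c0, c1 = pairs[:, 0], pairs[:, 1]
    acc = np.zeros_like(q)
    t01 = theta[c1] + off01
    t10 = theta[c0] + off10
    scatter_add(acc, c0, np.column_stack([mag[c1] * np.cos(t01),
                                          mag[c1] * np.sin(t01)]))
    scatter_add(acc, c1, np.column_stack([mag[c0] * np.cos(t10),
                                          mag[c0] * np.sin(t10)]))
    counts = np.array([len(nb) for nb in shell.cell_neighbors], dtype=float)
    if np.any(counts == 0):
        raise NematicError("isolated cell has no neighbors")
    return acc / counts[:, None]


def neighbor_average(shell: CellularShell, geom: ShellGeometry,
                     field: NematicField, cell: int) -> np.ndarray:
    """Transported-neighbor mean for a single cell (2x2 tensor form)."""
    avg = neighbor_average_all(shell, geom, field)[cell]
    return np.array([[avg[0], avg[1]], [avg[1], -avg[0]]])


def gradient_alignment_tensor(grad) -> np.ndarray:
    """Traceless-symmetric part of the outer product g (x) g, as a pair.

    Returns ``( (gx^2 - gy^2)/2, gx*gy )`` so the matrix form is
    ``[[T1, T2], [T2, -T1]]``; invariant under g -> -g, principal axis
    along g.
    """
    g = np.asarray(grad, float)
    if g.ndim == 1:
        return np.array([0.5 * (g[0] ** 2 - g[1] ** 2), g[0] * g[1]])
    return np.column_stack([0.5 * (g[:, 0] ** 2 - g[:, 1] ** 2), g[:, 0] * g[:, 1]])


def step_nematic(shell: CellularShell, geom: ShellGeometry, field: NematicField,
                 dt: float, gradients: np.ndarray | None = None) -> NematicField:
    """One explicit step of neighbor alignment plus gradient alignment.

    The unconstrained rate is ``<q>_c / tau_q + alpha * T(grad phi_c)``;
    its component orthogonal to q is applied and the result renormalized,
    which realizes the unit-norm multiplier to first order in dt.
    """
    q = field.q
    rate = neighbor_average_all(shell, geom, field) / field.tau_q
    if gradients is not None and field.alpha != 0.0:
        rate = rate + field.alpha * gradient_alignment_tensor(gradients)
    # project orthogonal to q (in the 2-component representation)
    rate = rate - np.sum(rate * q, axis=1, keepdims=True) * q
    # limit the per-step doubled-angle rotation to 0.5 rad (stability guard
    # against very strong gradient coupling; analogous to a local dt cap)
    step = dt * rate
    mag = np.linalg.norm(step, axis=1, keepdims=True)
    cap = 0.5
    step = np.where(mag > cap, step * (cap / np.maximum(mag, 1e-300)), step)
    q_new = q + step
    nrm = np.linalg.norm(q_new, axis=1, keepdims=True)
    dead = nrm[:, 0] < 1e-12
    if np.any(dead):
        q_new[dead] = q[dead]
        nrm[dead] = 1.0
    out = field.copy()
    out.q = q_new / nrm
    return out


# ---------------------------------------------------------------------------
# defect detection
# ---------------------------------------------------------------------------


@dataclass
class Defect:
    cell: int                     # representative cell (cluster's most-shared)
    position: np.ndarray          # mean position of the cluster's vertices
    charge: float                 # half-integer


@dataclass
class DefectSet:
    defects: list[Defect] = dc_field(default_factory=list)

    @property
    def total_charge(self) -> float:
        return float(sum(d.charge for d in self.defects))

    @property
    def charges(self) -> list[float]:
        return sorted((d.charge for d in self.defects), reverse=True)

    def of_charge(self, charge: float, tol: float = 1e-9) -> list[Defect]:
        return [d for d in self.defects if abs(d.charge - charge) < tol]


def _wrap(a):
    return (a + np.pi) % _TWO_PI - np.pi


def vertex_windings(shell: CellularShell, geom: ShellGeometry,
                    field: NematicField) -> np.ndarray:
    """Nematic winding charge of every vertex's cell-ring loop.

    For the ordered ring of cells around a vertex, orientation differences
    are accumulated after minimal-rotation transport between consecutive
    tangent frames; the loop's frame holonomy is added, and the result is
    rounded to the nearest half-integer.
    """
    field.check_unit(1e-6)
    theta = np.arctan2(field.q[:, 1], field.q[:, 0])  # doubled angle, per cell
    charges = np.zeros(shell.n_vertices)
    for v in range(shell.n_vertices):
        ring = shell.ordered_vertex_ring(v)
        k = len(ring)
        # transport offsets between consecutive ring frames
        delta_sum = 0.0
        e = geom.e1[ring[0]].copy()
        for j in range(k):
            a, b = ring[j], ring[(j + 1) % k]
            e_t = minimal_rotation_apply(geom.normals[a][None], geom.normals[b][None],
                                         e[None])[0]
            e_t -= (e_t @ geom.normals[b]) * geom.normals[b]
            e_t /= np.linalg.norm(e_t)
            # doubled-angle frame offset from a's frame to b's frame
            e1t = minimal_rotation_apply(geom.normals[a][None], geom.normals[b][None],
                                         geom.e1[a][None])[0]
            off = 2.0 * np.arctan2(e1t @ geom.e2[b], e1t @ geom.e1[b])
            delta_sum += _wrap(theta[b] - theta[a] - off)
            e = e_t
        # holonomy: doubled angle of the loop-transported axis vs the start frame
        hol = 2.0 * np.arctan2(e @ geom.e2[ring[0]], e @ geom.e1[ring[0]])
        total = delta_sum + _wrap(hol)
        charges[v] = np.round(total / _TWO_PI) / 2.0  # total / (4 pi), half-integers
    return charges


def detect_defects(shell: CellularShell, geom: ShellGeometry,
                   field: NematicField, merge_radius_cells: int = 1) -> DefectSet:
    """Locate nematic defects and their half-integer charges.

    Vertices with nonzero ring winding are clustered (vertices sharing an
    incident cell are merged) and cluster charges are summed; a +1 aster
    centred on a cell is thus reported as a single +1 defect.  On a closed
    genus-0 shell the total charge is +2.
    """
    w = vertex_windings(shell, geom, field)
    hot = np.where(np.abs(w) > 0.25)[0]
    if len(hot) == 0:
        return DefectSet([])
    # union-find over defective vertices sharing an incident cell
    parent = {int(v): int(v) for v in hot}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cell_to_hot: dict[int, list[int]] = {}
    for v in hot:
        for c in shell.vertex_cells[int(v)]:
            cell_to_hot.setdefault(int(c), []).append(int(v))
    for verts in cell_to_hot.values():
        for v in verts[1:]:
            ra, rb = find(verts[0]), find(v)
            if ra != rb:
                parent[rb] = ra
    clusters: dict[int, list[int]] = {}
    for v in hot:
        clusters.setdefault(find(int(v)), []).append(int(v))

    defects = []
    for verts in clusters.values():
        charge = float(np.sum(w[verts]))
        if abs(charge) < 0.25:
            continue
        counts: dict[int, int] = {}
        for v in verts:
            for c in shell.vertex_cells[v]:
                counts[int(c)] = counts.get(int(c), 0) + 1
        rep = max(sorted(counts), key=lambda c: counts[c])
        pos = shell.vertices[verts].mean(axis=0)
        defects.append(Defect(rep, pos, charge))
    return DefectSet(defects)
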