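"""Vertex-model energetics and constrained overdamped dynamics.

Energy (model units: lengths in sqrt(A0), energies in K*A0^2):

    E = sum_c K/2 (A_c - A0)^2  +  sum_b Lambda L_b
      + sum_c Gamma/2 P_c^2     +  sum_b beta/2 theta_b^2

The lumen volume enters the dynamics (not E) through a Lagrange
multiplier: forces are projected orthogonal to the volume gradient each
step and a uniform rescaling about the centroid removes residual drift.

Active stress: each cell carries a traceless in-plane stress zeta * q_c.
Vertex forces derive from the virtual work of the quadratic form
``E_act = zeta/2 sum_c sum_k u_k^T Q3_c u_k`` (u_k vertex offsets from the
cell center, Q3_c the 3D extension of q_c in the cell frame), evaluated at
frozen stress.  With zeta > 0 a cell contracts along its fiber axis and
extends transversally; the stress is traceless so cell area is unchanged
to first order.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import minimize

from nemashell.shell import (
    CellularShell,
    fast_cross,
    scatter_add,
    ShellError,
    ShellGeometry,
    compute_geometry,
    volume_gradient,
)
from nemashell.nematic import NematicField, transport_frames


@dataclass
class MechanicsParams:
    K: float = 1.0            # area elastic modulus
    A0: float = 1.0           # preferred cell area
    Lambda: float = -0.05     # bond tension (negative: preferred perimeter > 0)
    Gamma: float = 0.15       # perimeter elastic modulus; with Lambda above
                              # the network's 2D Poisson ratio is negative
    beta: float = 0.3         # cell-cell bending modulus
    gamma: float = 1.0        # friction coefficient
    dt: float = 0.05          # time step
    L_th: float = 0.02        # bond-collapse threshold length

    def __post_init__(self):
        for name in ("K", "A0", "Gamma", "beta", "gamma", "dt", "L_th"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.L_th >= np.sqrt(self.A0):
            raise ValueError("L_th must be small compared to sqrt(A0)")

    @property
    def dt_stable(self) -> float:
        """Empirical explicit-Euler stability bound."""
        return 0.1 * self.gamma / (self.K * self.A0 + self.Gamma + self.beta / self.A0)


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------


def _bend_terms(shell: CellularShell, geom: ShellGeometry):
    """Unit normals dotted across every interior bond -> (pairs, cos, theta)."""
    inner = shell.bond_cells[:, 1] >= 0
    pairs = shell.bond_cells[inner]
    c = np.clip(np.sum(geom.normals[pairs[:, 0]] * geom.normals[pairs[:, 1]], axis=1),
                -1.0, 1.0)
    return pairs, c, np.arccos(c)


def elastic_energy(shell: CellularShell, params: MechanicsParams,
                   geom: ShellGeometry | None = None) -> float:
    if geom is None:
        geom = compute_geometry(shell)
    E = 0.5 * params.K * np.sum((geom.areas - params.A0) ** 2)
    E += params.Lambda * np.sum(shell.bond_lengths())
    E += 0.5 * params.Gamma * np.sum(geom.perimeters ** 2)
    if params.beta != 0.0 and shell.is_closed():
        _, _, theta = _bend_terms(shell, geom)
        E += 0.5 * params.beta * np.sum(theta ** 2)
    return float(E)


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------


def elastic_forces(shell: CellularShell, params: MechanicsParams,
                   geom: ShellGeometry | None = None) -> np.ndarray:
    """-dE/dR_i for every vertex (analytic, matches an FD gradient to ~1e-6)."""
    if geom is None:
        geom = compute_geometry(shell)
    V = shell.vertices
    F = np.zeros_like(V)
    tc, ta, tb = shell.tri_cell, shell.tri_a, shell.tri_b
    rc = geom.centers[tc]
    ra, rb = V[ta], V[tb]
    cross = geom.tri_cross
    nrm = np.linalg.norm(cross, axis=1, keepdims=True)
    m = cross / np.maximum(nrm, 1e-300)

    # area term: dE = K (A_c - A0) dA_c
    coefA = (params.K * (geom.areas - params.A0))[tc][:, None]
    gA_a = 0.5 * fast_cross(rb - rc, m)
    gA_b = 0.5 * fast_cross(rc - ra, m)
    gA_c = 0.5 * fast_cross(ra - rb, m)
    scatter_add(F, ta, -coefA * gA_a)
    scatter_add(F, tb, -coefA * gA_b)
    gc = np.zeros((shell.n_cells, 3))
    scatter_add(gc, tc, -coefA * gA_c)
    gc /= shell.cell_sizes[:, None]
    scatter_add(F, shell.cell_vert_flat, gc[tc])

    # perimeter + bond tension: per directed cell edge (a -> b)
    edge = rb - ra
    elen = np.sqrt(np.einsum("ij,ij->i", edge, edge))[:, None]
    that = edge / np.maximum(elen, 1e-300)
    coefP = (params.Gamma * geom.perimeters)[tc][:, None]
    scatter_add(F, ta, coefP * that)
    scatter_add(F, tb, -coefP * that)
    if params.Lambda != 0.0:
        b0, b1 = shell.bonds[:, 0], shell.bonds[:, 1]
        dbond = V[b1] - V[b0]
        tb_hat = dbond / np.maximum(np.linalg.norm(dbond, axis=1, keepdims=True), 1e-300)
        scatter_add(F, b0, params.Lambda * tb_hat)
        scatter_add(F, b1, -params.Lambda * tb_hat)

    # bending: dE = -sum_b k_b d(n_c0 . n_c1), through the raw cell normals
    if params.beta != 0.0 and shell.is_closed():
        pairs, cth, theta = _bend_terms(shell, geom)
        sth = np.sqrt(np.maximum(1.0 - cth ** 2, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            k_b = np.where(sth > 1e-8, params.beta * theta / np.maximum(sth, 1e-300),
                           params.beta)
        # raw (unnormalized) cell normal lengths |N_c|
        nraw = np.zeros((shell.n_cells, 3))
        scatter_add(nraw, tc, cross)
        Nlen = np.linalg.norm(nraw, axis=1)
        n0, n1 = pairs[:, 0], pairs[:, 1]
        a0 = (geom.normals[n1] - cth[:, None] * geom.normals[n0]) / Nlen[n0][:, None]
        a1 = (geom.normals[n0] - cth[:, None] * geom.normals[n1]) / Nlen[n1][:, None]
        S = np.zeros((shell.n_cells, 3))
        scatter_add(S, n0, k_b[:, None] * a0)
        scatter_add(S, n1, k_b[:, None] * a1)
        # dN_c = sum_k dR_k x (R_next - R_prev); force on k is  e_k x S_c
        e_k = V[shell.tri_b] - V[shell.tri_prev]
        scatter_add(F, ta, fast_cross(e_k, S[tc]))
    return F


def active_forces(shell: CellularShell, geom: ShellGeometry,
                  field: NematicField, zeta: float) -> np.ndarray:
    """Vertex forces from per-cell traceless active stress zeta * q_c."""
    field.check_unit(1e-6)
    if zeta == 0.0:
        return np.zeros_like(shell.vertices)
    tc, ta = shell.tri_cell, shell.tri_a
    u = shell.vertices[ta] - geom.centers[tc]
    a = np.sum(u * geom.e1[tc], axis=1)
    b = np.sum(u * geom.e2[tc], axis=1)
    Q1, Q2 = field.q[tc, 0], field.q[tc, 1]
    f_in1 = Q1 * a + Q2 * b
    f_in2 = Q2 * a - Q1 * b
    f = -zeta * (f_in1[:, None] * geom.e1[tc] + f_in2[:, None] * geom.e2[tc])
    F = np.zeros_like(shell.vertices)
    scatter_add(F, ta, f)
    return F


def volume_constrained_forces(shell: CellularShell, forces: np.ndarray,
                              geom: ShellGeometry | None = None):
    """Project forces orthogonal to the volume gradient.

    Returns (projected forces, mu) with mu = (F.G)/(G.G); the projected
    forces satisfy sum_i F'_i . G_i = 0, i.e. instantaneous dV/dt = 0.
    """
    G = volume_gradient(shell, geom)
    gg = float(np.sum(G * G))
    if gg < 1e-30:
        raise ShellError("degenerate volume gradient")
    mu = float(np.sum(forces * G) / gg)
    return forces - mu * G, mu


# ---------------------------------------------------------------------------
# state and stepping
# ---------------------------------------------------------------------------


@dataclass
class MechanicsState:
    shell: CellularShell
    params: MechanicsParams
    geom: ShellGeometry = None
    V0: float = None
    mu: float = 0.0
    zeta: float = 0.0
    time: float = 0.0
    n_clamped: int = 0
    t1_log: list = dc_field(default_factory=list)

    def __post_init__(self):
        if self.geom is None:
            self.geom = compute_geometry(self.shell)
        if self.V0 is None:
            self.V0 = self.geom.volume

    def refresh_geometry(self, old_vertices: np.ndarray | None = None):
        """Recompute geometry, transporting tangent frames (co-rotation).

        The frames follow the minimal rotation of each cell normal plus,
        when the previous vertex positions are supplied, the in-plane spin
        of the cell (2D Procrustes rotation of the vertex offsets), so the
        nematic is fully convected and co-rotated with the cell.
        """
        old_geom = self.geom
        geom = compute_geometry(self.shell)
        e1, e2 = transport_frames(old_geom.normals, old_geom.e1, geom.normals)
        if old_vertices is not None:
            from nemashell.nematic import minimal_rotation_apply

            sh = self.shell
            tc, ta = sh.tri_cell, sh.tri_a
            u_old = old_vertices[ta] - old_geom.centers[tc]
            # carry the old offsets into the new tangent plane first
            u_old = minimal_rotation_apply(old_geom.normals[tc],
                                           geom.normals[tc], u_old)
            u_new = sh.vertices[ta] - geom.centers[tc]
            ao1 = np.einsum("ij,ij->i", u_old, e1[tc])
            ao2 = np.einsum("ij,ij->i", u_old, e2[tc])
            an1 = np.einsum("ij,ij->i", u_new, e1[tc])
            an2 = np.einsum("ij,ij->i", u_new, e2[tc])
            dot = np.zeros(sh.n_cells)
            crs = np.zeros(sh.n_cells)
            scatter_add(dot, tc, ao1 * an1 + ao2 * an2)
            scatter_add(crs, tc, ao1 * an2 - ao2 * an1)
            spin = np.arctan2(crs, dot)
            c, s = np.cos(spin)[:, None], np.sin(spin)[:, None]
            e1, e2 = c * e1 + s * e2, -s * e1 + c * e2
        geom.e1, geom.e2 = e1, e2
        self.geom = geom

    def rescale_volume(self):
        """Uniform rescale about the centroid enforcing |V - V0|/V0 <= 1e-10."""
        v = self.geom.volume
        if v <= 0:
            raise ShellError("non-positive volume during rescale")
        s = (self.V0 / v) ** (1.0 / 3.0)
        if abs(s - 1.0) > 1e-15:
            ctr = self.shell.vertices.mean(axis=0)
            self.shell.vertices[:] = ctr + s * (self.shell.vertices - ctr)
            self.refresh_geometry()


def step_dynamics(state: MechanicsState, field: NematicField | None = None,
                  zeta: float = 0.0, dt: float | None = None) -> MechanicsState:
    """One explicit Euler step of the volume-constrained overdamped dynamics."""
    p = state.params
    if dt is None:
        dt = p.dt
    F = elastic_forces(state.shell, p, state.geom)
    if field is not None and zeta != 0.0:
        F = F + active_forces(state.shell, state.geom, field, zeta)
    Fp, mu = volume_constrained_forces(state.shell, F, state.geom)
    disp = (dt / p.gamma) * Fp
    if not np.all(np.isfinite(disp)):
        raise ShellError("non-finite displacement: step-size blowup")
    # cap extreme per-step moves (guards against cell inversion during
    # strongly amplified pulses; direction of the gradient flow preserved)
    max_disp = np.abs(disp).max()
    cap = 0.1 * np.sqrt(p.A0)
    if max_disp > cap:
        disp *= cap / max_disp
    old_vertices = state.shell.vertices.copy()
    state.shell.vertices += disp
    state.refresh_geometry(old_vertices)
    state.rescale_volume()
    state.mu = mu
    state.zeta = zeta
    state.time += dt
    return state


def relax(state: MechanicsState, tol: float = 1e-4, max_steps: int = 5000,
          dt: float | None = None) -> MechanicsState:
    """Gradient-flow relaxation until the max projected force drops below tol."""
    for _ in range(max_steps):
        F = elastic_forces(state.shell, state.params, state.geom)
        Fp, _ = volume_constrained_forces(state.shell, F, state.geom)
        if np.abs(Fp).max() < tol:
            break
        step_dynamics(state, dt=dt)
    return state


def force_residual(state: MechanicsState) -> float:
    F = elastic_forces(state.shell, state.params, state.geom)
    Fp, _ = volume_constrained_forces(state.shell, F, state.geom)
    return float(np.abs(Fp).max())


# ---------------------------------------------------------------------------
# topology changes (bond collapse + multi-fold vertex resolution / T1)
# ---------------------------------------------------------------------------


def _collapse_bond(shell: CellularShell, a: int, b: int) -> CellularShell | None:
    """Merge vertices a and b at their midpoint; None if a cell would degenerate."""
    cells = []
    for cyc in shell.cells:
        new = [a if v == b else int(v) for v in cyc]
        dedup = [new[i] for i in range(len(new)) if new[i] != new[(i - 1) % len(new)]]
        if len(dedup) < 3:
            return None
        if len(set(dedup)) != len(dedup):
            return None
        cells.append(dedup)
    verts = shell.vertices.copy()
    verts[a] = 0.5 * (shell.vertices[a] + shell.vertices[b])
    used = sorted({v for cyc in cells for v in cyc})
    remap = {v: i for i, v in enumerate(used)}
    return CellularShell(verts[used], [[remap[v] for v in cyc] for cyc in cells])


def _split_vertex(shell: CellularShell, v: int, ring: np.ndarray, i: int,
                  sep: float) -> CellularShell | None:
    """Split multi-fold vertex v: ring cell i keeps one child vertex.

    The child w1 keeps the two bonds flanking ring[i]; the other child w2
    (reusing index v) keeps the rest.  The new bond (w1, w2) is shared by
    ring[i-1] and ring[i+1].
    """
    k = len(ring)
    ci = int(ring[i])
    cim = int(ring[(i - 1) % k])
    cip = int(ring[(i + 1) % k])
    centers = np.array([shell.vertices[shell.cells[c]].mean(axis=0)
                        for c in (ci,)])
    d = centers[0] - shell.vertices[v]
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        return None
    d /= nd
    w1 = shell.n_vertices
    verts = np.vstack([shell.vertices, shell.vertices[v] + sep * d])
    verts[v] = verts[v] - sep * d

    cells = []
    for cj, cyc in enumerate(shell.cells):
        cyc = [int(x) for x in cyc]
        if v not in cyc:
            cells.append(cyc)
            continue
        pos = cyc.index(v)
        if cj == ci:
            cyc[pos] = w1
        elif cj == cim:
            # ... pred, v, succ ... -> pred bonds to w1 side
            cyc[pos:pos + 1] = [w1, v]
        elif cj == cip:
            cyc[pos:pos + 1] = [v, w1]
        # other ring cells keep v (w2)
        cells.append(cyc)
    try:
        return CellularShell(verts, cells)
    except ShellError:
        return None


def handle_topology(state: MechanicsState, L_th: float | None = None,
                    probe_multifold: bool = True) -> bool:
    """Collapse short bonds and test multi-fold vertex resolutions (T1 rule).

    Every bond shorter than L_th collapses to a vertex.  Each vertex with
    more than three incident cells is then probed: all topologically
    distinct splits at separation 2*L_th are evaluated and the one with
    the largest energy decrease applied; on a tie (or if none decreases
    the energy) the vertex stays merged.  Returns True if the shell
    changed.  Per-cell fields are untouched (cell indices are preserved).
    """
    p = state.params
    if L_th is None:
        L_th = p.L_th
    changed = False

    # 1. collapse short bonds, one at a time
    while True:
        L = state.shell.bond_lengths()
        short = np.where(L < L_th)[0]
        if len(short) == 0:
            break
        bi = int(short[np.argmin(L[short])])
        a, b = (int(x) for x in state.shell.bonds[bi])
        merged = _collapse_bond(state.shell, a, b)
        if merged is None:
            break  # would degenerate a cell; leave as is
        state.shell = merged
        state.t1_log.append(("collapse", state.time, a, b))
        changed = True

    # 2. resolve multi-fold vertices by energy probing
    resolved = probe_multifold
    while resolved:
        resolved = False
        for v in range(state.shell.n_vertices):
            if len(state.shell.vertex_cells[v]) <= 3:
                continue
            ring = state.shell.ordered_vertex_ring(v)
            k = len(ring)
            E0 = elastic_energy(state.shell, p)
            picks = range(2) if k == 4 else range(k)  # i and i+2 coincide at k=4
            was_closed = state.shell.is_closed()
            cands = []
            for i in picks:
                cand = _split_vertex(state.shell, v, ring, i, L_th)
                if cand is not None and cand.is_closed() == was_closed:
                    cands.append((elastic_energy(cand, p), i, cand))
            if not cands:
                continue
            cands.sort(key=lambda t: t[0])
            tol = 1e-10 * max(1.0, abs(E0))
            best = cands[0]
            tie = len(cands) > 1 and abs(cands[1][0] - best[0]) < tol
            if best[0] < E0 - tol and not tie:
                state.shell = best[2]
                state.t1_log.append(("split", state.time, v, int(ring[best[1]])))
                changed = True
                resolved = True
                break
    if changed:
        old_geom = state.geom
        state.geom = compute_geometry(state.shell)
        # cell count is preserved by both surgeries: transport frames by cell
        state.geom.e1, state.geom.e2 = transport_frames(
            old_geom.normals, old_geom.e1, state.geom.normals, tolerant=True)
    return changed


# ---------------------------------------------------------------------------
# two-dimensional Poisson ratio (periodic honeycomb unit cell)
# ---------------------------------------------------------------------------


def _honeycomb_energy(lx, ly, dvec, params: MechanicsParams, L0: float):
    """Energy per cell of a periodic honeycomb under affine stretch.

    Lattice vectors a1 = (lx*sqrt(3)L0, 0), a2 = (lx*sqrt(3)L0/2,
    ly*1.5*L0); two-point basis with free offset ``dvec``.  Each unit cell
    holds one hexagonal face, three distinct bonds, area |a1 x a2|.
    """
    a1 = np.array([lx * np.sqrt(3) * L0, 0.0])
    a2 = np.array([lx * np.sqrt(3) * L0 / 2.0, ly * 1.5 * L0])
    A_pos = np.zeros(2)
    B_pos = np.asarray(dvec, float)
    # three bonds from B to A images: A, A + a2 - a1, A + a2  (rest geometry)
    bonds = [A_pos - B_pos, A_pos + a2 - a1 - B_pos, A_pos + a2 - B_pos]
    Ls = [np.linalg.norm(b) for b in bonds]
    area = abs(a1[0] * a2[1] - a1[1] * a2[0])
    P = 2.0 * sum(Ls)  # hexagon perimeter: each bond length appears twice
    E = 0.5 * params.K * (area - params.A0) ** 2
    E += params.Lambda * sum(Ls)
    E += 0.5 * params.Gamma * P ** 2
    return E


def measure_poisson_ratio(params: MechanicsParams, strain: float = 1e-2) -> float:
    """2D Poisson ratio of the periodic hexagonal network at rest.

    Finds the stress-free reference (lx = ly = 1 scale factor minimization),
    applies a uniaxial strain eps_xx, relaxes the transverse extent and the
    internal sublattice offset, and returns -eps_yy / eps_xx.
    """
    if strain == 0:
        raise ValueError("strain must be nonzero")
    L0 = np.sqrt(params.A0 / (1.5 * np.sqrt(3)))  # unit hexagon edge at A = A0

    def relax_rest():
        def f(x):
            return _honeycomb_energy(x[0], x[0], x[1:3], params, L0)
        x0 = np.array([1.0, (np.sqrt(3) * L0 / 2 + np.sqrt(3) * L0 / 4),
                       0.75 * L0 / 1.5])
        # basis offset rest position: centroid between the two sublattices
        a1 = np.array([np.sqrt(3) * L0, 0.0])
        a2 = np.array([np.sqrt(3) * L0 / 2.0, 1.5 * L0])
        d0 = (a1 + a2) / 3.0
        x0 = np.array([1.0, d0[0], d0[1]])
        res = minimize(f, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        return res.x

    rest = relax_rest()
    lx0 = rest[0]

    def ly_of_lx(lx):
        def f(x):
            return _honeycomb_energy(lx, x[0], x[1:3], params, L0)
        x0 = np.array([lx0, rest[1], rest[2]])
        res = minimize(f, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        if not np.isfinite(res.fun):
            raise ShellError("honeycomb patch failed to relax")
        return res.x[0]

    ly_plus = ly_of_lx(lx0 * (1 + strain))
    ly_minus = ly_of_lx(lx0 * (1 - strain))
    eps_yy = (ly_plus - ly_minus) / (2 * lx0 * strain)
    return float(-eps_yy)
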