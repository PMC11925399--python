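"""Per-cell morphogen dynamics: diffusion, degradation, strain-gated production.

Molecule counts N_c evolve by

    dN_c/dt = sum_{c'} D L_{cc'} (phi_c' - phi_c)  -  r_minus N_c
              + r_plus f(eps_c)

with phi_c = N_c / A_c the cell concentration, L_cc' the shared bond
length, eps_c = (A_c - A_c0)/A_c0 the cell area strain relative to the
t=0 reference, and f a sharp sigmoid around the strain threshold.
Setting r_plus = 1 expresses N_c in units of r_plus / r_minus.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from nemashell.shell import CellularShell, ShellGeometry, scatter_add


@dataclass
class MorphogenParams:
    D: float = 0.3             # effective inter-cell diffusion coefficient
    r_minus: float = 0.03      # degradation rate (morphogen outlives a pulse period)
    r_plus: float = 1.0        # maximum production rate
    eps_th: float = 0.7        # strain threshold for production
    w: float = 10.0            # sigmoid sharpness
    sigmoid_convention: str = "shifted"  # "shifted" (saturates at r_plus) or "raw"

    def __post_init__(self):
        if self.eps_th <= 0:
            raise ValueError("eps_th must be positive")
        if self.sigmoid_convention not in ("shifted", "raw"):
            raise ValueError("sigmoid_convention must be 'shifted' or 'raw'")

    @property
    def tau_minus(self) -> float:
        return 1.0 / self.r_minus

    @property
    def decay_length(self) -> float:
        """Length a morphogen diffuses before degrading, sqrt(D / r_minus)."""
        return float(np.sqrt(self.D / self.r_minus))


@dataclass
class MorphogenField:
    N: np.ndarray                       # (C,) molecule counts
    A_ref: np.ndarray                   # (C,) reference areas at t = 0
    params: MorphogenParams = dc_field(default_factory=MorphogenParams)
    n_clamped: int = 0                  # negativity clamps applied (should stay 0)

    def __post_init__(self):
        self.N = np.asarray(self.N, dtype=float)
        self.A_ref = np.asarray(self.A_ref, dtype=float)
        if np.any(self.A_ref <= 0):
            raise ValueError("reference areas must be positive")

    def concentrations(self, areas: np.ndarray) -> np.ndarray:
        return self.N / areas

    def copy(self) -> "MorphogenField":
        return MorphogenField(self.N.copy(), self.A_ref.copy(), self.params,
                              self.n_clamped)


def cell_strain(A, A_ref):
    """Area strain (A - A_ref) / A_ref."""
    A_ref = np.asarray(A_ref, dtype=float)
    if np.any(A_ref <= 0):
        raise ValueError("reference area must be positive")
    return (np.asarray(A, dtype=float) - A_ref) / A_ref


def production_rate(eps, params: MorphogenParams):
    """Strain-gated production, r_plus * f(eps).

    The 'shifted' convention f = (1 + tanh(w (eps - eps_th)/eps_th)) / 2 is
    ~0 far below threshold, 1/2 at threshold and saturates to 1 above it;
    'raw' keeps the bare tanh/2 form (negative below threshold, saturating
    at 1/2) for sensitivity checks.
    """
    t = np.tanh(params.w * (np.asarray(eps, dtype=float) - params.eps_th) / params.eps_th)
    if params.sigmoid_convention == "shifted":
        return params.r_plus * 0.5 * (1.0 + t)
    return params.r_plus * 0.5 * t


def _bond_flux_arrays(shell: CellularShell):
    inner = shell.bond_cells[:, 1] >= 0
    pairs = shell.bond_cells[inner]
    L = shell.bond_lengths()[inner]
    return pairs, L


def diffusion_rhs(shell: CellularShell, geom: ShellGeometry,
                  field: MorphogenField) -> np.ndarray:
    """Diffusive part of dN/dt; exactly antisymmetric per bond (conservative)."""
    phi = field.concentrations(geom.areas)
    pairs, L = _bond_flux_arrays(shell)
    c0, c1 = pairs[:, 0], pairs[:, 1]
    flux = field.params.D * L * (phi[c1] - phi[c0])  # into c0
    out = np.zeros(shell.n_cells)
    scatter_add(out, c0, flux)
    scatter_add(out, c1, -flux)
    return out


def gradient_estimate(shell: CellularShell, geom: ShellGeometry, phi: np.ndarray,
                      cell: int | None = None) -> np.ndarray:
    """Tangent-plane least-squares concentration gradient.

    Solves ``phi_c' - phi_c = g . (R_c' - R_c)`` over all neighbors in the
    least-squares sense, with center offsets projected into the cell's
    tangent frame.  Exact for fields linear in the tangent coordinates.
    Returns (C, 2) for all cells, or (2,) for a single cell.
    """
    C = shell.n_cells
    pairs, _ = _bond_flux_arrays(shell)
    c0, c1 = pairs[:, 0], pairs[:, 1]
    # accumulate per-cell normal equations sum(x x^T) g = sum(x y)
    M = np.zeros((C, 2, 2))
    rhs = np.zeros((C, 2))
    for a, b in ((c0, c1), (c1, c0)):
        off = geom.centers[b] - geom.centers[a]
        x1 = np.sum(off * geom.e1[a], axis=1)
        x2 = np.sum(off * geom.e2[a], axis=1)
        y = phi[b] - phi[a]
        scatter_add(M[:, 0], a, np.column_stack([x1 * x1, x1 * x2]))
        scatter_add(M[:, 1], a, np.column_stack([x1 * x2, x2 * x2]))
        scatter_add(rhs, a, np.column_stack([x1 * y, x2 * y]))
    if cell is not None:
        nb = shell.cell_neighbors[cell]
        if len(nb) < 2:
            raise ValueError(f"cell {cell} has fewer than 2 neighbors")
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    scale = np.maximum(M[:, 0, 0] + M[:, 1, 1], 1e-300)
    ok = det > 1e-10 * scale ** 2
    g = np.zeros((C, 2))
    inv = np.where(ok, det, 1.0)
    g[:, 0] = (M[:, 1, 1] * rhs[:, 0] - M[:, 0, 1] * rhs[:, 1]) / inv
    g[:, 1] = (M[:, 0, 0] * rhs[:, 1] - M[:, 1, 0] * rhs[:, 0]) / inv
    if np.any(~ok):
        # degenerate (collinear) neighborhoods: minimum-norm solution
        for c in np.where(~ok)[0]:
            g[c] = np.linalg.lstsq(M[c], rhs[c], rcond=None)[0]
    if cell is not None:
        return g[cell]
    return g


def stable_dt(shell: CellularShell, geom: ShellGeometry,
              params: MorphogenParams) -> float:
    """Explicit-Euler diffusion stability bound 0.2 min(A) / (D max(P))."""
    if params.D == 0:
        return np.inf
    return 0.2 * float(geom.areas.min()) / (params.D * float(geom.perimeters.max()))


def step_morphogen_train(shell: CellularShell, geom: ShellGeometry,
                         field: MorphogenField, dt_total: float,
                         n_sub: int) -> MorphogenField:
    """n_sub explicit Euler substeps at frozen geometry.

    Precomputes the bond flux arrays once, so stiff diffusion (small cells
    during a contraction pulse) costs only the inner vector updates.
    """
    p = field.params
    pairs, L = _bond_flux_arrays(shell)
    c0, c1 = pairs[:, 0], pairs[:, 1]
    DL = p.D * L
    areas = geom.areas
    prod = production_rate(cell_strain(areas, field.A_ref), p)
    dt = dt_total / n_sub
    N = field.N.copy()
    clamped = 0
    for _ in range(n_sub):
        phi = N / areas
        flux = DL * (phi[c1] - phi[c0])
        dN = np.bincount(c0, weights=flux, minlength=len(N))
        dN -= np.bincount(c1, weights=flux, minlength=len(N))
        N += dt * (dN + prod - p.r_minus * N)
        neg = N < 0
        if neg.any():
            clamped += int(neg.sum())
            np.maximum(N, 0.0, out=N)
    out = field.copy()
    out.N = N
    out.n_clamped += clamped
    return out


def step_morphogen(shell: CellularShell, geom: ShellGeometry,
                   field: MorphogenField, dt: float,
                   check_stability: bool = True) -> MorphogenField:
    """One explicit Euler step: diffusion + production - degradation."""
    p = field.params
    if check_stability and dt > stable_dt(shell, geom, p):
        raise ValueError(
            f"dt={dt:g} exceeds the diffusion stability bound "
            f"{stable_dt(shell, geom, p):g}")
    eps = cell_strain(geom.areas, field.A_ref)
    dN = diffusion_rhs(shell, geom, field)
    dN += production_rate(eps, p) - p.r_minus * field.N
    out = field.copy()
    out.N = field.N + dt * dN
    neg = out.N < 0
    if np.any(neg):
        out.n_clamped += int(np.sum(neg))
        out.N = np.maximum(out.N, 0.0)
    return out
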