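"""Deformation quantification: log-strain profiles, event classes, shape tensors.

The per-distance logarithmic area strain is

    mean(ln A_peak) - mean(ln A_before)   over cells at that graph distance,

identically equal to the mean of ln(A_peak / A_before); both orders are
computed and cross-checked.  Cell anisotropy uses the triangle
decomposition: each fan triangle is compared against an area-matched
equilateral reference at fixed orientation, the rotation is removed by a
left polar decomposition and the Hencky (log) strain retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from nemashell.shell import CellGeometry

CORE_MAX_DISTANCE = 3          # core region: <= 3 cells from the focus
INTERMEDIATE_MAX_DISTANCE = 5  # intermediate: 4-5 cells; far: >= 6
LARGE_EVENT_RATIO = 2.0        # 'greater than twofold' area increase


class StrainError(ValueError):
    pass


@dataclass
class StrainProfile:
    """Per-graph-distance logarithmic area strain around a focus."""

    distances: np.ndarray          # (n_d,) sorted unique distances
    mean: np.ndarray               # (n_d,) per-distance mean log strain
    std: np.ndarray                # (n_d,)
    counts: np.ndarray             # (n_d,) cells per distance
    flagged: np.ndarray            # (n_d,) True where < 3 cells support the mean
    core_value: float              # mean log strain at distance <= 1
    max_core_ratio: float          # max per-cell area ratio within the core region
    peak_frame: int | None = None

    def value_at(self, d: int) -> float:
        idx = np.where(self.distances == d)[0]
        return float(self.mean[idx[0]]) if len(idx) else float("nan")

    def region_means(self) -> dict[str, float]:
        """Means over the core (<=3), intermediate (4-5) and far (>=6) regions."""
        out = {}
        sel = {
            "core": self.distances <= CORE_MAX_DISTANCE,
            "intermediate": (self.distances > CORE_MAX_DISTANCE)
            & (self.distances <= INTERMEDIATE_MAX_DISTANCE),
            "far": self.distances > INTERMEDIATE_MAX_DISTANCE,
        }
        for name, mask in sel.items():
            w = self.counts[mask]
            out[name] = float(np.average(self.mean[mask], weights=w)) if w.sum() else float("nan")
        return out

    def decay_distance(self, fraction: float = 0.2) -> int:
        """Smallest distance at which the strain falls below fraction * core."""
        thr = fraction * self.core_value
        for d, v in zip(self.distances, self.mean):
            if v < thr:
                return int(d)
        return int(self.distances[-1]) + 1


def log_area_strain_profile(areas_before, areas_peak, distances) -> StrainProfile:
    """Per-distance mean/std of ln(A_peak / A_before) over matched cells."""
    a0 = np.asarray(areas_before, dtype=float)
    a1 = np.asarray(areas_peak, dtype=float)
    d = np.asarray(distances, dtype=int)
    if not (len(a0) == len(a1) == len(d)):
        raise StrainError("areas_before, areas_peak and distances must be matched")
    if np.any(a0 <= 0) or np.any(a1 <= 0):
        raise StrainError("areas must be positive")
    log_ratio = np.log(a1) - np.log(a0)
    uniq = np.unique(d)
    mean = np.empty(len(uniq))
    std = np.empty(len(uniq))
    counts = np.empty(len(uniq), dtype=int)
    for i, dist in enumerate(uniq):
        sel = d == dist
        counts[i] = int(sel.sum())
        # both printed-equivalent orders; assert the identity holds
        m_ratio = float(np.mean(log_ratio[sel]))
        m_diff = float(np.mean(np.log(a1[sel])) - np.mean(np.log(a0[sel])))
        assert abs(m_ratio - m_diff) < 1e-10 * max(1.0, abs(m_ratio))
        mean[i] = m_ratio
        std[i] = float(np.std(log_ratio[sel]))
    core_sel = d <= 1
    core_value = float(np.mean(log_ratio[core_sel])) if core_sel.any() else float("nan")
    core_region = d <= CORE_MAX_DISTANCE
    max_ratio = float(np.exp(log_ratio[core_region]).max()) if core_region.any() else float("nan")
    return StrainProfile(uniq, mean, std, counts, counts < 3, core_value, max_ratio)


def find_peak_frame(area_series, distances) -> int:
    """Frame maximizing the total area of cells within distance 3 of the focus.

    Ties resolve to the earliest frame.
    """
    A = np.asarray(area_series, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2:
        raise StrainError("area series must be (n_frames >= 2, n_cells)")
    d = np.asarray(distances, dtype=int)
    core = d <= CORE_MAX_DISTANCE
    if not core.any():
        raise StrainError("no cells within the core distance")
    totals = A[:, core].sum(axis=1)
    return int(np.argmax(totals))  # argmax returns the first maximum


def classify_event(profile: StrainProfile, coherence_threshold: float = 0.1) -> str:
    """'large' (> twofold core area increase), 'small', or 'none'."""
    if profile.max_core_ratio > LARGE_EVENT_RATIO:
        return "large"
    if profile.core_value > coherence_threshold:
        return "small"
    return "none"


# ---------------------------------------------------------------------------
# cell shape anisotropy (triangle method)
# ---------------------------------------------------------------------------


@dataclass
class ShapeTensor:
    Q: np.ndarray          # 2x2 traceless symmetric, tangent-frame components
    excluded: int = 0      # degenerate triangles dropped

    @property
    def magnitude(self) -> float:
        """Positive eigenvalue |Q| (Hencky convention)."""
        return float(np.sqrt(self.Q[0, 0] ** 2 + self.Q[0, 1] ** 2))

    @property
    def axis_angle(self) -> float:
        """Principal (elongation) axis angle in the tangent frame, mod pi."""
        return float(0.5 * np.arctan2(2 * self.Q[0, 1],
                                      self.Q[0, 0] - self.Q[1, 1]) % np.pi)


_REF_EQUILATERAL = np.array([[1.0, 0.5], [0.0, np.sqrt(3) / 2]])  # unit edge, col basis


def _triangle_anisotropy(p1, p2, p3):
    """Hencky elongation of one triangle vs an area-matched aligned reference.

    Returns (Q_t 2x2, area); the reference equilateral triangle is aligned
    with the frame's x axis and scaled to the triangle's area, so the map
    has unit determinant and its left-stretch log is traceless.
    """
    T = np.column_stack([p2 - p1, p3 - p1])
    area = 0.5 * abs(np.linalg.det(T))
    if area <= 0:
        return None, 0.0
    ref_area = np.sqrt(3) / 4
    R = _REF_EQUILATERAL * np.sqrt(area / ref_area)
    S = T @ np.linalg.inv(R)
    # left polar decomposition S = U' Rot: elongation from B = S S^T
    B = S @ S.T
    evals, evecs = np.linalg.eigh(B)
    if evals[0] <= 0:
        return None, 0.0
    H = evecs @ np.diag(0.5 * np.log(evals)) @ evecs.T
    H = H - 0.5 * np.trace(H) * np.eye(2)
    return H, area


def cell_shape_tensor(geometry: CellGeometry, vertices_2d: np.ndarray | None = None,
                      vertices_3d: np.ndarray | None = None) -> ShapeTensor:
    """Area-weighted triangle anisotropy tensor of one cell.

    The cell outline is taken in its tangent frame (either supplied as 2D
    coordinates or projected from the 3D vertex cycle); each fan triangle
    (center + adjacent vertex pair) contributes its Hencky elongation with
    the triangle rotation removed, weighted by triangle area.
    """
    if vertices_2d is None:
        if vertices_3d is None:
            raise StrainError("supply the cell vertex cycle (2D or 3D)")
        off = np.asarray(vertices_3d, float) - geometry.center
        vertices_2d = np.column_stack([off @ geometry.e1, off @ geometry.e2])
    P = np.asarray(vertices_2d, dtype=float)
    if len(P) < 3:
        raise StrainError("cell needs at least 3 vertices")
    center = P.mean(axis=0)
    acc = np.zeros((2, 2))
    wsum = 0.0
    excluded = 0
    for i in range(len(P)):
        Q_t, area = _triangle_anisotropy(center, P[i], P[(i + 1) % len(P)])
        if Q_t is None:
            excluded += 1
            continue
        acc += area * Q_t
        wsum += area
    if wsum == 0:
        raise StrainError("all triangles degenerate")
    return ShapeTensor(acc / wsum, excluded)


def project_anisotropy(Q, direction) -> float:
    """Elongation along a unit in-plane direction: d . Q . d."""
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise StrainError("direction must be nonzero")
    d = d / n
    Qm = Q.Q if isinstance(Q, ShapeTensor) else np.asarray(Q, dtype=float)
    return float(d @ Qm @ d)
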