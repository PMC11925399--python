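"""Generators for all package inputs.

- spheroidal cell shells (seeded spherical Voronoi + centroidal relaxation)
- initial nematic patterns (fragment / late_defects / four_half / uniform /
  random) built from exact stereographic defect fields
- synthetic fiber-intensity rasters with known orientation ground truth
- synthetic per-frame cell-area series for testing the strain analysis

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import SphericalVoronoi

from nemashell.shell import CellularShell, ShellError, compute_geometry, validate_shell
from nemashell.nematic import NematicField, angles_to_q

PATTERNS = ("fragment", "late_defects", "four_half", "uniform", "random")


# ---------------------------------------------------------------------------
# sphere meshes
# ---------------------------------------------------------------------------


def _fibonacci_jittered(n, rng):
    """Quasi-uniform seed points on the unit sphere with seeded jitter."""
    i = np.arange(n)
    phi = (1 + 5 ** 0.5) / 2
    z = 1 - (2 * i + 1) / n
    az = 2 * np.pi * i / phi
    pts = np.column_stack([np.sqrt(1 - z ** 2) * np.cos(az),
                           np.sqrt(1 - z ** 2) * np.sin(az), z])
    pts = pts + 0.25 * rng.normal(size=pts.shape) / np.sqrt(n)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _voronoi_shell(points, radius):
    sv = SphericalVoronoi(points, radius=1.0, threshold=1e-9)
    sv.sort_vertices_of_regions()
    verts = sv.vertices * radius
    # merge near-duplicate vertices (co-circular degeneracies)
    key = np.round(verts / radius, 9)
    _, idx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    cells = []
    for region in sv.regions:
        cyc = [int(inv[v]) for v in region]
        dedup = [cyc[i] for i in range(len(cyc)) if cyc[i] != cyc[(i - 1) % len(cyc)]]
        if len(dedup) < 3:
            raise ShellError("degenerate Voronoi region")
        cells.append(dedup)
    shell = CellularShell(verts[idx], cells)
    _orient_outward(shell)
    return shell


def _orient_outward(shell: CellularShell):
    centroid = shell.vertices.mean(axis=0)
    for i, cyc in enumerate(shell.cells):
        P = shell.vertices[cyc]
        c = P.mean(axis=0)
        n = np.cross(P - c, np.roll(P, -1, axis=0) - c).sum(axis=0)
        if n @ (c - centroid) < 0:
            shell.cells[i] = cyc[::-1].copy()
    shell._rebuild_connectivity()


def generate_sphere_shell(n_cells: int, seed: int, relax_iters: int = 40,
                          radius: float | None = None) -> CellularShell:
    """Seeded spherical Voronoi shell with centroidal (Lloyd) relaxation.

    ``radius`` defaults to ``sqrt(n_cells / 4 pi)`` so that the mean cell
    area is ~1 (the model's preferred area in dimensionless units).
    """
    if n_cells < 20:
        raise ValueError("n_cells must be >= 20")
    if radius is None:
        radius = float(np.sqrt(n_cells / (4 * np.pi)))
    rng = np.random.default_rng(seed)
    pts = _fibonacci_jittered(n_cells, rng)
    for attempt in range(5):
        try:
            p = pts
            for _ in range(relax_iters):
                sv = SphericalVoronoi(p, radius=1.0, threshold=1e-9)
                sv.sort_vertices_of_regions()
                cent = np.array([sv.vertices[r].mean(axis=0) for r in sv.regions])
                p = cent / np.linalg.norm(cent, axis=1, keepdims=True)
            shell = _voronoi_shell(p, radius)
            validate_shell(shell, strict=True)
            return shell
        except (ShellError, ValueError):
            pts = _fibonacci_jittered(n_cells, rng)  # perturbed retry
    raise ShellError(f"could not build a valid {n_cells}-cell shell (seed {seed})")


# ---------------------------------------------------------------------------
# nematic initialization
# ---------------------------------------------------------------------------


def _sphere_directions(shell: CellularShell, geom=None):
    if geom is None:
        geom = compute_geometry(shell)
    c = geom.centers - geom.centers.mean(axis=0)
    return geom, c / np.linalg.norm(c, axis=1, keepdims=True)


def _axis_field_angles(geom, xhat, axis=np.array([0.0, 0.0, 1.0])):
    """Angle of the projection of a fixed axis in each cell's tangent frame."""
    d = axis - np.sum(axis * geom.normals, axis=1, keepdims=True) * geom.normals
    nrm = np.linalg.norm(d, axis=1)
    sing = nrm < 1e-8
    d = np.where(sing[:, None], geom.e1, d / np.maximum(nrm, 1e-300)[:, None])
    return np.arctan2(np.sum(d * geom.e2, axis=1), np.sum(d * geom.e1, axis=1)), sing


def _stereographic_field_angles(geom, xhat, plane_defects, theta0=0.0):
    """Director angles of an exact defect field built in stereographic coords.

    ``plane_defects`` is a list of (unit_direction, charge) away from the
    north pole (0,0,1), which acts as projection point and carries charge
    ``2 - sum(charges)``.  The construction uses the conformality of the
    stereographic map: angles in the plane transfer directly to the sphere
    via the normalized coordinate tangent vectors.
    """
    x, y, z = xhat[:, 0], xhat[:, 1], xhat[:, 2]
    denom = np.maximum(1.0 - z, 1e-12)
    zeta = (x + 1j * y) / denom
    ang = theta0 * np.ones(len(xhat))
    for p, charge in plane_defects:
        pz = (p[0] + 1j * p[1]) / max(1.0 - p[2], 1e-12)
        ang = ang + charge * np.angle(zeta - pz)
    # tangent basis of the inverse stereographic map (orthogonal, conformal)
    u, v = zeta.real, zeta.imag
    s = 1 + u ** 2 + v ** 2
    bu = np.column_stack([s - 2 * u ** 2, -2 * u * v, 2 * u])
    bu /= np.linalg.norm(bu, axis=1, keepdims=True)
    bv = np.column_stack([-2 * u * v, s - 2 * v ** 2, 2 * v])
    bv /= np.linalg.norm(bv, axis=1, keepdims=True)
    d = np.cos(ang)[:, None] * bu + np.sin(ang)[:, None] * bv
    # express in each cell's tangent frame (normals are near-radial)
    d = d - np.sum(d * geom.normals, axis=1, keepdims=True) * geom.normals
    nrm = np.linalg.norm(d, axis=1)
    sing = nrm < 1e-8
    d = np.where(sing[:, None], geom.e1, d / np.maximum(nrm, 1e-300)[:, None])
    return np.arctan2(np.sum(d * geom.e2, axis=1), np.sum(d * geom.e1, axis=1)), sing


def init_nematic(shell: CellularShell, pattern: str, seed: int = 0,
                 tau_q: float = 1.0, alpha: float = 0.0,
                 pair_separation: float = 4.0,
                 disordered_fraction: float = 1.0 / 3.0,
                 bridge_halfwidth: float = 1.0) -> NematicField:
    """Initial unit nematic field in one of the closed list of patterns.

    Patterns
    --------
    ``fragment``
        Ordered band of fibers parallel to the z axis plus a disordered
        region (two polar caps joined by a meridional bridge) of net
        charge +2, filled with seeded random orientations.
    ``late_defects``
        A +1 aster at the +z pole and a +1/2 defect pair straddling the
        -z pole, separated by ``pair_separation`` mean cell diameters.
    ``four_half``
        Four +1/2 defects in a tetrahedral arrangement.
    ``uniform``
        Fibers along the z axis; the two polar cells are forced
        singularities (marked in ``field.singular``).
    ``random``
        I.i.d. orientations.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {PATTERNS}")
    rng = np.random.default_rng(seed)
    geom, xhat = _sphere_directions(shell)
    C = shell.n_cells
    sing = np.zeros(C, dtype=bool)

    if pattern == "random":
        psi = rng.uniform(0, np.pi, C)
    elif pattern == "uniform":
        psi, sing = _axis_field_angles(geom, xhat)
        # mark the two polar cells (nearest +-z) as the forced singularities
        sing = np.zeros(C, dtype=bool)
        sing[np.argmax(xhat[:, 2])] = True
        sing[np.argmin(xhat[:, 2])] = True
    elif pattern == "late_defects":
        # mean cell diameter and sphere radius, for the pair separation
        R = float(np.linalg.norm(geom.centers - geom.centers.mean(0), axis=1).mean())
        diam = 2 * np.sqrt(np.mean(geom.areas) / np.pi)
        half_angle = 0.5 * pair_separation * diam / R
        p1 = np.array([np.sin(half_angle), 0, -np.cos(half_angle)])
        p2 = np.array([-np.sin(half_angle), 0, -np.cos(half_angle)])
        psi, sing = _stereographic_field_angles(
            geom, xhat, [(p1, 0.5), (p2, 0.5)])
    elif pattern == "four_half":
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
        psi, sing = _stereographic_field_angles(
            geom, xhat, [(p, 0.5) for p in tet])
    else:  # fragment
        psi, _ = _axis_field_angles(geom, xhat)
        z = np.clip(xhat[:, 2], -1, 1)
        phi_az = np.arctan2(xhat[:, 1], xhat[:, 0])
        # two caps whose combined area is ~80% of the disordered fraction
        cap_frac = 0.8 * disordered_fraction
        cos_cap = 1.0 - cap_frac  # two caps: 2 * (1 - cos) / 2 = 1 - cos
        in_cap = np.abs(z) > cos_cap
        # meridional bridge joining the caps, ~2 cell rows wide
        R = float(np.linalg.norm(geom.centers - geom.centers.mean(0), axis=1).mean())
        diam = 2 * np.sqrt(np.mean(geom.areas) / np.pi)
        sin_pol = np.sqrt(np.maximum(1 - z ** 2, 1e-9))
        in_bridge = np.abs(((phi_az + np.pi) % (2 * np.pi)) - np.pi) \
            < bridge_halfwidth * diam / (R * sin_pol)
        disordered = in_cap | in_bridge
        psi = np.where(disordered, rng.uniform(0, np.pi, C), psi)
        sing = disordered

    field = NematicField(angles_to_q(psi), tau_q=tau_q, alpha=alpha, singular=sing)
    field.check_unit()
    return field


# ---------------------------------------------------------------------------
# fiber-intensity rasters
# ---------------------------------------------------------------------------


@dataclass
class FiberImage:
    image: np.ndarray        # (H, W) float intensity
    orientation: np.ndarray  # (H, W) ground-truth angle, radians mod pi
    pixel_size: float


def _ground_truth_orientation(kind, H, W, angle=0.0, charge=1.0, center=None):
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    if center is None:
        center = ((W - 1) / 2.0, (H - 1) / 2.0)
    if kind == "stripes":
        return np.full((H, W), angle % np.pi)
    if kind == "aster":
        return np.arctan2(yy - center[1], xx - center[0]) % np.pi
    if kind == "defect":
        az = np.arctan2(yy - center[1], xx - center[0])
        return (charge * az + angle) % np.pi
    raise ValueError(f"unknown fiber-image kind {kind!r}")


def render_fiber_image(kind: str, size: int = 128, pixel_size: float = 1.0,
                       noise: float = 0.0, seed: int = 0, angle: float = 0.0,
                       charge: float = 1.0, n_segments: int | None = None,
                       segment_length: float = 12.0) -> FiberImage:
    """Synthetic oriented line texture with known orientation ground truth.

    Renders short anti-aliased segments that follow the ground-truth
    orientation field (stripes, +1 asters, arbitrary half-integer defect
    motifs) and adds seeded Gaussian noise.
    """
    if size < 64:
        raise ValueError("raster size must be >= 64")
    H = W = int(size)
    rng = np.random.default_rng(seed)
    theta = _ground_truth_orientation(kind, H, W, angle=angle, charge=charge)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    if kind == "stripes":
        # exact sinusoidal texture: intensity varies perpendicular to the fibers
        wavelength = 8.0
        phase = (xx * np.cos(angle + np.pi / 2) + yy * np.sin(angle + np.pi / 2))
        img = 0.5 * (1 + np.cos(2 * np.pi * phase / wavelength))
        if noise > 0:
            img = img + noise * rng.normal(size=img.shape)
        return FiberImage(img, theta, pixel_size)
    if kind == "aster":
        # radial spokes: intensity modulated in azimuth only
        cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
        az = np.arctan2(yy - cy, xx - cx)
        img = 0.5 * (1 + np.cos(2 * 24 * az / 2))
        if noise > 0:
            img = img + noise * rng.normal(size=img.shape)
        return FiberImage(img, theta, pixel_size)
    # line-integral-convolution texture: directionally smooth seeded noise
    # along the orientation field (gives a fiber-like streak pattern for
    # arbitrary defect charges)
    from scipy.ndimage import map_coordinates

    img = rng.normal(size=(H, W))
    dy, dx = np.sin(theta), np.cos(theta)
    base = np.mgrid[0:H, 0:W].astype(float)
    half = int(segment_length // 2)
    for _ in range(2):
        acc = img.copy()
        for s in range(1, half + 1):
            for sgn in (1.0, -1.0):
                coords = np.stack([base[0] + sgn * s * dy, base[1] + sgn * s * dx])
                acc += map_coordinates(img, coords, order=1, mode="reflect")
        img = acc / (2 * half + 1)
    img -= img.min()
    img /= max(img.max(), 1e-12)
    if noise > 0:
        img = img + noise * rng.normal(size=img.shape)
    return FiberImage(img, theta, pixel_size)


# ---------------------------------------------------------------------------
# synthetic cell-area event series
# ---------------------------------------------------------------------------


@dataclass
class EventSeries:
    areas: np.ndarray            # (n_frames, n_cells)
    distances: np.ndarray        # (n_cells,) graph distance from the core
    peak_frame: int              # ground truth
    true_profile: dict[int, float]  # per-distance ground-truth log strain


def synthetic_event_series(distances, n_frames: int = 20, amplitude: float = np.log(2),
                           peak_frame: int | None = None, duration: float = 2.0,
                           decay_cells: float = 2.0, noise: float = 0.0,
                           seed: int = 0, baseline: np.ndarray | None = None) -> EventSeries:
    """Cell areas with one Gaussian-in-time stretching bump.

    The per-cell log-area amplitude is ``amplitude * exp(-d^2 / (2 dc^2))``
    with d the graph distance from the core, so the ground-truth core log
    strain equals ``amplitude`` exactly.
    """
    distances = np.asarray(distances, dtype=int)
    n_cells = len(distances)
    rng = np.random.default_rng(seed)
    if peak_frame is None:
        peak_frame = n_frames // 2
    if baseline is None:
        baseline = np.ones(n_cells)
    frames = np.arange(n_frames)
    temporal = np.exp(-((frames - peak_frame) ** 2) / (2 * duration ** 2))
    spatial = amplitude * np.exp(-(distances.astype(float) ** 2) / (2 * decay_cells ** 2))
    log_areas = np.log(baseline)[None, :] + temporal[:, None] * spatial[None, :]
    if noise > 0:
        log_areas = log_areas + noise * rng.normal(size=log_areas.shape)
    profile = {int(d): float(amplitude * np.exp(-d ** 2 / (2 * decay_cells ** 2)))
               for d in np.unique(distances)}
    return EventSeries(np.exp(log_areas), distances, int(peak_frame), profile)
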