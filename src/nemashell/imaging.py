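"""2D fiber-orientation analysis on grayscale intensity rasters.

Pipeline: structure-tensor raw orientation (minor eigenvector of locally
averaged gradient outer products), doubled-angle Gaussian smoothing,
windowed coherence |cos(theta - theta_raw)|, nematic order parameter
S = |windowed mean of e^{2 i theta}|, coherence-threshold masking
(default 0.88) and plaquette winding-number defect detection.

Physical window sizes are micrometres and convert through ``pixel_size``
(default 1 um/px).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter
from skimage.measure import label, regionprops

DEFAULT_COHERENCE_THRESHOLD = 0.88


@dataclass
class OrientationMaps:
    raw: np.ndarray          # theta_ij, radians mod pi
    smoothed: np.ndarray     # theta, radians mod pi
    coherence: np.ndarray    # in [0, 1]
    order: np.ndarray        # S in [0, 1]
    defined: np.ndarray      # False where gradient energy vanished
    pixel_size: float
    coherence_threshold: float = DEFAULT_COHERENCE_THRESHOLD

    @property
    def mask(self) -> np.ndarray:
        return self.coherence >= self.coherence_threshold


def _px(um: float, pixel_size: float) -> int:
    return max(1, int(round(um / pixel_size)))


def raw_orientation_field(raster, window_um: float = 6.0, pixel_size: float = 1.0,
                          presmooth_px: float = 1.0):
    """Structure-tensor orientation (mod pi) per pixel.

    The orientation minimizing the gradient energy in a box of
    ``window_um`` around each pixel, i.e. the minor eigenvector of the
    locally averaged gradient outer-product tensor.  Returns
    (theta, defined) where ``defined`` is False at zero-gradient pixels.
    """
    img = np.asarray(raster, dtype=float)
    win = _px(window_um, pixel_size)
    if win < 3:
        raise ValueError(f"structure-tensor window {win} px is below 3 px")
    sm = gaussian_filter(img, presmooth_px)
    gy, gx = np.gradient(sm)
    Jxx = uniform_filter(gx * gx, win)
    Jyy = uniform_filter(gy * gy, win)
    Jxy = uniform_filter(gx * gy, win)
    energy = Jxx + Jyy
    defined = energy > 1e-12 * max(float(energy.max()), 1e-300)
    # gradient (major) axis angle; fiber orientation is orthogonal to it
    grad_angle = 0.5 * np.arctan2(2 * Jxy, Jxx - Jyy)
    theta = (grad_angle + 0.5 * np.pi) % np.pi
    return theta, defined


def smooth_orientation(theta, sigma_um: float = 4.0, pixel_size: float = 1.0):
    """Gaussian smoothing in doubled-angle components (wraparound-safe)."""
    sig = sigma_um / pixel_size
    c = gaussian_filter(np.cos(2 * np.asarray(theta, float)), sig)
    s = gaussian_filter(np.sin(2 * np.asarray(theta, float)), sig)
    return 0.5 * np.arctan2(s, c) % np.pi


def coherence_map(theta_raw, theta_smooth, window_um: float = 15.0,
                  pixel_size: float = 1.0):
    """Windowed mean of |cos(theta - theta_ij)|.

    ``theta`` is the smoothed orientation at the window center; the average
    of |cos| against the raw field runs over a square window.
    """
    win = _px(window_um, pixel_size)
    half = win // 2
    th_c = np.asarray(theta_smooth, float)
    th_r = np.asarray(theta_raw, float)
    acc = np.zeros_like(th_c)
    cnt = np.zeros_like(th_c)
    H, W = th_c.shape
    for dy in range(-half, half + 1):
        ys = slice(max(0, dy), min(H, H + dy))
        yd = slice(max(0, -dy), min(H, H - dy))
        for dx in range(-half, half + 1):
            xs = slice(max(0, dx), min(W, W + dx))
            xd = slice(max(0, -dx), min(W, W - dx))
            acc[yd, xd] += np.abs(np.cos(th_c[yd, xd] - th_r[ys, xs]))
            cnt[yd, xd] += 1.0
    out = acc / cnt
    return np.clip(out, 0.0, 1.0)


def order_parameter_map(theta, window_um: float = 25.0, pixel_size: float = 1.0):
    """S = |windowed mean of (cos 2 theta, sin 2 theta)|, in [0, 1]."""
    win = _px(window_um, pixel_size)
    c = uniform_filter(np.cos(2 * np.asarray(theta, float)), win)
    s = uniform_filter(np.sin(2 * np.asarray(theta, float)), win)
    return np.clip(np.hypot(c, s), 0.0, 1.0)


def analyze_orientation(raster, pixel_size: float = 1.0,
                        coherence_threshold: float = DEFAULT_COHERENCE_THRESHOLD,
                        window_raw_um: float = 6.0, sigma_smooth_um: float = 4.0,
                        window_coherence_um: float = 15.0,
                        window_order_um: float = 25.0) -> OrientationMaps:
    """Full orientation pipeline on one grayscale raster."""
    theta_raw, defined = raw_orientation_field(raster, window_raw_um, pixel_size)
    theta = smooth_orientation(theta_raw, sigma_smooth_um, pixel_size)
    coh = coherence_map(theta_raw, theta, window_coherence_um, pixel_size)
    S = order_parameter_map(theta, window_order_um, pixel_size)
    return OrientationMaps(theta_raw, theta, coh, S, defined, pixel_size,
                           coherence_threshold)


# ---------------------------------------------------------------------------
# defect detection on the pixel grid
# ---------------------------------------------------------------------------


def _wrap(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


def detect_defects_2d(theta, mask=None, min_abs_charge: float = 0.25,
                      merge_radius_px: int = 6, border_px: int = 12):
    """Winding-number defects of an orientation field (mod pi).

    Computes the winding of the doubled angle around every elementary
    pixel plaquette, halves it, clusters nonzero plaquettes within
    ``merge_radius_px`` of each other (charges summed, so the two half
    charges of a smoothed +1 core merge back to +1) and reports
    (x, y, charge) per cluster.  A ``border_px`` margin is excluded to
    avoid filter edge artifacts.
    """
    th2 = 2.0 * np.asarray(theta, dtype=float)
    d_right = _wrap(th2[:, 1:] - th2[:, :-1])     # (H, W-1)
    d_down = _wrap(th2[1:, :] - th2[:-1, :])      # (H-1, W)
    # loop: (i,j)->(i,j+1)->(i+1,j+1)->(i+1,j)->(i,j)
    circ = (d_right[:-1, :] + d_down[:, 1:] - d_right[1:, :] - d_down[:, :-1])
    charge = np.round(circ / (2 * np.pi)) / 2.0   # half-integer per plaquette
    if mask is not None:
        m = np.asarray(mask, bool)
        ok = m[:-1, :-1] & m[:-1, 1:] & m[1:, :-1] & m[1:, 1:]
        charge = np.where(ok, charge, 0.0)
    if border_px > 0:
        charge[:border_px, :] = 0.0
        charge[-border_px:, :] = 0.0
        charge[:, :border_px] = 0.0
        charge[:, -border_px:] = 0.0
    hot = np.abs(charge) >= min_abs_charge
    if not hot.any():
        return []
    if merge_radius_px > 0:
        from scipy.ndimage import binary_dilation
        yy, xx = np.mgrid[-merge_radius_px:merge_radius_px + 1,
                          -merge_radius_px:merge_radius_px + 1]
        selem = xx ** 2 + yy ** 2 <= merge_radius_px ** 2
        blob = binary_dilation(hot, structure=selem)
    else:
        blob = hot
    labels = label(blob, connectivity=2)
    out = []
    for region in regionprops(labels):
        sel = (labels == region.label) & hot
        q = float(charge[sel].sum())
        if abs(q) < min_abs_charge:
            continue
        ys, xs = np.nonzero(sel)
        w = np.abs(charge[sel])
        cy = float(np.average(ys, weights=w))
        cx = float(np.average(xs, weights=w))
        out.append((cx + 0.5, cy + 0.5, q))  # plaquette center in pixel coords
    return out
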