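"""Lucas-Kanade local optical flow.

Under the intensity-constancy assumption, a point that moves by u_dot
between two frames satisfies ``I_t + grad(I) . u_dot = 0``.  Stacking that
constraint for every pixel p_i in a small observation window gives the
overdetermined system ``U u_dot = V`` with rows ``[I_x(p_i), I_y(p_i)]``
and ``V_i = -I_t(p_i)``; the least-squares solution is

    u_dot = (U^T U)^{-1} U^T V.

The flow is local by design: a lesion ROI is tiled into small patches so
the brightness-constancy and smoothness assumptions hold within each
window, and the per-window estimates are combined by a conditioning-
weighted trimmed mean.  Degenerate windows (smallest eigenvalue of U^T U
below ``tau_eig``, e.g. flat shadow regions) are flagged and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BoundingBox

__all__ = [
    "FlowEstimate",
    "spatiotemporal_gradients",
    "lk_window_flow",
    "roi_flow",
]

DEFAULT_WINDOW = 15
DEFAULT_PATCH_GRID = (4, 4)
TAU_EIG = 1e-6


@dataclass(frozen=True)
class FlowEstimate:
    """Flow (u_x, u_y) in pixels/frame for one observation window."""

    u: tuple[float, float]
    window_center: tuple[float, float]  # (x, y)
    window_size: int
    conditioning: float  # smallest eigenvalue of U^T U
    degenerate: bool = False
    aperture: bool = False  # rank-1 normal matrix: only the gradient-parallel
    # component is constrained (minimum-norm solution reported)
    unreliable: bool = False  # |u| exceeds half the window: outside LK's regime

    @property
    def vector(self) -> np.ndarray:
        return np.array(self.u, dtype=float)


def spatiotemporal_gradients(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    smooth_sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatial and temporal intensity derivatives between two frames.

    Frames are Gaussian-smoothed (``smooth_sigma`` px, 0 disables) first;
    ``I_t = frame_b - frame_a`` (dt = 1 frame) and ``I_x``, ``I_y`` are
    central differences averaged over the two frames.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if smooth_sigma > 0:
        a = ndimage.gaussian_filter(a, smooth_sigma, mode="nearest")
        b = ndimage.gaussian_filter(b, smooth_sigma, mode="nearest")
    ay, ax = np.gradient(a)
    by, bx = np.gradient(b)
    i_x = 0.5 * (ax + bx)
    i_y = 0.5 * (ay + by)
    i_t = b - a
    return i_x, i_y, i_t


def lk_window_flow(
    i_x: np.ndarray,
    i_y: np.ndarray,
    i_t: np.ndarray,
    center: tuple[float, float],
    window_size: int = DEFAULT_WINDOW,
    tau_eig: float = TAU_EIG,
) -> FlowEstimate:
    """Solve the LK normal equations on one window centered at ``(x, y)``.

    Returns a flagged zero-flow estimate when the normal matrix U^T U is
    (near-)singular, which happens on flat or 1-D-textured windows.
    """
    if window_size % 2 != 1:
        raise ValueError("window_size must be odd")
    half = window_size // 2
    cx, cy = int(round(center[0])), int(round(center[1]))
    H, W = i_x.shape
    if cx - half < 0 or cy - half < 0 or cx + half >= W or cy + half >= H:
        raise ValueError(
            f"window at ({cx},{cy}) size {window_size} outside {H}x{W} grid"
        )
    sl = (slice(cy - half, cy + half + 1), slice(cx - half, cx + half + 1))
    gx = i_x[sl].ravel()
    gy = i_y[sl].ravel()
    gt = i_t[sl].ravel()

    # U^T U and U^T V assembled directly (2x2 system)
    g11 = float(gx @ gx)
    g12 = float(gx @ gy)
    g22 = float(gy @ gy)
    tr = g11 + g22
    det = g11 * g22 - g12 * g12
    disc = max(tr * tr / 4.0 - det, 0.0)
    lam_min = tr / 2.0 - np.sqrt(disc)

    lam_max = tr / 2.0 + np.sqrt(disc)
    if lam_max < tau_eig:  # flat window: nothing is constrained
        return FlowEstimate(
            u=(0.0, 0.0),
            window_center=(float(cx), float(cy)),
            window_size=window_size,
            conditioning=max(lam_min, 0.0),
            degenerate=True,
        )
    b1 = -float(gx @ gt)
    b2 = -float(gy @ gt)
    if lam_min < tau_eig:
        # 1-D texture (aperture problem): minimum-norm least squares gives
        # the gradient-parallel component, the orthogonal one stays zero
        G = np.array([[g11, g12], [g12, g22]])
        ux, uy = np.linalg.pinv(G, rcond=1e-10) @ np.array([b1, b2])
        return FlowEstimate(
            u=(float(ux), float(uy)),
            window_center=(float(cx), float(cy)),
            window_size=window_size,
            conditioning=max(lam_min, 0.0),
            aperture=True,
            unreliable=float(np.hypot(ux, uy)) > window_size / 2.0,
        )
    ux = (g22 * b1 - g12 * b2) / det
    uy = (g11 * b2 - g12 * b1) / det
    unreliable = float(np.hypot(ux, uy)) > window_size / 2.0
    return FlowEstimate(
        u=(ux, uy),
        window_center=(float(cx), float(cy)),
        window_size=window_size,
        conditioning=lam_min,
        unreliable=unreliable,
    )


def _trimmed_weighted_mean(values: np.ndarray, weights: np.ndarray, trim: float = 0.25) -> float:
    """Weighted mean after discarding the lowest/highest ``trim`` fraction."""
    order = np.argsort(values)
    k = int(np.floor(trim * len(values)))
    keep = order[k : len(values) - k] if len(values) > 2 * k else order
    w = weights[keep]
    if w.sum() <= 0:
        return float(values[keep].mean())
    return float(np.average(values[keep], weights=w))


def roi_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    box: BoundingBox,
    patch_grid: tuple[int, int] = DEFAULT_PATCH_GRID,
    window_size: int = DEFAULT_WINDOW,
    smooth_sigma: float = 1.0,
    tau_eig: float = TAU_EIG,
) -> FlowEstimate:
    """Aggregate LK flow over an ROI tiled into ``patch_grid`` windows.

    Per-window flows are combined component-wise by a conditioning-weighted
    trimmed mean over the non-degenerate, reliable windows, which tolerates
    a fraction of corrupted windows (e.g. under a partial shadow).  If no
    window is usable the result is a flagged zero flow.
    """
    H, W = frame_a.shape
    x0, y0, bw, bh = box.to_corner()
    if x0 < 0 or y0 < 0 or x0 + bw > W or y0 + bh > H:
        raise ValueError(f"box {box} outside {H}x{W} frames")

    i_x, i_y, i_t = spatiotemporal_gradients(frame_a, frame_b, smooth_sigma)
    half = window_size // 2
    ny, nx = patch_grid
    estimates: list[FlowEstimate] = []
    for iy in range(ny):
        for ix in range(nx):
            cx = x0 + (ix + 0.5) * bw / nx
            cy = y0 + (iy + 0.5) * bh / ny
            # keep the window inside the frame
            cx = min(max(cx, half), W - 1 - half)
            cy = min(max(cy, half), H - 1 - half)
            est = lk_window_flow(i_x, i_y, i_t, (cx, cy), window_size, tau_eig)
            estimates.append(est)

    good = [e for e in estimates if not (e.degenerate or e.aperture or e.unreliable)]
    center = (box.cx, box.cy)
    if not good:
        return FlowEstimate(
            u=(0.0, 0.0),
            window_center=center,
            window_size=window_size,
            conditioning=0.0,
            degenerate=True,
        )
    ux = np.array([e.u[0] for e in good])
    uy = np.array([e.u[1] for e in good])
    wts = np.array([e.conditioning for e in good])
    agg = (
        _trimmed_weighted_mean(ux, wts),
        _trimmed_weighted_mean(uy, wts),
    )
    unreliable = float(np.hypot(*agg)) > window_size / 2.0
    return FlowEstimate(
        u=agg,
        window_center=center,
        window_size=window_size,
        conditioning=float(wts.min()),
        unreliable=unreliable,
    )
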