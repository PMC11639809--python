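"""Feature-point selection and sparse Lucas-Kanade trajectory tracking.

Feature points are FAST segment-test corners (16-pixel Bresenham circle,
arc length 9): a pixel is a corner when a contiguous arc of the circle is
uniformly brighter or darker than the centre by more than the contrast
threshold.  Detected responses are bucketed on a coarse grid (at most one
point per cell) so the strongest points spread across the ROI instead of
clustering on the sharpest texture, and the best ``max_points`` survive.

Tracking is classic pyramidal Lucas-Kanade: points seeded once on the
first frame, flow solved frame-to-frame on a Gaussian pyramid and chained;
a point whose normal matrix is ill-conditioned, whose iteration diverges or
whose window leaves the image is marked invalid from that frame on and is
never re-seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import corner_fast

from ._lk import lk_level
from .exceptions import DegenerateInputError, ParameterError
from .video_io import FrameSequence

__all__ = [
    "TrackerConfig",
    "TrajectorySet",
    "MotionSignals",
    "detect_feature_points",
    "track",
    "differentiate",
]


@dataclass(frozen=True)
class TrackerConfig:
    """Detector and tracker settings.

    ``contrast_threshold`` is in 8-bit gray levels; ``cell_size`` is the
    bucketing grid pitch in pixels; ``lk_window`` the side of the square
    Lucas-Kanade window; ``lk_levels`` the number of pyramid levels.
    """

    max_points: int = 200
    contrast_threshold: float = 2.0
    cell_size: int = 4
    lk_window: int = 21
    lk_levels: int = 3
    lk_max_iter: int = 20
    lk_eps: float = 0.01
    min_determinant: float = 1e-6

    def __post_init__(self):
        if self.max_points < 1:
            raise ParameterError("max_points must be >= 1")
        if self.contrast_threshold < 1:
            raise ParameterError("contrast_threshold must be >= 1 gray level")
        if self.cell_size < 1:
            raise ParameterError("cell_size must be >= 1")
        if self.lk_window < 3 or self.lk_window % 2 == 0:
            raise ParameterError("lk_window must be an odd integer >= 3")
        if self.lk_levels < 1:
            raise ParameterError("lk_levels must be >= 1")


@dataclass
class TrajectorySet:
    """Chained (x, y) positions of N points over T frames.

    ``valid[i, t]`` is True while point ``i`` is still tracked at frame
    ``t``; validity is monotone non-increasing in ``t`` (a lost point stays
    lost).  Positions are NaN once invalid.
    """

    positions: np.ndarray  # (N, T, 2) float, columns (x, y)
    valid: np.ndarray  # (N, T) bool
    fps: float

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def fully_valid(self) -> np.ndarray:
        """Boolean selector of points tracked through the whole sequence."""
        return self.valid[:, -1]


@dataclass
class MotionSignals:
    """First differences of fully tracked trajectories, split by axis."""

    dx: np.ndarray  # (M, T-1)
    dy: np.ndarray  # (M, T-1)
    fps: float

    @property
    def n_signals(self) -> int:
        return self.dx.shape[0]


def detect_feature_points(
    image: np.ndarray, mask: np.ndarray | None = None, cfg: TrackerConfig = TrackerConfig()
) -> np.ndarray:
    """Select up to ``cfg.max_points`` FAST corners inside the mask.

    Returns an ``(n, 2)`` float array of (x, y) positions, strongest corner
    first, at most one per ``cell_size`` x ``cell_size`` grid cell.  An
    empty array (e.g. on a constant image) is a valid result the caller
    must handle.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ParameterError("detect_feature_points expects a grayscale image")
    response = corner_fast(
        img / 255.0, n=9, threshold=cfg.contrast_threshold / 255.0
    )
    if mask is not None:
        response = response * (np.asarray(mask) != 0)
    ys, xs = np.nonzero(response > 0)
    if len(ys) == 0:
        return np.empty((0, 2), dtype=np.float64)
    scores = response[ys, xs]
    # One winner per grid cell: best score, ties to the smaller pixel index.
    cells = (ys // cfg.cell_size) * (1 + xs.max() // cfg.cell_size) + xs // cfg.cell_size
    order = np.lexsort((ys * response.shape[1] + xs, -scores))
    seen: set[int] = set()
    picked = []
    for k in order:
        c = int(cells[k])
        if c in seen:
            continue
        seen.add(c)
        picked.append(k)
        if len(picked) >= cfg.max_points:
            break
    picked = np.array(picked)
    return np.column_stack([xs[picked], ys[picked]]).astype(np.float64)


# ---------------------------------------------------------------------------
# pyramidal Lucas-Kanade


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [np.ascontiguousarray(img, dtype=np.float64)]
    for _ in range(levels - 1):
        prev = pyr[-1]
        if min(prev.shape) < 8:
            break
        sm = gaussian_filter(prev, sigma=1.0, mode="nearest")
        pyr.append(np.ascontiguousarray(sm[::2, ::2]))
    return pyr


def _gradients(pyr: list[np.ndarray]) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for lvl in pyr:
        gy, gx = np.gradient(lvl)
        out.append((np.ascontiguousarray(gx), np.ascontiguousarray(gy)))
    return out


def _lk_pair(
    pyr_prev, grads_prev, pyr_next, pts: np.ndarray, cfg: TrackerConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Flow for one frame pair; returns (new_pts, ok) for the given points."""
    n = len(pts)
    r = cfg.lk_window // 2
    levels = len(pyr_prev)
    flow = np.zeros((n, 2), dtype=np.float64)
    ok = np.ones(n, dtype=bool)

    for lvl in range(levels - 1, -1, -1):
        scale = 2.0**lvl
        gx_img, gy_img = grads_prev[lvl]
        p = np.ascontiguousarray(pts / scale)
        v = np.ascontiguousarray(flow / scale)
        status = lk_level(
            pyr_prev[lvl], gx_img, gy_img, pyr_next[lvl], p, v,
            r, cfg.lk_max_iter, cfg.lk_eps, cfg.min_determinant,
        )
        flow = v * scale
        if lvl == 0:
            ok &= status == 1

    # Divergence / out-of-image checks at full resolution.
    new_pts = pts + flow
    h0, w0 = pyr_prev[0].shape
    inside = (
        (new_pts[:, 0] >= 0) & (new_pts[:, 0] <= w0 - 1)
        & (new_pts[:, 1] >= 0) & (new_pts[:, 1] <= h0 - 1)
    )
    ok &= inside & (np.hypot(flow[:, 0], flow[:, 1]) <= cfg.lk_window * len(pyr_prev))
    return new_pts, ok


def track(
    frames: FrameSequence | np.ndarray,
    seeds: np.ndarray,
    cfg: TrackerConfig = TrackerConfig(),
    fps: float | None = None,
) -> TrajectorySet:
    """Track seed points through the sequence with chained pyramidal LK.

    ``frames`` may be a :class:`FrameSequence` (converted to luminance) or a
    raw ``(T, H, W)`` stack.  Seeds are ``(n, 2)`` (x, y) positions on frame
    0.  No re-detection is performed: a lost point stays lost.
    """
    if isinstance(frames, FrameSequence):
        stack = frames.gray()
        fps = frames.fps
    else:
        stack = np.asarray(frames)
        if fps is None:
            raise ParameterError("fps is required when passing a raw frame stack")
    seeds = np.atleast_2d(np.asarray(seeds, dtype=np.float64))
    if seeds.size == 0:
        raise ParameterError("track requires at least one seed point")
    if len(stack) < 2:
        raise ParameterError("track requires at least two frames")

    n, t_total = len(seeds), len(stack)
    positions = np.full((n, t_total, 2), np.nan)
    valid = np.zeros((n, t_total), dtype=bool)
    positions[:, 0] = seeds
    valid[:, 0] = True

    pyr_prev = _pyramid(stack[0], cfg.lk_levels)
    grads_prev = _gradients(pyr_prev)
    cur = seeds.copy()
    alive = np.ones(n, dtype=bool)
    for t in range(1, t_total):
        pyr_next = _pyramid(stack[t], cfg.lk_levels)
        if alive.any():
            new_pts, ok = _lk_pair(pyr_prev, grads_prev, pyr_next, cur[alive], cfg)
            idx = np.flatnonzero(alive)
            cur[idx] = new_pts
            lost = idx[~ok]
            alive[lost] = False
            keep = idx[ok]
            positions[keep, t] = new_pts[ok]
            valid[keep, t] = True
        pyr_prev = pyr_next
        grads_prev = _gradients(pyr_next)
    return TrajectorySet(positions=positions, valid=valid, fps=float(fps))


def differentiate(traj: TrajectorySet) -> MotionSignals:
    """First time-difference of every fully valid trajectory, per axis.

    Differencing removes the (slowly varying) absolute position so that the
    periodic chest displacement dominates; the result is unscaled (no fps
    factor) because the spectral stage is scale-invariant.
    """
    sel = traj.fully_valid()
    if not sel.any():
        raise DegenerateInputError("no trajectory remained valid over all frames")
    pos = traj.positions[sel]  # (M, T, 2)
    diff = np.diff(pos, axis=1)
    return MotionSignals(dx=diff[..., 0], dy=diff[..., 1], fps=traj.fps)
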