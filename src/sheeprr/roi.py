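"""ROI handling: detection filtering, masking, CLAHE enhancement,
segmentation-quality metrics and R1/R2/R3 region splitting.

Threshold comparisons are strict ("above" a threshold means ``>``): a
certainty of exactly 0.75 or a box IoU of exactly 0.80 is rejected.
Boxes use half-open, 0-based pixel coordinates ``(x0, y0, x1, y1)`` so that
areas are plain coordinate differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import exposure

from .exceptions import DegenerateInputError, FormatError, ParameterError
from .video_io import InstanceMask

log = logging.getLogger(__name__)

CERTAINTY_THRESHOLD = 0.75
IOU_BOX_THRESHOLD = 0.80

REGION_NAMES = ("total", "r1", "r2", "r3")


@dataclass(frozen=True)
class SegmentationScore:
    """Quality metrics of one detection: box IoU, mask IoU, detector certainty."""

    iou_bbox: float
    iou_mask: float
    certainty: float

    def __post_init__(self):
        for name in ("iou_bbox", "iou_mask", "certainty"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class RegionSpec:
    """A named sub-region of the thorax mask."""

    name: str
    mask: np.ndarray

    def __post_init__(self):
        if self.name not in REGION_NAMES:
            raise ParameterError(f"region name must be one of {REGION_NAMES}")


def filter_detections(
    instances: Sequence[InstanceMask], min_certainty: float = CERTAINTY_THRESHOLD
) -> list[InstanceMask]:
    """Keep instances whose certainty is strictly above the threshold."""
    kept = [m for m in instances if m.certainty > min_certainty]
    if instances and not kept:
        log.warning(
            "all %d detections below certainty threshold %.2f", len(instances), min_certainty
        )
    return kept


def iou_mask(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two binary masks of identical shape."""
    a = np.asarray(a) != 0
    b = np.asarray(b) != 0
    if a.shape != b.shape:
        raise FormatError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise DegenerateInputError("IoU undefined: both masks are empty")
    return float(np.logical_and(a, b).sum() / union)


def iou_box(a: Sequence[float], b: Sequence[float]) -> float:
    """Jaccard index of two half-open boxes ``(x0, y0, x1, y1)``."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    if ax1 < ax0 or ay1 < ay0 or bx1 < bx0 or by1 < by0:
        raise ParameterError("box coordinates must satisfy x0<=x1 and y0<=y1")
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = area_a + area_b - inter
    if union == 0:
        raise DegenerateInputError("IoU undefined: both boxes are empty")
    return float(inter / union)


def iou(a, b) -> float:
    """Dispatch to :func:`iou_mask` (2-D arrays) or :func:`iou_box` (4-tuples)."""
    if isinstance(a, np.ndarray) and a.ndim == 2:
        return iou_mask(a, b)
    return iou_box(a, b)


def valid_detection(
    score: SegmentationScore, iou_threshold: float = IOU_BOX_THRESHOLD
) -> bool:
    """A detection is a valid ROI iff its box IoU is strictly above threshold."""
    return score.iou_bbox > iou_threshold


def apply_mask(frame: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Multiply the frame by the binary mask: foreground kept, rest zeroed."""
    frame = np.asarray(frame)
    m = np.asarray(mask) != 0
    if frame.shape[:2] != m.shape:
        raise FormatError(f"frame shape {frame.shape[:2]} != mask shape {m.shape}")
    if frame.ndim == 3:
        m = m[..., None]
    return frame * m.astype(frame.dtype)


def enhance(
    frame: np.ndarray, tile: tuple[int, int] = (8, 8), clip: float = 2.0
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation of an 8-bit frame.

    ``tile`` is the grid of contextual blocks (rows, cols); ``clip`` is the
    clip limit expressed as a multiple of the uniform histogram height (the
    convention most CV toolchains use; internally rescaled to skimage's
    [0, 1] fraction as ``clip / 256``).  Output is uint8 spanning [0, 255].
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise FormatError("enhance expects a single-channel (grayscale) frame")
    h, w = frame.shape
    if tile[0] > h or tile[1] > w or tile[0] < 1 or tile[1] < 1:
        raise ParameterError(f"CLAHE tile grid {tile} invalid for image {frame.shape}")
    if frame.max() == frame.min():
        return frame.copy()  # nothing to equalise
    kernel = (max(1, h // tile[0]), max(1, w // tile[1]))
    out = exposure.equalize_adapthist(
        frame.astype(np.uint8), kernel_size=kernel, clip_limit=clip / 256.0
    )
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def split_regions(
    mask: np.ndarray, orientation: str = "r1_left"
) -> dict[str, RegionSpec]:
    """Partition a thorax mask into three equal bands along its long axis.

    The bounding box of the mask is cut perpendicular to its longer side
    into three equal-width bands.  R1 is the abdominal band: the
    low-coordinate end for ``r1_left``, the high end for ``r1_right``
    (lower row index counts as "left" when the long axis is vertical).
    R2 is always the middle band.  The three regions are pairwise disjoint
    and their union is exactly the input mask.
    """
    if orientation not in ("r1_left", "r1_right"):
        raise ParameterError(f"orientation must be r1_left or r1_right, got {orientation!r}")
    m = np.asarray(mask) != 0
    if m.ndim != 2 or not m.any():
        raise DegenerateInputError("split_regions needs a nonempty 2-D mask")
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    height = rows[-1] - rows[0] + 1
    width = cols[-1] - cols[0] + 1
    axis_len = max(height, width)
    if axis_len < 3:
        raise ParameterError("mask thinner than 3 pixels along its long axis")
    along_cols = width >= height  # tie -> horizontal long axis
    lo = cols[0] if along_cols else rows[0]
    edges = [lo + int(round(i * axis_len / 3.0)) for i in range(4)]

    bands = []
    idx = np.arange(m.shape[1] if along_cols else m.shape[0])
    for i in range(3):
        sel = (idx >= edges[i]) & (idx < edges[i + 1])
        band = m & (sel[None, :] if along_cols else sel[:, None])
        bands.append(band)
    if orientation == "r1_right":
        bands = bands[::-1]
    regions = {
        "total": RegionSpec("total", m.copy()),
        "r1": RegionSpec("r1", bands[0]),
        "r2": RegionSpec("r2", bands[1]),
        "r3": RegionSpec("r3", bands[2]),
    }
    return regions
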