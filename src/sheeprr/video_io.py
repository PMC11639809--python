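"""Reading and writing frame sequences, instance masks and result tables.

The on-disk dialects are deliberately plain: a video is either a directory of
sequentially numbered 8-bit PNG/TIFF frames or any container imageio can
decode; an instance mask is an 8-bit single-channel PNG (nonzero =
foreground) with an optional CSV sidecar carrying instance id, class label
and detector certainty; respiratory-rate series and agreement records are
CSV with a fixed header.  Image origin is top-left, ``x`` is the column
index and ``y`` the row index.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, FormatError, InputError

log = logging.getLogger(__name__)

#: ITU-R BT.601 luminance weights used for RGB -> grayscale conversion.
_BT601 = np.array([0.299, 0.587, 0.114])

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


@dataclass
class FrameSequence:
    """An ordered stack of equally sized 8-bit frames plus acquisition metadata.

    Parameters
    ----------
    frames:
        Array of shape ``(T, H, W)`` (grayscale) or ``(T, H, W, 3)`` (RGB),
        dtype uint8.
    fps:
        Acquisition frame rate in frames per second. The RGB stage of the
        reference acquisition ran at 20 fps, the NIR stage at 10 fps; the
        value is caller-supplied metadata and is never inferred.
    modality:
        ``"rgb"`` or ``"nir"``.
    source_id:
        Free-text label used in logs and output file names.
    """

    frames: np.ndarray
    fps: float
    modality: str = "rgb"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise FormatError(
                f"frames must be (T,H,W) or (T,H,W,3); got shape {self.frames.shape}"
            )
        if len(self.frames) < 2:
            raise FormatError("a frame sequence needs at least 2 frames")
        if self.fps <= 0:
            raise FormatError(f"fps must be positive, got {self.fps}")
        if self.modality not in ("rgb", "nir"):
            raise FormatError(f"modality must be 'rgb' or 'nir', got {self.modality!r}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @property
    def is_color(self) -> bool:
        return self.frames.ndim == 4

    def gray(self) -> np.ndarray:
        """Return the sequence as ``(T, H, W)`` uint8 luminance frames."""
        if not self.is_color:
            return self.frames
        y = np.tensordot(self.frames.astype(np.float64), _BT601, axes=([3], [0]))
        return np.clip(np.rint(y), 0, 255).astype(np.uint8)


@dataclass
class InstanceMask:
    """A binary region-of-interest mask for one detected instance."""

    mask: np.ndarray
    class_label: str = "thorax"
    certainty: float = 1.0
    instance_id: int = 0
    source_file: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask) != 0
        if self.mask.ndim != 2:
            raise FormatError(f"mask must be 2-D, got shape {self.mask.shape}")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    def require_foreground(self) -> None:
        """Raise if the mask has no foreground pixel (unusable for RR work)."""
        if self.n_foreground == 0:
            raise DegenerateInputError(
                f"instance {self.instance_id}: mask has no foreground pixels"
            )


def _numeric_sort_key(p: Path):
    m = re.search(r"(\d+)(?=\D*$)", p.stem)
    return (0, int(m.group(1)), p.name) if m else (1, 0, p.name)


def _list_frame_files(d: Path) -> list[Path]:
    files = [p for p in sorted(d.iterdir()) if p.suffix.lower() in _IMAGE_SUFFIXES]
    if not files:
        raise InputError(f"no image files found in directory {d}")
    keyed = sorted(files, key=_numeric_sort_key)
    if any(_numeric_sort_key(p)[0] == 1 for p in files):
        log.warning("non-numeric frame names in %s; falling back to lexicographic order", d)
    return keyed


def read_frame_sequence(
    path: str | Path, fps: float, modality: str = "rgb", source_id: str | None = None
) -> FrameSequence:
    """Read a frame directory or a video container into a :class:`FrameSequence`.

    Frames in a directory are ordered by the trailing number in their file
    name (zero-padded or not); names without a number fall back to
    lexicographic order with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file or directory: {path}")
    if path.is_dir():
        files = _list_frame_files(path)
        frames = []
        for f in files:
            try:
                frames.append(np.asarray(iio.imread(f)))
            except Exception as exc:  # pragma: no cover - backend specific
                raise InputError(f"unreadable frame file {f}: {exc}") from exc
        shapes = {a.shape for a in frames}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent frame sizes in {path}: {sorted(shapes)}")
        stack = np.stack(frames)
    else:
        try:
            stack = np.stack(list(iio.imiter(path)))
        except Exception as exc:
            raise InputError(f"unreadable video container {path}: {exc}") from exc
    if stack.ndim == 4 and stack.shape[-1] == 4:  # drop alpha
        stack = stack[..., :3]
    if stack.ndim == 4 and modality == "nir":
        # NIR sources are single-channel; collapse an RGB-saved gray triplet.
        stack = np.tensordot(stack.astype(np.float64), _BT601, axes=([3], [0]))
        stack = np.clip(np.rint(stack), 0, 255).astype(np.uint8)
    return FrameSequence(
        frames=stack.astype(np.uint8),
        fps=fps,
        modality=modality,
        source_id=source_id if source_id is not None else path.name,
    )


def write_frame_sequence(seq: FrameSequence, directory: str | Path) -> list[Path]:
    """Write each frame as ``frame_%05d.png``; returns the written paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(seq.frames):
        p = d / f"frame_{i:05d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def read_instance_masks(
    path: str | Path, sidecar: str | Path | None = None
) -> list[InstanceMask]:
    """Read one or more mask PNGs, optionally joined with a detection sidecar.

    ``path`` may be a single PNG or a directory of PNGs.  The sidecar is a
    CSV with columns ``instance_id,class_label,certainty,mask_file``; without
    one, certainty defaults to 1.0 and the class label to ``thorax``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such mask path: {path}")
    files = _list_frame_files(path) if path.is_dir() else [path]

    meta: dict[str, tuple[int, str, float]] = {}
    if sidecar is not None:
        df = pd.read_csv(sidecar)
        required = {"instance_id", "class_label", "certainty", "mask_file"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"sidecar {sidecar} missing columns: {sorted(missing)}")
        for row in df.itertuples(index=False):
            meta[str(row.mask_file)] = (
                int(row.instance_id),
                str(row.class_label),
                float(row.certainty),
            )

    out = []
    for i, f in enumerate(files):
        arr = np.asarray(iio.imread(f))
        if arr.ndim == 3:
            arr = arr[..., 0]
        inst_id, label, certainty = meta.get(f.name, (i, "thorax", 1.0))
        out.append(
            InstanceMask(
                mask=arr, class_label=label, certainty=certainty,
                instance_id=inst_id, source_file=f.name,
            )
        )
    return out


def write_instance_mask(mask: InstanceMask, path: str | Path) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(p, (mask.mask.astype(np.uint8)) * 255)


def check_mask_matches(mask: InstanceMask, seq: FrameSequence) -> None:
    if mask.mask.shape != seq.frame_shape:
        raise FormatError(
            f"mask shape {mask.mask.shape} != frame shape {seq.frame_shape}"
        )


# ---------------------------------------------------------------------------
# result tables

RR_COLUMNS = ["time_s", "rr_bpm", "rr_smoothed_bpm"]
AGREEMENT_COLUMNS = ["video_id", "region", "rr_ref", "rr_video", "abs_err", "rel_err_pct"]


def write_rr_series(series, path: str | Path) -> None:
    """Write an RR series as CSV (columns ``time_s,rr_bpm,rr_smoothed_bpm``)."""
    df = pd.DataFrame(
        {
            "time_s": np.asarray(series.times_s, dtype=float),
            "rr_bpm": np.asarray(series.rr_bpm, dtype=float),
            "rr_smoothed_bpm": np.asarray(series.rr_smoothed_bpm, dtype=float),
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_rr_series(path: str | Path):
    from .spectral import RRSeries  # local import to avoid a cycle

    df = pd.read_csv(path)
    missing = set(RR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"RR table {path} missing columns: {sorted(missing)}")
    return RRSeries(
        times_s=df["time_s"].to_numpy(float),
        rr_bpm=df["rr_bpm"].to_numpy(float),
        rr_smoothed_bpm=df["rr_smoothed_bpm"].to_numpy(float),
    )


def write_agreement_table(records: Iterable, path: str | Path) -> None:
    """Write agreement records as CSV (see ``AGREEMENT_COLUMNS``)."""
    rows = [
        {
            "video_id": r.video_id,
            "region": r.region,
            "rr_ref": r.rr_ref,
            "rr_video": r.rr_video,
            "abs_err": r.abs_err,
            "rel_err_pct": r.rel_err_pct,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=AGREEMENT_COLUMNS)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_agreement_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(AGREEMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"agreement table {path} missing columns: {sorted(missing)}")
    return df
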