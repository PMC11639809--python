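"""Synthetic breathing-video generator with known ground truth.

Real recordings of resting sheep are rarely shareable, so every downstream
stage is exercised on synthetic scenes: a speckle-textured elliptical
"thorax" whose boundary expands and contracts radially at a chosen
respiratory frequency.  The radial displacement is tapered linearly along
the long axis so the abdominal end moves more than the cranial end, which
reproduces the empirical ordering of signal strength across the R1/R2/R3
sub-regions of a recumbent animal.  Sensor noise and slow illumination
drift are added per frame; a fixed seed makes every output bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .exceptions import ParameterError
from .video_io import FrameSequence, InstanceMask

#: Default additive sensor noise (gray levels) per modality.  NIR night
#: footage is noisier and flatter than daytime RGB.
DEFAULT_NOISE_SD = {"rgb": 2.0, "nir": 4.0}
#: Foreground texture contrast (speckle sd in gray levels) per modality.
_TEXTURE_SD = {"rgb": 28.0, "nir": 18.0}
_FOREGROUND_LEVEL = {"rgb": 150.0, "nir": 120.0}
_BACKGROUND_LEVEL = 40.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic breathing scene.

    ``rr_bpm`` is the true respiratory rate (breaths/min); healthy resting
    sheep sit around 20-40 bpm, i.e. 0.33-0.67 Hz.  ``amplitude_px`` is the
    peak radial boundary displacement; ``amplitude_gradient`` is the
    fraction of that amplitude retained at the cranial end (1.0 = uniform
    motion, small values = strongly abdominal breathing).
    """

    duration_s: float = 30.0
    fps: float = 20.0
    rr_bpm: float = 27.0
    amplitude_px: float = 3.0
    amplitude_gradient: float = 0.3
    noise_sd: Optional[float] = None  # None -> modality default
    drift_per_s: float = 0.0
    seed: int = 0
    modality: str = "rgb"
    image_size: tuple[int, int] = (120, 160)
    center: Optional[tuple[float, float]] = None  # (row, col); None -> image centre
    axes: Optional[tuple[float, float]] = None  # (semi_row, semi_col); None -> auto

    def __post_init__(self):
        if self.fps <= 2.0 * self.rr_bpm / 60.0:
            raise ParameterError(
                f"fps={self.fps} violates Nyquist for rr_bpm={self.rr_bpm} "
                f"({self.rr_bpm / 60.0:.3f} Hz)"
            )
        if self.modality not in ("rgb", "nir"):
            raise ParameterError(f"modality must be 'rgb' or 'nir', got {self.modality!r}")
        if not 0.0 <= self.amplitude_gradient <= 1.0:
            raise ParameterError("amplitude_gradient must be in [0, 1]")
        if self.duration_s <= 0 or self.amplitude_px < 0:
            raise ParameterError("duration_s must be > 0 and amplitude_px >= 0")

    @property
    def freq_hz(self) -> float:
        return self.rr_bpm / 60.0

    @property
    def n_frames(self) -> int:
        return max(2, int(round(self.duration_s * self.fps)))

    @property
    def resolved_noise_sd(self) -> float:
        return DEFAULT_NOISE_SD[self.modality] if self.noise_sd is None else self.noise_sd

    def geometry(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Resolved (center, semiaxes) in (row, col) order."""
        h, w = self.image_size
        c = self.center if self.center is not None else (h / 2.0, w / 2.0)
        a = self.axes if self.axes is not None else (0.32 * h, 0.40 * w)
        return c, a


def boundary_displacement(spec: SyntheticSpec) -> np.ndarray:
    """Radial displacement of the abdominal-end boundary, one value per frame."""
    t = np.arange(spec.n_frames) / spec.fps
    return spec.amplitude_px * np.sin(2.0 * np.pi * spec.freq_hz * t)


def _texture(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Wool-like speckle template (float, gray levels) over the full canvas."""
    h, w = spec.image_size
    speckle = rng.uniform(-1.0, 1.0, size=(h, w))
    speckle = gaussian_filter(speckle, sigma=1.2)
    speckle *= _TEXTURE_SD[spec.modality] / max(speckle.std(), 1e-12)
    return _FOREGROUND_LEVEL[spec.modality] + speckle


def _ellipse_fields(spec: SyntheticSpec):
    """Per-pixel normalised elliptical radius rho and amplitude taper.

    rho is 1.0 on the resting boundary; the taper runs from 1.0 at the
    abdominal (left) end of the ellipse to ``amplitude_gradient`` at the
    cranial (right) end.
    """
    h, w = spec.image_size
    (cy, cx), (ay, ax) = spec.geometry()
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    rho = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    u = np.clip((xx - (cx - ax)) / (2.0 * ax), 0.0, 1.0)
    taper = 1.0 - (1.0 - spec.amplitude_gradient) * u
    # Distance from centre to resting boundary along each pixel's direction.
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_boundary = np.where(rho > 1e-9, r / np.maximum(rho, 1e-9), np.inf)
    return yy, xx, rho, taper, r_boundary


def _warped_frame(template, spec, fields, phase_sin):
    """Warp the template so the boundary sits at rho=1 + taper*amp*sin/R."""
    (cy, cx), _ = spec.geometry()
    yy, xx, rho, taper, r_boundary = fields
    scale = 1.0 + (taper * spec.amplitude_px * phase_sin) / r_boundary
    inv = 1.0 / np.maximum(scale, 1e-6)
    src_y = cy + (yy - cy) * inv
    src_x = cx + (xx - cx) * inv
    warped = map_coordinates(template, [src_y, src_x], order=1, mode="nearest")
    # Foreground support: material boundary is at rho = scale.
    support = rho <= np.maximum(scale, 1e-6)
    return warped, support


def _render(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Render the grayscale stack (T, H, W) in float gray levels, no noise."""
    template = _texture(spec, rng)
    fields = _ellipse_fields(spec)
    t = np.arange(spec.n_frames) / spec.fps
    phases = np.sin(2.0 * np.pi * spec.freq_hz * t)
    h, w = spec.image_size
    stack = np.empty((spec.n_frames, h, w), dtype=np.float64)
    for i, ph in enumerate(phases):
        warped, support = _warped_frame(template, spec, fields, ph)
        frame = np.full((h, w), _BACKGROUND_LEVEL)
        frame[support] = warped[support]
        stack[i] = frame
    return stack


def _finalize(stack: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Add drift + sensor noise and quantise to uint8 (RGB -> 3 channels)."""
    t = np.arange(len(stack)) / spec.fps
    stack = stack.astype(np.float32) + (spec.drift_per_s * t)[:, None, None].astype(np.float32)
    sd = np.float32(spec.resolved_noise_sd)
    if spec.modality == "rgb":
        gains = np.array([1.0, 0.97, 0.94], dtype=np.float32)
        rgb = stack[..., None] * gains
        rgb += rng.standard_normal(rgb.shape, dtype=np.float32) * sd
        return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    gray = stack + rng.standard_normal(stack.shape, dtype=np.float32) * sd
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def resting_mask(spec: SyntheticSpec) -> np.ndarray:
    """The thorax region at mid-expansion (phase 0): the resting ellipse."""
    rho = _ellipse_fields(spec)[2]
    return rho <= 1.0


def generate_breathing_video(
    spec: SyntheticSpec,
) -> tuple[FrameSequence, InstanceMask, np.ndarray]:
    """Generate one breathing scene.

    Returns
    -------
    (frames, mask, truth):
        ``frames`` is a :class:`FrameSequence` at ``spec.fps``; ``mask`` the
        thorax region at mid-expansion; ``truth`` a per-frame array holding
        the constant true RR in breaths/min.
    """
    rng = np.random.default_rng(spec.seed)
    stack = _render(spec, rng)
    frames = _finalize(stack, spec, rng)
    seq = FrameSequence(
        frames=frames, fps=spec.fps, modality=spec.modality,
        source_id=f"synth_rr{spec.rr_bpm:g}_fps{spec.fps:g}_seed{spec.seed}",
    )
    mask = InstanceMask(mask=resting_mask(spec), class_label="thorax",
                        certainty=1.0, instance_id=0)
    truth = np.full(spec.n_frames, float(spec.rr_bpm))
    return seq, mask, truth


def _max_footprint(spec: SyntheticSpec) -> np.ndarray:
    """Support of the instance at maximal expansion plus a safety margin."""
    rho = _ellipse_fields(spec)[2]
    (cy, cx), (ay, ax) = spec.geometry()
    margin = (spec.amplitude_px + 2.0) / min(ay, ax)
    return rho <= 1.0 + margin


def generate_two_instance_scene(
    spec_a: SyntheticSpec, spec_b: SyntheticSpec
) -> tuple[FrameSequence, tuple[InstanceMask, InstanceMask]]:
    """Two independently breathing instances on one canvas.

    The specs must share ``image_size``, ``fps``, ``duration_s`` and
    ``modality`` and their (maximally expanded) regions must be disjoint.
    """
    for attr in ("image_size", "fps", "duration_s", "modality"):
        if getattr(spec_a, attr) != getattr(spec_b, attr):
            raise ParameterError(f"specs disagree on {attr}")
    if (_max_footprint(spec_a) & _max_footprint(spec_b)).any():
        raise ParameterError("instance regions overlap (including breathing margin)")

    rng_a = np.random.default_rng(spec_a.seed)
    rng_b = np.random.default_rng(spec_b.seed)
    stack_a = _render(spec_a, rng_a)
    stack_b = _render(spec_b, rng_b)
    h, w = spec_a.image_size
    canvas = np.full((spec_a.n_frames, h, w), _BACKGROUND_LEVEL)
    sup_a = _max_footprint(spec_a)
    sup_b = _max_footprint(spec_b)
    canvas[:, sup_a] = stack_a[:, sup_a]
    canvas[:, sup_b] = stack_b[:, sup_b]
    # Scene-level noise/drift comes from spec_a's stream, after both renders.
    frames = _finalize(canvas, spec_a, rng_a)
    seq = FrameSequence(
        frames=frames, fps=spec_a.fps, modality=spec_a.modality,
        source_id=f"synth_two_{spec_a.rr_bpm:g}_{spec_b.rr_bpm:g}",
    )
    masks = (
        InstanceMask(mask=resting_mask(spec_a), instance_id=0),
        InstanceMask(mask=resting_mask(spec_b), instance_id=1),
    )
    return seq, masks
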