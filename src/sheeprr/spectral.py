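"""From motion signals to a respiratory signal and an RR time series.

The chain is: band-pass every trajectory derivative to the physiological
band (0.33-0.67 Hz, i.e. 19.8-40.2 breaths/min), decompose the stack with
PCA, pick one component as the respiratory signal, then slide a 10 s window
frame by frame and read the dominant in-band frequency of each window off a
zero-padded FFT.  A moving-average convolution yields the smoothed curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import PCA

from .exceptions import DegenerateInputError, ParameterError
from .tracking import MotionSignals

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandpassConfig:
    """Butterworth band-pass design: cut-offs in Hz and filter order.

    The defaults bracket the resting ovine respiratory band: 0.33 Hz
    (19.8 bpm) to 0.67 Hz (40.2 bpm).
    """

    low_hz: float = 0.33
    high_hz: float = 0.67
    order: int = 2

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ParameterError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ParameterError("order must be >= 1")

    def validate_fps(self, fps: float) -> None:
        if self.high_hz >= fps / 2.0:
            raise ParameterError(
                f"high_hz={self.high_hz} at or above Nyquist ({fps / 2.0} Hz)"
            )


@dataclass
class RespiratorySignal:
    """A 1-D band-limited motion component at the video frame rate.

    ``component_index`` is the 1-based rank of the chosen principal
    component (1 = largest explained variance).
    """

    samples: np.ndarray
    fps: float
    component_index: int = 1

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ParameterError("RespiratorySignal expects a 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("RespiratorySignal samples must be finite")


@dataclass
class RRSeries:
    """Per-window RR estimates plus the convolution-smoothed curve.

    ``times_s`` are window-end times in seconds; RR values are in
    breaths/min.  One estimate per window position, windows advancing one
    frame at a time.
    """

    times_s: np.ndarray
    rr_bpm: np.ndarray
    rr_smoothed_bpm: np.ndarray
    window_s: float = 10.0
    fps: float | None = None

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.rr_bpm = np.asarray(self.rr_bpm, dtype=np.float64)
        self.rr_smoothed_bpm = np.asarray(self.rr_smoothed_bpm, dtype=np.float64)
        if not len(self.times_s) == len(self.rr_bpm) == len(self.rr_smoothed_bpm):
            raise ParameterError("RRSeries arrays must have equal length")

    def __len__(self) -> int:
        return len(self.rr_bpm)


@dataclass
class PCAResult:
    """Principal-component scores over time, ordered by explained variance."""

    components: np.ndarray  # (k, T) score time series
    explained_variance: np.ndarray  # (k,)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def bandpass(x: np.ndarray, fps: float, cfg: BandpassConfig = BandpassConfig()) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a 1-D (or row-wise 2-D) signal.

    Forward-backward (``sosfiltfilt``) application keeps windowed estimates
    free of phase lag; the effective magnitude response is the squared
    design response.
    """
    cfg.validate_fps(fps)
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    if n < 3 * (2 * cfg.order + 1):
        raise ParameterError(f"signal too short ({n}) for order-{cfg.order} filtering")
    sos = sps.butter(cfg.order, [cfg.low_hz, cfg.high_hz], btype="bandpass",
                     fs=fps, output="sos")
    default_pad = 3 * (2 * len(sos) + 1)
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=min(default_pad, n - 1))


def pca_decompose(motion: MotionSignals, n_components: int = 6) -> PCAResult:
    """PCA over the stacked horizontal and vertical derivative signals.

    The data matrix has one variable per signal (2M variables: every dx row
    then every dy row, each mean-centred) and one observation per time
    sample.  The returned component scores are the candidate respiratory
    signals, strongest variance first.  If fewer signals than requested
    components exist, all available components are returned.
    """
    x = np.vstack([motion.dx, motion.dy]).astype(np.float64)  # (2M, T)
    if x.shape[0] < 2:
        raise DegenerateInputError("PCA needs at least two motion signals")
    k = min(n_components, x.shape[0], x.shape[1])
    if k < n_components:
        log.info("pca_decompose: only %d components available (%d requested)",
                 k, n_components)
    x = x - x.mean(axis=1, keepdims=True)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x.T)  # (T, k)
    return PCAResult(components=scores.T, explained_variance=pca.explained_variance_)


def total_variance(motion: MotionSignals) -> float:
    """Total variance of the stacked, mean-centred signal matrix
    (the quantity the explained variances of a full PCA sum to)."""
    x = np.vstack([motion.dx, motion.dy]).astype(np.float64)
    x = x - x.mean(axis=1, keepdims=True)
    return float(np.sum(np.var(x, axis=1, ddof=1)))


def _inband_ratio(comp: np.ndarray, fps: float, cfg: BandpassConfig) -> float:
    spec = np.abs(np.fft.rfft(comp - comp.mean())) ** 2
    freqs = np.fft.rfftfreq(len(comp), d=1.0 / fps)
    total = spec.sum()
    if total <= 0:
        return 0.0
    band = (freqs >= cfg.low_hz) & (freqs <= cfg.high_hz)
    if not band.any():
        return 0.0
    return float(spec[band].max() / total)


def select_component(
    pca: PCAResult,
    fps: float,
    cfg: BandpassConfig = BandpassConfig(),
    strategy: Literal["first", "best_inband"] = "first",
) -> RespiratorySignal:
    """Choose the respiratory signal among the leading principal components.

    ``first`` takes component 1 — in practice the chest contraction/
    relaxation pattern already dominates the first component.
    ``best_inband`` scans the first six components and keeps the one whose
    spectrum concentrates the most power at a single in-band peak.
    """
    if pca.n_components < 1:
        raise DegenerateInputError("no components to select from")
    if strategy == "first":
        idx = 0
    elif strategy == "best_inband":
        candidates = min(6, pca.n_components)
        ratios = [
            _inband_ratio(pca.components[i], fps, cfg) for i in range(candidates)
        ]
        idx = int(np.argmax(ratios))
    else:
        raise ParameterError(f"unknown strategy {strategy!r}")
    comp = pca.components[idx]
    return RespiratorySignal(samples=comp - comp.mean(), fps=fps,
                             component_index=idx + 1)


def estimate_rr(
    sig: RespiratorySignal,
    window_s: float = 10.0,
    pad_len: int = 4096,
    band: BandpassConfig = BandpassConfig(),
) -> RRSeries:
    """Windowed dominant-frequency RR estimation.

    For every window position (stride one frame): linear detrend, zero-pad
    to ``pad_len``, magnitude FFT, and the dominant frequency is the argmax
    restricted to [low_hz, high_hz] (ties resolved toward the lower
    frequency).  RR = 60 * f_peak.  The smoothed curve is initialised to
    the raw estimates; apply :func:`smooth_rr` to replace it.
    """
    x = np.asarray(sig.samples, dtype=np.float64)
    fps = sig.fps
    w = int(round(window_s * fps))
    if w < 2:
        raise ParameterError(f"window_s={window_s} too short at fps={fps}")
    if len(x) < w:
        raise DegenerateInputError(
            f"signal length {len(x)} shorter than one {w}-frame window"
        )
    if pad_len < w:
        raise ParameterError("pad_len must be at least the window length")
    windows = np.lib.stride_tricks.sliding_window_view(x, w)  # (T-w+1, w)
    windows = sps.detrend(windows, axis=1, type="linear")
    spec = np.abs(np.fft.rfft(windows, n=pad_len, axis=1))
    freqs = np.fft.rfftfreq(pad_len, d=1.0 / fps)
    band_sel = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    if not band_sel.any():
        raise ParameterError("no FFT bin inside the pass band; increase pad_len")
    band_idx = np.flatnonzero(band_sel)
    peak = band_idx[np.argmax(spec[:, band_idx], axis=1)]  # argmax: first max -> lower f
    rr = 60.0 * freqs[peak]
    starts = np.arange(len(rr))
    times = (starts + w - 1) / fps
    return RRSeries(times_s=times, rr_bpm=rr, rr_smoothed_bpm=rr.copy(),
                    window_s=window_s, fps=fps)


def smooth_rr(series: RRSeries, kernel_s: float = 10.0) -> RRSeries:
    """Moving-average smoothing of the per-window RR curve.

    The kernel spans ``kernel_s`` seconds (capped at the series length) and
    is edge-normalised: partial windows at the borders are divided by the
    actual overlap, so the output has the series' own length and constant
    series are fixed points.
    """
    if len(series) == 0:
        raise DegenerateInputError("cannot smooth an empty RR series")
    fps = series.fps if series.fps else 1.0 / max(
        np.median(np.diff(series.times_s)) if len(series) > 1 else 1.0, 1e-9
    )
    k = int(round(kernel_s * fps))
    k = max(1, min(k, len(series)))
    kernel = np.ones(k)
    num = np.convolve(series.rr_bpm, kernel, mode="same")
    den = np.convolve(np.ones(len(series)), kernel, mode="same")
    return replace(series, rr_smoothed_bpm=num / den)
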