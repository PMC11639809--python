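"""Agreement statistics between reference and video-derived respiratory rates.

Conventions: the absolute error of a pair is |RR_ref - RR_video| in
breaths/min and the relative error is that error as a percentage of the
reference (the expert count).  Bland-Altman differences are taken as
reference minus video, spread quantified by the sample standard deviation
(ddof=1) and the limits of agreement as mean +/- 1.96 SD.  Everything is
computed at full precision; rounding is for display only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, ParseError

Pair = tuple[float, float]  # (rr_ref, rr_video)


@dataclass(frozen=True)
class AgreementRecord:
    """One paired comparison of reference and video RR."""

    video_id: str
    region: str
    rr_ref: float
    rr_video: float
    abs_err: float
    rel_err_pct: float

    @classmethod
    def from_pair(
        cls, rr_ref: float, rr_video: float, video_id: str = "", region: str = "total"
    ) -> "AgreementRecord":
        if rr_ref <= 0:
            raise DegenerateInputError(f"rr_ref must be positive, got {rr_ref}")
        abs_err = abs(rr_ref - rr_video)
        return cls(
            video_id=video_id,
            region=region,
            rr_ref=float(rr_ref),
            rr_video=float(rr_video),
            abs_err=abs_err,
            rel_err_pct=100.0 * abs_err / rr_ref,
        )


@dataclass(frozen=True)
class AgreementSummary:
    mean_abs_err: float
    mean_rel_err_pct: float
    records: tuple[AgreementRecord, ...]


@dataclass(frozen=True)
class BlandAltman:
    """Mean difference (ref - video) and 95% limits of agreement."""

    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float


@dataclass(frozen=True)
class CoverageReport:
    total_duration_s: int
    rest_duration_s: int
    coverage_pct: float


def agreement(
    pairs: Sequence[Pair],
    video_ids: Sequence[str] | None = None,
    region: str = "total",
) -> AgreementSummary:
    """Per-pair and mean absolute/relative errors for (ref, video) pairs."""
    if len(pairs) == 0:
        raise DegenerateInputError("agreement needs at least one pair")
    ids = video_ids if video_ids is not None else [str(i + 1) for i in range(len(pairs))]
    records = tuple(
        AgreementRecord.from_pair(r, v, video_id=str(i), region=region)
        for (r, v), i in zip(pairs, ids)
    )
    return AgreementSummary(
        mean_abs_err=float(np.mean([r.abs_err for r in records])),
        mean_rel_err_pct=float(np.mean([r.rel_err_pct for r in records])),
        records=records,
    )


def pearson(pairs: Sequence[Pair]) -> float:
    """Product-moment correlation between reference and video RR."""
    if len(pairs) < 3:
        raise DegenerateInputError("pearson needs at least 3 pairs")
    a = np.asarray(pairs, dtype=np.float64)
    if np.ptp(a[:, 0]) == 0 or np.ptp(a[:, 1]) == 0:
        raise DegenerateInputError("pearson undefined: zero variance on one side")
    return float(stats.pearsonr(a[:, 0], a[:, 1]).statistic)


def bland_altman(pairs: Sequence[Pair]) -> BlandAltman:
    """Bland-Altman agreement of (ref, video) pairs; differences ref - video."""
    if len(pairs) < 2:
        raise DegenerateInputError("bland_altman needs at least 2 pairs")
    a = np.asarray(pairs, dtype=np.float64)
    d = a[:, 0] - a[:, 1]
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        mean_diff=mean, loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd, sd_diff=sd
    )


def parse_duration(token: str) -> int:
    """Parse ``H:M:S`` or ``M:S`` into whole seconds."""
    parts = str(token).strip().split(":")
    if len(parts) not in (2, 3) or not all(p.isdigit() for p in parts):
        raise ParseError(f"malformed duration {token!r} (expected H:M:S or M:S)")
    vals = [int(p) for p in parts]
    if len(parts) == 2:
        m, s = vals
        h = 0
    else:
        h, m, s = vals
    if m >= 60 or s >= 60:
        raise ParseError(f"malformed duration {token!r}: minutes/seconds must be < 60")
    return h * 3600 + m * 60 + s


def coverage(
    durations_total: Iterable[str], durations_rest: Iterable[str]
) -> CoverageReport:
    """Fraction of recorded sheep-in-scene time usable for RR estimation."""
    total = sum(parse_duration(t) for t in durations_total)
    rest = sum(parse_duration(t) for t in durations_rest)
    if total <= 0:
        raise DegenerateInputError("total duration must be positive")
    if rest > total:
        raise DegenerateInputError("rest duration exceeds total duration")
    return CoverageReport(
        total_duration_s=total,
        rest_duration_s=rest,
        coverage_pct=100.0 * rest / total,
    )
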