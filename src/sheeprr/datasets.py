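"""Bundled reference tables from a two-stage sheep monitoring validation study.

Stage one filmed a single post-surgical sheep with an RGB camera (20 fps)
and compares video-derived RR against the mean of four experts' visual
counts, for the whole thorax and its R1/R2/R3 sub-regions.  Stage two
filmed five sheep overnight with a NIR camera (10 fps); each of the 36 rows
is one sheep in one video segment, compared against a single expert's
count.  A third table carries the stage-two footage durations used for the
rest-coverage statistic.

These tables are inputs for the evaluation statistics; nothing in the
package is fitted to them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import CoverageReport, coverage


def _read(name: str) -> pd.DataFrame:
    with resources.files("sheeprr.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_rgb_reference() -> pd.DataFrame:
    """Stage-one (RGB) per-video, per-region reference vs video RR."""
    return _read("rgb_reference.csv")


def load_nir_reference() -> pd.DataFrame:
    """Stage-two (NIR) per-observation reference vs video RR (36 rows)."""
    return _read("nir_reference.csv")


def rgb_pairs(region: str = "total") -> list[tuple[float, float]]:
    """(rr_ref, rr_video) pairs of the RGB stage for one region."""
    df = load_rgb_reference()
    sub = df[df["region"] == region]
    if sub.empty:
        raise KeyError(f"unknown region {region!r}")
    return list(zip(sub["rr_ref"], sub["rr_video"]))


def nir_pairs() -> list[tuple[float, float]]:
    """(rr_ref, rr_video) pairs of the NIR stage."""
    df = load_nir_reference()
    return list(zip(df["rr_ref"], df["rr_video"]))


def study_coverage() -> CoverageReport:
    """Rest-coverage report computed from the stage-two footage durations."""
    df = _read("coverage_durations.csv").set_index("phase")["duration"]
    return coverage([df["sheep_in_scene"]], [df["at_rest"]])
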