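"""Hierarchical accumulation/dissipation rates and inter-nadir intervals.

Each iteration level partitions its span into segments that run
nadir -> peak -> nadir.  Rise amplitude over rise duration generalises
the secretory rate (accumulation rate), fall amplitude over fall
duration generalises the clearance rate (dissipation rate), and the
nadir-to-nadir time generalises the interpulse interval.  At level 1
these are analogous to — not estimates of — pharmacokinetic constants,
because secretion and clearance are treated as temporally distinct
within a segment and no deconvolution is attempted.

A level with m nadirs yields m - 1 segments, hence m - 1 of each rate
and m - 1 intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .classify import FeaturePoint
from .parser import HapResult

__all__ = [
    "RiseFallSegment",
    "RegressionSummary",
    "extract_segments",
    "compute_rates",
    "fit_rate_regression",
    "multiscale_summary",
]


@dataclass(frozen=True)
class RiseFallSegment:
    """A nadir -> peak -> nadir stretch at one iteration level."""

    level: int
    nadir_start: FeaturePoint
    peak: FeaturePoint
    nadir_end: FeaturePoint

    def __post_init__(self) -> None:
        if not self.nadir_start.time < self.peak.time < self.nadir_end.time:
            raise ValueError("segment points must be time-ordered nadir < peak < nadir")

    @property
    def rise_duration(self) -> float:
        return self.peak.time - self.nadir_start.time

    @property
    def fall_duration(self) -> float:
        return self.nadir_end.time - self.peak.time

    @property
    def rise_amplitude(self) -> float:
        return self.peak.value - self.nadir_start.value

    @property
    def fall_amplitude(self) -> float:
        return self.peak.value - self.nadir_end.value

    @property
    def accumulation_rate(self) -> float:
        """Rise amplitude / rise duration, µg/(dL·min)."""
        return self.rise_amplitude / self.rise_duration

    @property
    def dissipation_rate(self) -> float:
        """Fall amplitude / fall duration, µg/(dL·min)."""
        return self.fall_amplitude / self.fall_duration

    @property
    def internadir_interval(self) -> float:
        """Nadir-to-nadir time in minutes."""
        return self.nadir_end.time - self.nadir_start.time


@dataclass(frozen=True)
class RegressionSummary:
    """OLS of amplitude (µg/dL) on duration (min), intercept included."""

    side: str                       # "rise" or "fall"
    slope: float                    # µg/(dL·min)
    intercept: Optional[float]
    ci95: Optional[tuple[float, float]]
    r2: Optional[float]
    n: int


def extract_segments(hap: HapResult, level: int) -> list[RiseFallSegment]:
    """Ordered nadir->peak->nadir segments of one iteration level.

    A level with fewer than 2 nadirs (e.g. the terminal iteration of a
    monotone series) yields no segments.
    """
    lv = hap.level(level)
    segments = []
    for a, b in zip(lv.nadirs, lv.nadirs[1:]):
        between = [p for p in lv.peaks if a.index < p.index < b.index]
        # the parser guarantees exactly one peak between consecutive nadirs
        segments.append(RiseFallSegment(level, a, between[0], b))
    return segments


_COLUMNS = [
    "level",
    "t_nadir_start",
    "t_peak",
    "t_nadir_end",
    "rise_duration",
    "fall_duration",
    "internadir_interval",
    "rise_amplitude",
    "fall_amplitude",
    "accumulation_rate",
    "dissipation_rate",
]


def compute_rates(segments: list[RiseFallSegment]) -> pd.DataFrame:
    """Per-segment rate table (one row per segment, ordered in time)."""
    rows = [
        (
            s.level,
            s.nadir_start.time,
            s.peak.time,
            s.nadir_end.time,
            s.rise_duration,
            s.fall_duration,
            s.internadir_interval,
            s.rise_amplitude,
            s.fall_amplitude,
            s.accumulation_rate,
            s.dissipation_rate,
        )
        for s in segments
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def fit_rate_regression(
    segments: list[RiseFallSegment], side: str
) -> RegressionSummary:
    """Regress amplitude on duration for the rises or the falls.

    The slope is the level's average accumulation (rise) or dissipation
    (fall) rate; with fewer than 3 segments only the slope is reported
    (no confidence interval or R²).
    """
    if side not in ("rise", "fall"):
        raise ValueError("side must be 'rise' or 'fall'")
    if not segments:
        raise ValueError("no segments to fit")
    if side == "rise":
        x = np.array([s.rise_duration for s in segments])
        y = np.array([s.rise_amplitude for s in segments])
    else:
        x = np.array([s.fall_duration for s in segments])
        y = np.array([s.fall_amplitude for s in segments])
    n = len(segments)
    if n < 3:
        slope = float(np.polyfit(x, y, 1)[0]) if n == 2 and x[0] != x[1] else float(
            y[0] / x[0]
        )
        return RegressionSummary(side, slope, None, None, None, n)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = model.conf_int(alpha=0.05)[1]
    return RegressionSummary(
        side,
        float(model.params[1]),
        float(model.params[0]),
        (float(lo), float(hi)),
        float(model.rsquared),
        n,
    )


def multiscale_summary(hap: HapResult) -> pd.DataFrame:
    """Per-level min/median/max of durations, intervals and amplitudes.

    Rows are the pulse-bearing iteration levels; the median of exactly
    two values is their mean (the numpy convention).  The median
    inter-nadir interval is also reported in hours: these are the
    parse's time-scale components (pulse scale at level 1, ultradian
    scales above it).
    """
    quantities = [
        "rise_duration",
        "fall_duration",
        "internadir_interval",
        "rise_amplitude",
        "fall_amplitude",
    ]
    rows = []
    for lv in hap.levels:
        segs = extract_segments(hap, lv.level)
        if not segs:
            continue
        table = compute_rates(segs)
        row: dict[str, float] = {"level": lv.level, "n_segments": len(segs)}
        for q in quantities:
            row[f"{q}_min"] = float(table[q].min())
            row[f"{q}_median"] = float(table[q].median())
            row[f"{q}_max"] = float(table[q].max())
        row["internadir_interval_median_h"] = row["internadir_interval_median"] / 60.0
        rows.append(row)
    return pd.DataFrame(rows)
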