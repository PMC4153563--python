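"""The nadir selection algorithm: recursive hierarchical decomposition.

One iteration classifies every interior point, collapses plateau spans,
and keeps the nadir-class points {N, DF, FR}.  The sub-series formed by
the first sample, the selected nadirs and the last sample is then
re-parsed, at the original (now non-uniform) times, until an iteration
finds no interior peak — i.e. no rise-and-fall remains.  The resulting
hierarchy of levels is the complete parse of the series: level-1 nadirs
bound individual pulses, deeper levels bound clusters of pulses.

Everything here is deterministic; identical input yields an identical
parse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .classify import FeatureLabel, FeaturePoint, label_values
from .series_io import HormoneSeries

__all__ = [
    "BoundaryFlank",
    "IterationLevel",
    "HapResult",
    "HapConvergenceError",
    "collapse_plateaus",
    "select_nadirs",
    "select_peaks",
    "run_hap",
]


class HapConvergenceError(RuntimeError):
    """Internal-consistency failure: the recursion stopped contracting."""


@dataclass(frozen=True)
class BoundaryFlank:
    """A maximal monotone run at a series boundary (no pulse inside it)."""

    symbol: str        # ">" falling lead-in, "<" rising tail
    t_start: float
    t_end: float


def collapse_plateaus(
    features: list[FeaturePoint],
) -> list[tuple[str, FeaturePoint]]:
    """Collapse plateau spans and classify every feature as nadir or peak.

    A down-flat-up span (DF ... FR) acts as one broad nadir and an
    up-flat-down span (RF ... FD) as one broad peak; both are represented
    by their first sample.  Staircase spans (down-flat-down, up-flat-up)
    are not extrema as a whole: their DF/FR ends stay nadir-class and
    RF/FD ends peak-class, which preserves nadir/peak alternation.
    Plain R, D and F points carry no event.
    """
    events: list[tuple[str, FeaturePoint]] = []
    i = 0
    n = len(features)
    while i < n:
        f = features[i]
        lab = f.label
        if lab is FeatureLabel.N:
            events.append(("nadir", f))
        elif lab is FeatureLabel.P:
            events.append(("peak", f))
        elif lab is FeatureLabel.DF:
            j = i + 1
            while j < n and features[j].label is FeatureLabel.F:
                j += 1
            events.append(("nadir", f))
            if j < n and features[j].label is FeatureLabel.FR:
                i = j  # broad nadir: swallow the FR terminus
        elif lab is FeatureLabel.RF:
            j = i + 1
            while j < n and features[j].label is FeatureLabel.F:
                j += 1
            events.append(("peak", f))
            if j < n and features[j].label is FeatureLabel.FD:
                i = j  # broad peak: swallow the FD terminus
        elif lab is FeatureLabel.FR:
            events.append(("nadir", f))
        elif lab is FeatureLabel.FD:
            events.append(("peak", f))
        i += 1
    return events


def select_nadirs(features: list[FeaturePoint]) -> list[FeaturePoint]:
    """Nadir-class points {N, DF, FR} after plateau collapsing, in order."""
    return [f for kind, f in collapse_plateaus(features) if kind == "nadir"]


def select_peaks(features: list[FeaturePoint]) -> list[FeaturePoint]:
    """Peak-class points {P, RF, FD} after plateau collapsing (the
    peak-anchored variant of the partitioning)."""
    return [f for kind, f in collapse_plateaus(features) if kind == "peak"]


@dataclass
class IterationLevel:
    """One pass of the nadir selection recursion.

    ``nadirs`` is time-ordered and includes boundary anchors: a start
    sample the series rises away from, or an end sample it falls into,
    delimits the outermost segments exactly like a detected nadir and is
    flagged in ``anchor_mask``.  Between consecutive entries of
    ``nadirs`` lies exactly one entry of ``peaks``.
    """

    level: int
    times: np.ndarray           # input points of this iteration
    values: np.ndarray
    nadirs: list[FeaturePoint] = field(default_factory=list)
    anchor_mask: list[bool] = field(default_factory=list)
    peaks: list[FeaturePoint] = field(default_factory=list)
    features: list[FeaturePoint] = field(default_factory=list)
    leading: Optional[BoundaryFlank] = None
    trailing: Optional[BoundaryFlank] = None

    @property
    def interior_nadirs(self) -> list[FeaturePoint]:
        """Detected (non-anchor) nadirs."""
        return [f for f, a in zip(self.nadirs, self.anchor_mask) if not a]

    @property
    def nadir_times(self) -> np.ndarray:
        return np.array([f.time for f in self.nadirs])

    @property
    def is_terminal(self) -> bool:
        return not self.peaks

    def subseries(self) -> tuple[np.ndarray, np.ndarray]:
        """(first sample, selected nadirs, last sample) for the next pass."""
        pts = {0: (self.times[0], self.values[0]),
               len(self.times) - 1: (self.times[-1], self.values[-1])}
        for f in self.nadirs:
            pts[f.index] = (f.time, f.value)
        ordered = [pts[k] for k in sorted(pts)]
        t, v = zip(*ordered)
        return np.array(t), np.array(v)


def _compare(a: float, b: float, eps: float) -> str:
    if abs(a - b) <= eps:
        return "="
    return "<" if a < b else ">"


def _build_level(
    times: np.ndarray, values: np.ndarray, k: int, epsilon: float
) -> IterationLevel:
    lv = IterationLevel(level=k, times=times, values=values)
    n = len(values)
    if n < 2:
        return lv
    rel = [_compare(values[i], values[i + 1], epsilon) for i in range(n - 1)]
    if all(r == "=" for r in rel):
        return lv  # flat: nothing to find, no flanks

    if n >= 3:
        labels = label_values(values, epsilon)
        lv.features = [
            FeaturePoint(i, float(times[i]), float(values[i]), lab)
            for i, lab in zip(range(1, n - 1), labels)
        ]
    events = collapse_plateaus(lv.features)

    # boundary handling: an initial flat run is absorbed into the boundary
    lead_end = next(i for i, r in enumerate(rel) if r != "=")      # last idx of leading run
    trail_start = n - 1 - next(i for i, r in enumerate(rel[::-1]) if r != "=")
    lead_dir = rel[lead_end]
    trail_dir = rel[trail_start - 1]

    if lead_dir == "<":  # series rises away from its start: start anchor
        if not (events and events[0][1].index == lead_end):
            anchor = FeaturePoint(
                lead_end, float(times[lead_end]), float(values[lead_end]),
                FeatureLabel.START_ASC,
            )
            events.insert(0, ("nadir", anchor))
        start_anchor_idx = lead_end
    else:
        start_anchor_idx = None
    if trail_dir == ">":  # series falls into its end: end anchor
        if not (events and events[-1][1].index == trail_start):
            anchor = FeaturePoint(
                trail_start, float(times[trail_start]), float(values[trail_start]),
                FeatureLabel.END_DESC,
            )
            events.append(("nadir", anchor))
        end_anchor_idx = trail_start
    else:
        end_anchor_idx = None

    for kind, f in events:
        if kind == "nadir":
            lv.nadirs.append(f)
            lv.anchor_mask.append(f.index in (start_anchor_idx, end_anchor_idx))
        else:
            lv.peaks.append(f)

    # one peak between consecutive nadirs (guard for implementation bugs)
    for a, b in zip(lv.nadirs, lv.nadirs[1:]):
        between = [p for p in lv.peaks if a.index < p.index < b.index]
        if len(between) != 1:
            raise HapConvergenceError(
                f"level {k}: {len(between)} peaks between nadirs at "
                f"t={a.time:g} and t={b.time:g}"
            )

    if start_anchor_idx is None:
        end_t = lv.nadirs[0].time if lv.nadirs else float(times[-1])
        lv.leading = BoundaryFlank(">", float(times[0]), end_t)
    if end_anchor_idx is None:
        start_t = lv.nadirs[-1].time if lv.nadirs else float(times[0])
        lv.trailing = BoundaryFlank("<", start_t, float(times[-1]))
    return lv


@dataclass
class HapResult:
    """The full hierarchy produced by the nadir selection recursion."""

    series: HormoneSeries
    levels: list[IterationLevel]
    epsilon: float = 0.0

    @property
    def terminal_level(self) -> int:
        """Number of recorded iterations; the last found no rise-and-fall."""
        return len(self.levels)

    @property
    def n_pulse_levels(self) -> int:
        """Iterations that identified at least one peak (pulse-bearing)."""
        return sum(1 for lv in self.levels if lv.peaks)

    @property
    def boundary(self) -> tuple[Optional[BoundaryFlank], Optional[BoundaryFlank]]:
        """Level-1 leading/trailing monotone-run descriptors."""
        return self.levels[0].leading, self.levels[0].trailing

    def level(self, k: int) -> IterationLevel:
        if not 1 <= k <= len(self.levels):
            raise IndexError(f"level {k} out of range 1..{len(self.levels)}")
        return self.levels[k - 1]


def run_hap(series: HormoneSeries, epsilon: float = 0.0) -> HapResult:
    """Parse a hormone series into its hierarchy of nadir-bounded levels.

    Iterates classify -> collapse plateaus -> select nadirs -> recurse on
    (first sample, nadirs, last sample) until an iteration identifies no
    interior peak.  That peakless iteration is recorded as the terminal
    level, so a parse of ``m`` pulse-bearing levels has ``m + 1`` levels
    in total (a monotone or flat series terminates at level 1).
    """
    t, v = series.observed()
    if len(t) < 3:
        raise ValueError("need at least 3 non-missing samples")
    levels: list[IterationLevel] = []
    times, values = t, v
    while True:
        lv = _build_level(times, values, k=len(levels) + 1, epsilon=epsilon)
        levels.append(lv)
        if lv.is_terminal:
            break
        if len(levels) > len(levels[0].nadirs) + 2:
            raise HapConvergenceError(
                "iteration count exceeded the level-1 nadir count"
            )
        nxt_t, nxt_v = lv.subseries()
        if len(nxt_t) >= len(times):
            raise HapConvergenceError(
                f"level {lv.level}: sub-series did not contract"
            )
        times, values = nxt_t, nxt_v
    return HapResult(series=series, levels=levels, epsilon=epsilon)
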