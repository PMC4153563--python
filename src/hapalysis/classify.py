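"""Pointwise feature classification of a hormone series.

Every interior sample is labelled by a comparator operator: the ordered
pair of three-way comparisons of the sample against its nearest
non-missing neighbours.  The nine possible pairs map onto the nine
interior feature codes (nadir, peak, rise, fall, the four plateau
transitions, flat); these labels drive the recursive parser.

No smoothing or denoising is applied anywhere: the labels are a pure
function of the stored values, so low-amplitude events and assay noise
are deliberately retained at the first iteration level.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .series_io import HormoneSeries

__all__ = [
    "FeatureLabel",
    "FeaturePoint",
    "classify_points",
    "comparator_neighbors",
    "label_values",
]


class FeatureLabel(str, Enum):
    """Interior feature codes plus boundary/missing markers."""

    N = "N"    # nadir: higher on both sides
    P = "P"    # peak: lower on both sides
    R = "R"    # rising
    D = "D"    # descending
    RF = "RF"  # rising to flat
    FD = "FD"  # flat to descending
    DF = "DF"  # descending to flat
    FR = "FR"  # flat to rising
    F = "F"    # flat
    # boundary run descriptors (assigned by the parser, not the comparator)
    START_DESC = "START_DESC"
    START_ASC = "START_ASC"
    END_DESC = "END_DESC"
    END_ASC = "END_ASC"
    # adjacent-to-missing: a comparator side could not be resolved
    M = "M"


#: comparator-pair -> label; keys are (c[i-1] vs c[i], c[i] vs c[i+1])
_LABEL_TABLE: dict[tuple[str, str], FeatureLabel] = {
    (">", "<"): FeatureLabel.N,
    ("<", ">"): FeatureLabel.P,
    ("<", "<"): FeatureLabel.R,
    (">", ">"): FeatureLabel.D,
    ("<", "="): FeatureLabel.RF,
    ("=", ">"): FeatureLabel.FD,
    (">", "="): FeatureLabel.DF,
    ("=", "<"): FeatureLabel.FR,
    ("=", "="): FeatureLabel.F,
}

#: Eq.-style feature classes used by the nadir selection recursion
NADIR_CLASS = frozenset({FeatureLabel.N, FeatureLabel.DF, FeatureLabel.FR})
PEAK_CLASS = frozenset({FeatureLabel.P, FeatureLabel.RF, FeatureLabel.FD})


@dataclass(frozen=True)
class FeaturePoint:
    """A labelled sample: grid index, time (min), value (µg/dL), label."""

    index: int
    time: float
    value: float
    label: FeatureLabel


def _compare(a: float, b: float, epsilon: float) -> str:
    """Three-way comparison with an equality tolerance (default exact)."""
    if abs(a - b) <= epsilon:
        return "="
    return "<" if a < b else ">"


def label_values(values: np.ndarray, epsilon: float = 0.0) -> list[FeatureLabel]:
    """Comparator labels for the interior points of a gap-free value sequence.

    Returns one label per interior index 1..n-2.  This is the primitive
    the parser applies at every recursion level, where the sub-series of
    selected nadirs is gap-free but no longer uniformly spaced (the
    comparator only uses value order, never spacing).
    """
    values = np.asarray(values, dtype=float)
    out = []
    for i in range(1, len(values) - 1):
        left = _compare(values[i - 1], values[i], epsilon)
        right = _compare(values[i], values[i + 1], epsilon)
        out.append(_LABEL_TABLE[(left, right)])
    return out


def comparator_neighbors(
    series: HormoneSeries, index: int, epsilon: float = 0.0
) -> tuple[str, str]:
    """Comparisons of sample ``index`` against its nearest non-missing
    neighbours on each side.

    Missing samples are skipped, not imputed.  A side with no
    non-missing neighbour yields ``"M"``.
    """
    if not 0 < index < len(series) - 1:
        raise IndexError(f"index {index} is not interior")
    v = series.values[index]
    left = right = "M"
    for j in range(index - 1, -1, -1):
        if not series.missing_mask[j]:
            left = _compare(series.values[j], v, epsilon)
            break
    for j in range(index + 1, len(series)):
        if not series.missing_mask[j]:
            right = _compare(v, series.values[j], epsilon)
            break
    return left, right


def classify_points(series: HormoneSeries, epsilon: float = 0.0) -> list[FeaturePoint]:
    """Label every interior non-missing sample with a resolvable comparator.

    Because comparisons skip missing samples to the nearest observed
    neighbour, the result equals classifying the compressed sequence of
    observed samples; points whose comparator cannot be resolved on one
    side (label ``M``) are omitted.
    """
    if series.missing_mask[1:-1].all():
        raise ValueError("no classifiable points: all interior samples are missing")
    obs_idx = np.flatnonzero(~series.missing_mask)
    if len(obs_idx) < 3:
        raise ValueError("no classifiable points: fewer than 3 observed samples")
    labels = label_values(series.values[obs_idx], epsilon)
    return [
        FeaturePoint(int(i), float(series.times[i]), float(series.values[i]), lab)
        for i, lab in zip(obs_idx[1:-1], labels)
    ]
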