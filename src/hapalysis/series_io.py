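"""Reading, validating and writing uniformly sampled hormone series.

A series is a regular time grid (minutes) of concentration values
(µg/dL) with an explicit missing-data mask: samples absent from an
otherwise regular grid are kept on the grid and masked, never dropped,
so that downstream analysis always sees one nominal sampling interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["HormoneSeries", "SeriesFormatError", "read_series", "write_series"]

#: relative tolerance used when snapping times onto the inferred grid
_GRID_RTOL = 1e-6


class SeriesFormatError(ValueError):
    """Raised when a file cannot be interpreted as a regular hormone series."""


@dataclass
class HormoneSeries:
    """Uniformly sampled (time, concentration) series with missing-data mask.

    Parameters
    ----------
    times:
        Sample times in minutes since series start; an arithmetic
        progression with common difference ``delta_t``.
    values:
        Concentrations in µg/dL.  Entries at masked positions are ignored
        (stored as NaN).
    missing_mask:
        Boolean array, ``True`` where the sample is missing.
    delta_t:
        Nominal sampling interval in minutes.
    meta:
        Free-form labels (subject id, state annotations, ...).
    """

    times: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray
    delta_t: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n = len(self.times)
        if not (len(self.values) == len(self.missing_mask) == n):
            raise ValueError("times, values and missing_mask must have equal length")
        if n < 3:
            raise ValueError(f"series too short for analysis: {n} samples (need >= 3)")
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            raise SeriesFormatError("times must be strictly increasing")
        if not np.allclose(diffs, self.delta_t, rtol=_GRID_RTOL, atol=0):
            bad = int(np.argmax(np.abs(diffs - self.delta_t)))
            raise SeriesFormatError(
                f"irregular grid: gap of {diffs[bad]:g} min after t={self.times[bad]:g}"
                f" (expected delta_t={self.delta_t:g})"
            )
        observed = self.values[~self.missing_mask]
        if not np.all(np.isfinite(observed)):
            raise ValueError("non-finite concentration at a non-missing position")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_observed(self) -> int:
        return int((~self.missing_mask).sum())

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and values of the non-missing samples."""
        keep = ~self.missing_mask
        return self.times[keep], self.values[keep]

    def __eq__(self, other: object) -> bool:  # value semantics for round-trips
        if not isinstance(other, HormoneSeries):
            return NotImplemented
        keep = ~self.missing_mask
        okeep = ~other.missing_mask
        return (
            len(self) == len(other)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.array_equal(self.values[keep], other.values[okeep])
            and self.delta_t == other.delta_t
        )


def _infer_delta_t(times: np.ndarray) -> float:
    diffs = np.diff(times)
    return float(diffs.min())


def _complete_grid(
    times: np.ndarray, values: np.ndarray, delta_t: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place (times, values) on the full delta_t grid, masking absent rows."""
    offsets = (times - times[0]) / delta_t
    steps = np.rint(offsets)
    if not np.allclose(offsets, steps, rtol=0, atol=_GRID_RTOL * max(1.0, offsets[-1])):
        bad = int(np.argmax(np.abs(offsets - steps)))
        raise SeriesFormatError(
            f"time {times[bad]:g} min does not lie on a grid with delta_t={delta_t:g}"
        )
    n = int(steps[-1]) + 1
    grid_times = times[0] + delta_t * np.arange(n)
    grid_values = np.full(n, np.nan)
    mask = np.ones(n, dtype=bool)
    idx = steps.astype(int)
    grid_values[idx] = values
    mask[idx] = False
    # rows present in the file but with an empty concentration field stay masked
    empty = np.isnan(values)
    mask[idx[empty]] = True
    return grid_times, grid_values, mask


def read_series(
    path: str | Path,
    *,
    delimiter: str | None = None,
    time_column: str = "time_min",
    value_column: str = "concentration",
    delta_t: float | None = None,
    meta: dict[str, Any] | None = None,
) -> HormoneSeries:
    """Read a headered CSV/TSV hormone series file.

    Rows absent from an otherwise regular grid become missing-masked
    samples; a row with an empty concentration field is likewise masked.
    ``delta_t`` is inferred as the minimal positive time difference unless
    declared, in which case a mismatch with the inferred value is an error.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    for col in (time_column, value_column):
        if col not in frame.columns:
            raise SeriesFormatError(f"{path.name}: required column {col!r} not found")
    times = frame[time_column].to_numpy(dtype=float)
    values = frame[value_column].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise SeriesFormatError(f"{path.name}: times are not strictly increasing")
    inferred = _infer_delta_t(times)
    if delta_t is not None and not np.isclose(delta_t, inferred, rtol=_GRID_RTOL):
        raise SeriesFormatError(
            f"{path.name}: declared delta_t={delta_t:g} but inferred {inferred:g}"
        )
    dt = delta_t if delta_t is not None else inferred
    if np.any(values[~np.isnan(values)] < 0):
        warnings.warn(
            f"{path.name}: negative concentration values retained", stacklevel=2
        )
    grid_times, grid_values, mask = _complete_grid(times, values, dt)
    info: dict[str, Any] = {"source": str(path), "subject": path.stem}
    if meta:
        info.update(meta)
    return HormoneSeries(grid_times, grid_values, mask, dt, info)


def write_series(series: HormoneSeries, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a series so that :func:`read_series` reproduces it exactly.

    Missing samples are written as rows with an empty concentration
    field, which keeps the grid explicit in the file.
    """
    path = Path(path)
    values = [
        "" if missing else repr(float(v))
        for v, missing in zip(series.values, series.missing_mask)
    ]
    frame = pd.DataFrame(
        {"time_min": [f"{t:g}" for t in series.times], "concentration": values}
    )
    frame.to_csv(path, sep=delimiter, index=False)
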