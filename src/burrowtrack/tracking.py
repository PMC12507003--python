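"""Reconstruction of per-individual grid locations from RFID detections.

A detection places an individual in the pipe carrying the reader.  Between
two detections the interval is assigned the unique cell "between" the two
readers: the shared pipe if both readers sit on one pipe; for a repeated
read of the same reader, the pipe if the gap is within ``redetect_s``
(0.3 s) and the box at that reader's end otherwise; for readers on two
different pipes, the box flanked by both pipes.  Readers with no shared
pipe or box leave the interval unlocatable (UNKNOWN).  Ticks before the
first detection are UNKNOWN; ticks after the last detection carry the
final inferred cell (the last reader's end box).

Intervals are half-open ``[t_i, t_{i+1})`` on the 0.1-s tick grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .layout import UNKNOWN, GridLayout


@dataclass
class LocationSeries:
    """Per-tick cell occupancy for one individual.

    ``cells`` holds flat cell codes with :data:`~burrowtrack.layout.UNKNOWN`
    (-1) marking unlocatable ticks.
    """

    individual: object
    tick_s: float
    cells: np.ndarray

    @property
    def n_ticks(self) -> int:
        return self.cells.size

    def error_rate(self) -> float:
        return float(np.count_nonzero(self.cells == UNKNOWN)) / self.cells.size


class DetectionError(ValueError):
    """Raised for malformed detection logs."""


def _interval_cells(
    layout: GridLayout,
    readers: list[str],
    times: np.ndarray,
    redetect_s: float,
) -> np.ndarray:
    """Cell assigned to each inter-detection interval (UNKNOWN = -1)."""
    n = len(readers)
    try:
        objs = [layout.readers[r] for r in readers]
    except KeyError as exc:
        raise DetectionError(f"unknown reader id {exc.args[0]!r}") from exc
    cells = np.empty(max(n - 1, 0), dtype=np.int16)
    eps = 1e-9
    for k in range(n - 1):
        a, b = objs[k], objs[k + 1]
        if a.id == b.id:
            gap = times[k + 1] - times[k]
            cells[k] = a.pipe if gap <= redetect_s + eps else a.box
        elif a.pipe == b.pipe:
            cells[k] = a.pipe
        else:
            shared = layout.common_box(a.pipe, b.pipe)
            cells[k] = UNKNOWN if shared is None else shared
    return cells


def reconstruct_individual(
    times: np.ndarray,
    readers: list[str],
    layout: GridLayout,
    duration_s: float,
    tick_s: float = 0.1,
    redetect_s: float = 0.3,
) -> np.ndarray:
    """Per-tick cell codes for one individual from its detection records."""
    n_ticks = int(round(duration_s / tick_s))
    out = np.full(n_ticks, UNKNOWN, dtype=np.int16)
    if len(readers) == 0:
        return out
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise DetectionError("detection times must be non-decreasing")
    # duplicate timestamps for one tag (possible with noise): keep the first
    ticks = np.round(times / tick_s).astype(np.int64)
    keep = np.ones(times.size, dtype=bool)
    keep[1:] = ~((np.diff(times) == 0))
    if not keep.all():
        warnings.warn("dropped simultaneous duplicate detections", stacklevel=2)
        times, ticks = times[keep], ticks[keep]
        readers = [r for r, k in zip(readers, keep) if k]
    ticks = np.clip(ticks, 0, n_ticks)
    cells = _interval_cells(layout, readers, times, redetect_s)
    for k in range(len(readers) - 1):
        out[ticks[k] : ticks[k + 1]] = cells[k]
    # trailing ticks: the final inferred cell (the last reader's end box)
    out[ticks[-1] :] = layout.readers[readers[-1]].box
    return out


def reconstruct_locations(
    log: pd.DataFrame,
    layout: GridLayout,
    duration_s: float,
    tick_s: float = 0.1,
    redetect_s: float = 0.3,
    individuals: Iterable | None = None,
) -> dict[object, LocationSeries]:
    """Reconstruct per-individual location series from a detection log.

    ``log`` must have columns ``time_s, tag, reader`` and be time-sorted;
    each tag's records are processed independently.  Individuals listed in
    ``individuals`` but absent from the log come back all-UNKNOWN.
    """
    required = {"time_s", "tag", "reader"}
    if not required.issubset(log.columns):
        raise DetectionError(f"detection log must have columns {sorted(required)}")
    tags = sorted(log["tag"].unique()) if individuals is None else list(individuals)
    out: dict[object, LocationSeries] = {}
    grouped = dict(tuple(log.groupby("tag", sort=False)))
    for tag in tags:
        g = grouped.get(tag)
        if g is None:
            cells = np.full(int(round(duration_s / tick_s)), UNKNOWN, dtype=np.int16)
        else:
            cells = reconstruct_individual(
                g["time_s"].to_numpy(), list(g["reader"]), layout,
                duration_s, tick_s, redetect_s,
            )
        out[tag] = LocationSeries(individual=tag, tick_s=tick_s, cells=cells)
    return out


def compute_error_rate(series: Iterable[LocationSeries] | Mapping) -> float:
    """Pooled fraction of UNKNOWN ticks across individuals."""
    if isinstance(series, Mapping):
        series = series.values()
    unknown = total = 0
    for s in series:
        unknown += int(np.count_nonzero(s.cells == UNKNOWN))
        total += s.cells.size
    if total == 0:
        raise ValueError("no location series supplied")
    return unknown / total


def downsample(series: LocationSeries, interval_s: float = 10.0) -> np.ndarray:
    """Cell codes sampled every ``interval_s`` (instantaneous values)."""
    step = int(round(interval_s / series.tick_s))
    return series.cells[::step].copy()
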