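"""Memory-frugal colony processing: detections -> events + sampled locations.

Reconstructing every individual's full-resolution tick series at once is
wasteful for large colonies; this two-pass driver reconstructs one
individual at a time, keeping only its 10-s downsampled locations,
segmented stays and movement events before discarding the tick array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dyads import extract_movements
from .events import (
    ChamberAnnotation,
    StayEvent,
    annotate_nest_sampled,
    apply_corrections,
    classify_stays,
    detect_disturbances,
    rest_fraction,
    segment_stays,
)
from .layout import GridLayout, cell_code
from .tracking import LocationSeries, reconstruct_individual


@dataclass
class ColonyDataset:
    """Everything downstream dyadic/phenotype analyses need for one colony."""

    duration_s: float
    events: dict[object, list[StayEvent]]
    locations10: dict[object, np.ndarray]
    movements: dict[object, tuple[np.ndarray, np.ndarray]]
    annotation: ChamberAnnotation
    disturbances: list[tuple[float, float]]
    error_rate: float


def process_colony(
    log: pd.DataFrame,
    layout: GridLayout,
    duration_s: float,
    individuals,
    toilet: tuple[int, int] = (0, 0),
    garbage: tuple[int, int] = (4, 4),
    tick_s: float = 0.1,
    redetect_s: float = 0.3,
    interval_s: float = 10.0,
    rest_threshold_s: float = 600.0,
) -> ColonyDataset:
    """Run tracking + event building for a whole colony, one tag at a time."""
    step = int(round(interval_s / tick_s))
    grouped = dict(tuple(log.groupby("tag", sort=False)))
    loc10: dict[object, np.ndarray] = {}
    raw_segments: dict[object, list[StayEvent]] = {}
    movements: dict[object, tuple[np.ndarray, np.ndarray]] = {}
    unknown = total = 0
    n_ticks = int(round(duration_s / tick_s))
    for tag in individuals:
        g = grouped.get(tag)
        if g is None:
            cells = np.full(n_ticks, -1, dtype=np.int16)
        else:
            cells = reconstruct_individual(
                g["time_s"].to_numpy(), list(g["reader"]), layout,
                duration_s, tick_s, redetect_s,
            )
        unknown += int(np.count_nonzero(cells == -1))
        total += cells.size
        loc10[tag] = cells[::step].copy()
        series = LocationSeries(individual=tag, tick_s=tick_s, cells=cells)
        raw_segments[tag] = segment_stays(series)
        movements[tag] = extract_movements(cells, tick_s)
        del cells, series

    nest = annotate_nest_sampled(loc10.values(), layout, interval_s)
    annotation = ChamberAnnotation(
        sample_s=interval_s, nest_code=nest,
        toilet=cell_code(*toilet), garbage=cell_code(*garbage),
    )
    classified = {
        tag: classify_stays(evs, annotation, layout, rest_threshold_s)
        for tag, evs in raw_segments.items()
    }
    events = apply_corrections(classified, annotation, layout, duration_s,
                               rest_threshold_s)
    rf = rest_fraction(events, duration_s, interval_s)
    disturbances = detect_disturbances(rf, interval_s)
    return ColonyDataset(
        duration_s=duration_s,
        events=events,
        locations10=loc10,
        movements=movements,
        annotation=annotation,
        disturbances=disturbances,
        error_rate=unknown / total if total else 0.0,
    )
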