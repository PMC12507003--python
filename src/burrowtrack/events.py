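"""Chamber annotation, stay-event segmentation and classification.

A *stay event* is a maximal period an individual spends in one grid cell.
Nest stays longer than 600 s are Rest; shorter nest stays are Nest; stays
in the toilet or garbage chamber take that label regardless of duration;
everything else (pipes, unannotated boxes) is Other.  Cleaning rules
reclassify long nest-adjacent pipe stays and sub-nest stays as Rest, fill
long unlocatable gaps as Rest in the nest, and flag colony-wide
disturbance episodes (resting fraction below 25% with a dip below 10%)
for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

from .layout import UNKNOWN, GridLayout, cell_code, cell_coords
from .tracking import LocationSeries

REST_THRESHOLD_S = 600.0

#: stay-event categories
REST, NEST, TOILET, GARBAGE, OTHER, NA = "Rest", "Nest", "Toilet", "Garbage", "Other", "NA"
CATEGORIES = (REST, NEST, TOILET, GARBAGE, OTHER)


@dataclass
class StayEvent:
    """A contiguous single-cell occupancy (or an unlocatable gap)."""

    individual: object
    start_s: float
    end_s: float
    cell: int  # flat cell code; UNKNOWN for gaps
    category: str | None = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass
class ChamberAnnotation:
    """Chamber functions over time.

    ``nest_code[k]`` is the nest box at sample time ``k * sample_s``;
    toilet and garbage locations are manual, fixed annotations.
    """

    sample_s: float
    nest_code: np.ndarray
    toilet: int
    garbage: int

    def nest_at(self, t_s: float) -> int:
        k = int(t_s / self.sample_s)
        return int(self.nest_code[min(max(k, 0), self.nest_code.size - 1)])

    def transitions(self) -> list[tuple[float, int, int]]:
        """Nest relocations as ``(time_s, old_box, new_box)``."""
        idx = np.flatnonzero(np.diff(self.nest_code) != 0) + 1
        return [
            (float(k * self.sample_s), int(self.nest_code[k - 1]), int(self.nest_code[k]))
            for k in idx
        ]


def classify_spatial_position(cell: int) -> str:
    """Spatial class of a box in the 3x3 arrangement: corner/edge/center."""
    r, c = cell_coords(cell)
    if r % 2 or c % 2:
        raise ValueError(f"cell {(r, c)} is not a box")
    br, bc = r // 2, c // 2
    if (br, bc) == (1, 1):
        return "center"
    if br in (0, 2) and bc in (0, 2):
        return "corner"
    return "edge"


def annotate_nest_sampled(
    sampled: Iterable[np.ndarray],
    layout: GridLayout,
    sample_s: float = 10.0,
    window_s: float = 21600.0,
) -> np.ndarray:
    """Nest box per sample from pre-sampled per-individual cell codes.

    The nest at each sample is the box with the highest mean occupant
    count over a centered 6-hour window (clipped at the recording edges).
    Ties break to the lowest (row, col); all-unlocatable windows carry the
    previous nest forward.
    """
    boxes = np.asarray(layout.box_codes)
    counts = None
    for cells in sampled:
        if counts is None:
            counts = np.zeros((cells.size, boxes.size), dtype=np.int32)
        for b, code in enumerate(boxes):
            counts[:, b] += cells == code
    if counts is None:
        raise ValueError("no location series supplied")
    half = int(round(window_s / 2 / sample_s))
    csum = np.cumsum(np.vstack([np.zeros((1, boxes.size)), counts]), axis=0)
    n = counts.shape[0]
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    window_mean = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    nest = boxes[np.argmax(window_mean, axis=1)].astype(np.int16)
    empty = window_mean.sum(axis=1) == 0
    if empty.any():
        for k in np.flatnonzero(empty):
            nest[k] = nest[k - 1] if k > 0 else nest[~empty][0] if (~empty).any() else boxes[0]
    return nest


def annotate_nest(
    series: Mapping[object, LocationSeries],
    layout: GridLayout,
    sample_s: float = 10.0,
    window_s: float = 21600.0,
) -> np.ndarray:
    """Nest box per sample from full-resolution location series.

    See :func:`annotate_nest_sampled` for the window-mean rule.
    """
    def _iter():
        for s in series.values():
            step = int(round(sample_s / s.tick_s))
            yield s.cells[::step]

    return annotate_nest_sampled(_iter(), layout, sample_s, window_s)


def make_annotation(
    series: Mapping[object, LocationSeries],
    layout: GridLayout,
    toilet: tuple[int, int] | int,
    garbage: tuple[int, int] | int,
    sample_s: float = 10.0,
    window_s: float = 21600.0,
) -> ChamberAnnotation:
    """Convenience constructor: occupancy-derived nest + manual toilet/garbage."""
    toilet_code = toilet if np.isscalar(toilet) else cell_code(*toilet)
    garbage_code = garbage if np.isscalar(garbage) else cell_code(*garbage)
    nest = annotate_nest(series, layout, sample_s, window_s)
    return ChamberAnnotation(sample_s=sample_s, nest_code=nest,
                             toilet=int(toilet_code), garbage=int(garbage_code))


def segment_stays(series: LocationSeries) -> list[StayEvent]:
    """Maximal constant-cell runs; UNKNOWN runs come back as NA gap events."""
    cells = series.cells
    if cells.size == 0:
        return []
    change = np.flatnonzero(np.diff(cells) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [cells.size]])
    tick = series.tick_s
    return [
        StayEvent(
            individual=series.individual,
            start_s=float(s * tick),
            end_s=float(e * tick),
            cell=int(cells[s]),
            category=NA if cells[s] == UNKNOWN else None,
        )
        for s, e in zip(starts, ends)
    ]


def find_duration_modes(
    durations: Sequence[float], bw_method: str | float = "silverman"
) -> tuple[np.ndarray, np.ndarray]:
    """KDE modes and antimodes of a stay-duration sample.

    The density is estimated on log-duration (Silverman bandwidth) and the
    extrema are back-transformed to seconds.  Returns ``(modes, antimodes)``.
    """
    d = np.asarray(durations, dtype=float)
    d = d[d > 0]
    if d.size < 2:
        raise ValueError("need at least two positive durations")
    logs = np.log(d)
    if np.ptp(logs) == 0:
        return np.array([float(d[0])]), np.array([])
    kde = gaussian_kde(logs, bw_method=bw_method)
    grid = np.linspace(logs.min() - 1.0, logs.max() + 1.0, 2048)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    minima = argrelextrema(dens, np.less)[0]
    return np.exp(grid[maxima]), np.exp(grid[minima])


def classify_stays(
    events: Iterable[StayEvent],
    annotation: ChamberAnnotation,
    layout: GridLayout,
    rest_threshold_s: float = REST_THRESHOLD_S,
) -> list[StayEvent]:
    """Assign categories; chamber function is evaluated at the event midpoint.

    Nest stays strictly longer than ``rest_threshold_s`` are Rest.
    Classification is idempotent.
    """
    out = []
    for ev in events:
        if ev.cell == UNKNOWN:
            cat = NA
        elif not layout.is_box(ev.cell):
            cat = OTHER
        else:
            nest = annotation.nest_at(ev.midpoint_s())
            if ev.cell == nest:
                cat = REST if ev.duration_s > rest_threshold_s else NEST
            elif ev.cell == annotation.toilet:
                cat = TOILET
            elif ev.cell == annotation.garbage:
                cat = GARBAGE
            else:
                cat = OTHER
        out.append(StayEvent(ev.individual, ev.start_s, ev.end_s, ev.cell, cat))
    return out


def rest_fraction(
    events_by_individual: Mapping[object, Sequence[StayEvent]],
    duration_s: float,
    sample_s: float = 10.0,
) -> np.ndarray:
    """Fraction of the colony inside a Rest event at each sample time."""
    n_samples = int(round(duration_s / sample_s))
    counts = np.zeros(n_samples, dtype=np.int32)
    for evs in events_by_individual.values():
        for ev in evs:
            if ev.category == REST:
                lo = int(np.ceil(ev.start_s / sample_s - 1e-9))
                hi = int(np.ceil(ev.end_s / sample_s - 1e-9))
                counts[max(lo, 0) : min(hi, n_samples)] += 1
    return counts / max(len(events_by_individual), 1)


def detect_disturbances(
    rest_frac: np.ndarray,
    sample_s: float = 10.0,
    low: float = 0.25,
    dip: float = 0.10,
) -> list[tuple[float, float]]:
    """Maximal sub-``low`` intervals containing at least one sub-``dip`` sample."""
    below = rest_frac < low
    out: list[tuple[float, float]] = []
    k = 0
    n = below.size
    while k < n:
        if below[k]:
            j = k
            while j < n and below[j]:
                j += 1
            if np.any(rest_frac[k:j] < dip):
                out.append((k * sample_s, j * sample_s))
            k = j
        else:
            k += 1
    return out


def _coresidence_intervals(
    events_by_individual: Mapping[object, Sequence[StayEvent]],
    box: int,
    duration_s: float,
    min_individuals: int,
    min_duration_s: float,
    sample_s: float = 10.0,
) -> list[tuple[float, float]]:
    """Periods during which >= min_individuals co-reside in ``box``."""
    n_samples = int(round(duration_s / sample_s))
    counts = np.zeros(n_samples, dtype=np.int32)
    for evs in events_by_individual.values():
        for ev in evs:
            if ev.cell == box:
                lo = int(np.ceil(ev.start_s / sample_s - 1e-9))
                hi = int(np.ceil(ev.end_s / sample_s - 1e-9))
                counts[max(lo, 0) : min(hi, n_samples)] += 1
    dense = counts >= min_individuals
    out = []
    k = 0
    while k < n_samples:
        if dense[k]:
            j = k
            while j < n_samples and dense[j]:
                j += 1
            if (j - k) * sample_s > min_duration_s:
                out.append((k * sample_s, j * sample_s))
            k = j
        else:
            k += 1
    return out


def _overlap(a_lo: float, a_hi: float, intervals: Sequence[tuple[float, float]]) -> float:
    return sum(max(0.0, min(a_hi, hi) - max(a_lo, lo)) for lo, hi in intervals)


def apply_corrections(
    events_by_individual: Mapping[object, Sequence[StayEvent]],
    annotation: ChamberAnnotation,
    layout: GridLayout,
    duration_s: float,
    rest_threshold_s: float = REST_THRESHOLD_S,
    subnest_min_individuals: int = 5,
    na_fill_s: float = 1800.0,
) -> dict[object, list[StayEvent]]:
    """Cleaning rules applied after classification (idempotent).

    (a) stays > ``rest_threshold_s`` in a pipe adjacent to the current
    nest become Rest; (b) a non-nest box where >= 5 individuals co-reside
    continuously for > ``rest_threshold_s`` is a sub-nest, and stays
    > ``rest_threshold_s`` there become Rest; (c) unlocatable gaps longer
    than 30 min are relocated to the nest and classified Rest.
    """
    # sub-nest intervals are derived from location occupancy, which the
    # corrections themselves never change -> idempotence
    subnest: dict[int, list[tuple[float, float]]] = {}
    nest_boxes = set(int(b) for b in np.unique(annotation.nest_code))
    for box in layout.box_codes:
        if box in nest_boxes:
            continue
        ivals = _coresidence_intervals(
            events_by_individual, box, duration_s,
            subnest_min_individuals, rest_threshold_s, annotation.sample_s,
        )
        if ivals:
            subnest[box] = ivals

    out: dict[object, list[StayEvent]] = {}
    for ind, evs in events_by_individual.items():
        fixed = []
        for ev in evs:
            cat = ev.category
            cell = ev.cell
            if cell == UNKNOWN and ev.duration_s > na_fill_s:
                cell = annotation.nest_at(ev.midpoint_s())
                cat = REST
            elif (
                layout.is_pipe(cell)
                and ev.duration_s > rest_threshold_s
                and cell in layout.pipes_adjacent_to(annotation.nest_at(ev.midpoint_s()))
            ):
                cat = REST
            elif (
                cell in subnest
                and ev.duration_s > rest_threshold_s
                and _overlap(ev.start_s, ev.end_s, subnest[cell]) > rest_threshold_s
            ):
                cat = REST
            fixed.append(StayEvent(ev.individual, ev.start_s, ev.end_s, cell, cat))
        out[ind] = fixed
    return out


def build_events(
    series: Mapping[object, LocationSeries],
    annotation: ChamberAnnotation,
    layout: GridLayout,
    duration_s: float,
    rest_threshold_s: float = REST_THRESHOLD_S,
    corrections: bool = True,
) -> dict[object, list[StayEvent]]:
    """Segment, classify and (optionally) clean stay events for a colony."""
    classified = {
        ind: classify_stays(segment_stays(s), annotation, layout, rest_threshold_s)
        for ind, s in series.items()
    }
    if corrections:
        classified = apply_corrections(
            classified, annotation, layout, duration_s, rest_threshold_s
        )
    return classified
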