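import numpy as np
import pytest

from burrowtrack.events import (
    ChamberAnnotation,
    StayEvent,
    annotate_nest_sampled,
    apply_corrections,
    classify_spatial_position,
    classify_stays,
    detect_disturbances,
    find_duration_modes,
    rest_fraction,
    segment_stays,
)
from burrowtrack.layout import UNKNOWN, cell_code
from burrowtrack.tracking import LocationSeries

NEST = cell_code(2, 2)


def _annotation(nest=NEST, n_samples=10000, toilet=cell_code(0, 0),
                garbage=cell_code(4, 4)):
    return ChamberAnnotation(
        sample_s=10.0,
        nest_code=np.full(n_samples, nest, dtype=np.int16),
        toilet=toilet,
        garbage=garbage,
    )


# -- nest annotation -------------------------------------------------------

def test_nest_follows_constant_majority(layout):
    sampled = [np.full(100, NEST, dtype=np.int16) for _ in range(5)]
    nest = annotate_nest_sampled(sampled, layout, sample_s=10.0, window_s=600.0)
    assert (nest == NEST).all()


def test_nest_switch_tracks_window_mean(layout):
    """Occupancy flips mid-recording; the annotated nest switches where the
    window mean crosses, matching a direct window-mean computation."""
    b1, b2 = cell_code(0, 0), cell_code(4, 4)
    n = 200
    cells = np.full(n, b1, dtype=np.int16)
    cells[120:] = b2
    sampled = [cells.copy() for _ in range(4)]
    window_s, sample_s = 400.0, 10.0
    nest = annotate_nest_sampled(sampled, layout, sample_s, window_s)
    half = int(window_s / 2 / sample_s)
    for k in range(n):
        lo, hi = max(k - half, 0), min(k + half + 1, n)
        c1 = np.sum(cells[lo:hi] == b1)
        c2 = np.sum(cells[lo:hi] == b2)
        expected = b1 if c1 > c2 else b2 if c2 > c1 else min(b1, b2)
        assert nest[k] == expected


def test_nest_tie_breaks_to_lowest_row_col(layout):
    b1, b2 = cell_code(0, 2), cell_code(2, 0)
    sampled = [np.full(50, b1, dtype=np.int16), np.full(50, b2, dtype=np.int16)]
    nest = annotate_nest_sampled(sampled, layout, 10.0, 600.0)
    assert (nest == min(b1, b2)).all()  # lowest (row, col) = lowest code


# -- segmentation ----------------------------------------------------------

def test_constant_series_yields_one_event():
    s = LocationSeries(0, 0.1, np.full(1000, NEST, dtype=np.int16))
    events = segment_stays(s)
    assert len(events) == 1
    assert events[0].duration_s == pytest.approx(100.0)


def test_three_runs_yield_three_events():
    cells = np.concatenate([
        np.full(50, 3, dtype=np.int16),
        np.full(30, 4, dtype=np.int16),
        np.full(20, 3, dtype=np.int16),
    ])
    events = segment_stays(LocationSeries(0, 0.1, cells))
    assert [e.duration_s for e in events] == pytest.approx([5.0, 3.0, 2.0])
    assert [e.cell for e in events] == [3, 4, 3]


def test_unknown_run_is_not_merged():
    cells = np.concatenate([
        np.full(50, 3, dtype=np.int16),
        np.full(10, UNKNOWN, dtype=np.int16),
        np.full(50, 3, dtype=np.int16),
    ])
    events = segment_stays(LocationSeries(0, 0.1, cells))
    assert len(events) == 3
    assert events[1].category == "NA"


def test_event_durations_sum_to_recording(colony_day, colony_day_dataset):
    cfg, _, _ = colony_day
    for evs in colony_day_dataset.events.values():
        total = sum(ev.duration_s for ev in evs)
        assert total == pytest.approx(cfg.duration_s, abs=1e-6)


# -- classification --------------------------------------------------------

@pytest.mark.parametrize(
    "cell, duration, expected",
    [
        (NEST, 601.0, "Rest"),
        (NEST, 600.0, "Nest"),  # "more than 600 s" is strict
        (NEST, 2.0, "Nest"),
        (cell_code(0, 0), 2.0, "Toilet"),
        (cell_code(4, 4), 5000.0, "Garbage"),
        (cell_code(0, 4), 5000.0, "Other"),  # unannotated box
        (cell_code(0, 1), 100.0, "Other"),  # pipe
    ],
)
def test_stay_classification_rules(layout, cell, duration, expected):
    events = [StayEvent(0, 0.0, duration, cell)]
    out = classify_stays(events, _annotation(), layout)
    assert out[0].category == expected


def test_classification_is_idempotent(layout, colony_day_dataset):
    evs = colony_day_dataset.events[0]
    ann = colony_day_dataset.annotation
    once = classify_stays(evs, ann, layout)
    twice = classify_stays(once, ann, layout)
    assert [e.category for e in once] == [e.category for e in twice]


# -- duration modes --------------------------------------------------------

def test_duration_modes_recover_planted_mixture():
    """Lognormal mixture with modes ~6 s and ~5000 s: the antimode falls
    within a factor of 2 of the true valley (173.2 s, computed from the
    mixture density)."""
    rng = np.random.default_rng(0)
    durations = np.concatenate([
        np.exp(rng.normal(np.log(6.0), 0.5, 2000)),
        np.exp(rng.normal(np.log(5000.0), 0.5, 2000)),
    ])
    modes, antimodes = find_duration_modes(durations)
    assert len(antimodes) == 1
    true_valley = 173.2
    assert true_valley / 2 < antimodes[0] < true_valley * 2
    assert len(modes) == 2


def test_unimodal_sample_has_no_antimode():
    rng = np.random.default_rng(1)
    durations = np.exp(rng.normal(np.log(50.0), 0.4, 3000))
    _, antimodes = find_duration_modes(durations)
    assert len(antimodes) == 0


def test_duration_modes_need_two_points():
    with pytest.raises(ValueError):
        find_duration_modes([5.0])


# -- disturbances ----------------------------------------------------------

def test_constant_rest_fraction_has_no_disturbances():
    assert detect_disturbances(np.full(100, 0.5)) == []


def test_dip_inside_low_run_is_flagged():
    rf = np.full(100, 0.5)
    rf[40:60] = 0.2
    rf[50] = 0.05
    assert detect_disturbances(rf) == [(400.0, 600.0)]


def test_low_run_without_dip_is_not_flagged():
    rf = np.full(100, 0.5)
    rf[40:60] = 0.15
    assert detect_disturbances(rf) == []


def test_planted_disturbances_are_recovered(colony_day, colony_day_dataset):
    """Detected intervals cover >=95% of planted disturbance time and
    <5% of the rest of the day."""
    cfg, _, truth = colony_day
    detected = colony_day_dataset.disturbances
    assert truth.disturbance_intervals

    def overlap(a, b_list):
        return sum(max(0.0, min(a[1], b[1]) - max(a[0], b[0])) for b in b_list)

    planted_total = sum(e - s for s, e in truth.disturbance_intervals)
    covered = sum(overlap(p, detected) for p in truth.disturbance_intervals)
    assert covered / planted_total >= 0.95
    detected_total = sum(e - s for s, e in detected)
    false_time = detected_total - covered
    assert false_time / (cfg.duration_s - planted_total) < 0.05


# -- corrections -----------------------------------------------------------

def test_long_stay_in_nest_adjacent_pipe_becomes_rest(layout):
    pipe = cell_code(2, 1)  # adjacent to nest (2, 2)
    events = {0: classify_stays([StayEvent(0, 0.0, 700.0, pipe)], _annotation(), layout)}
    out = apply_corrections(events, _annotation(), layout, 700.0)
    assert out[0][0].category == "Rest"


def test_far_pipe_long_stay_stays_other(layout):
    pipe = cell_code(0, 1)  # not adjacent to nest (2, 2)
    events = {0: classify_stays([StayEvent(0, 0.0, 700.0, pipe)], _annotation(), layout)}
    out = apply_corrections(events, _annotation(), layout, 700.0)
    assert out[0][0].category == "Other"


def _co_residence_events(n_individuals, box, duration=86400.0):
    events = {}
    for i in range(n_individuals):
        events[i] = [StayEvent(i, 0.0, 700.0, box, "Other"),
                     StayEvent(i, 700.0, duration, cell_code(2, 0), "Other")]
    return events


def test_five_co_residents_make_a_subnest(layout):
    box = cell_code(0, 4)
    events = _co_residence_events(5, box)
    out = apply_corrections(events, _annotation(), layout, 86400.0)
    assert all(out[i][0].category == "Rest" for i in range(5))


def test_four_co_residents_do_not_make_a_subnest(layout):
    box = cell_code(0, 4)
    events = _co_residence_events(4, box)
    out = apply_corrections(events, _annotation(), layout, 86400.0)
    assert all(out[i][0].category == "Other" for i in range(4))


def test_long_na_gap_becomes_rest_at_nest(layout):
    events = {0: [
        StayEvent(0, 0.0, 100.0, cell_code(2, 0), "Other"),
        StayEvent(0, 100.0, 100.0 + 45 * 60, UNKNOWN, "NA"),
        StayEvent(0, 100.0 + 45 * 60, 86400.0, cell_code(2, 0), "Other"),
    ]}
    out = apply_corrections(events, _annotation(), layout, 86400.0)
    gap = out[0][1]
    assert gap.category == "Rest"
    assert gap.cell == NEST


def test_corrections_are_idempotent(layout, colony_day_dataset):
    ds = colony_day_dataset
    once = ds.events
    twice = apply_corrections(once, ds.annotation, layout, ds.duration_s)
    for i in once:
        assert [(e.cell, e.category) for e in once[i]] == [
            (e.cell, e.category) for e in twice[i]
        ]


# -- spatial position ------------------------------------------------------

@pytest.mark.parametrize(
    "cell, expected",
    [
        ((0, 0), "corner"), ((0, 4), "corner"), ((4, 0), "corner"), ((4, 4), "corner"),
        ((0, 2), "edge"), ((2, 0), "edge"), ((2, 4), "edge"), ((4, 2), "edge"),
        ((2, 2), "center"),
    ],
)
def test_spatial_position_of_boxes(cell, expected):
    assert classify_spatial_position(cell_code(*cell)) == expected


def test_spatial_position_rejects_pipe():
    with pytest.raises(ValueError):
        classify_spatial_position(cell_code(0, 1))
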