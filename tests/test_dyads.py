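import numpy as np
import pytest

from burrowtrack.dyads import (
    ACTIVE_STATE,
    MISSING,
    REST_STATE,
    binarize_activity,
    count_follows,
    count_synchrony,
    extract_movements,
    follow_result,
    proximity_restriction,
    proximity_result,
    synchrony_result,
    transform_follow_indices,
)
from burrowtrack.events import StayEvent
from burrowtrack.layout import UNKNOWN, cell_code

NEST = cell_code(2, 2)
OTHER = cell_code(2, 0)


# -- binarization ----------------------------------------------------------

def test_all_day_rest_binarizes_to_rest():
    events = [StayEvent(0, 0.0, 86400.0, NEST, "Rest")]
    v = binarize_activity(events, 86400.0)
    assert (v == REST_STATE).all()


def test_state_change_lands_on_the_right_sample():
    events = [
        StayEvent(0, 0.0, 43200.0, NEST, "Rest"),
        StayEvent(0, 43200.0, 86400.0, OTHER, "Other"),
    ]
    v = binarize_activity(events, 86400.0)
    assert (v[:4320] == REST_STATE).all()
    assert (v[4320:] == ACTIVE_STATE).all()


def test_disturbance_samples_are_missing():
    events = [StayEvent(0, 0.0, 86400.0, NEST, "Rest")]
    v = binarize_activity(events, 86400.0, exclusions=[(1000.0, 2000.0)])
    assert (v[100:200] == MISSING).all()
    assert (v[:100] == REST_STATE).all()


def test_unlocatable_gap_is_missing():
    events = [
        StayEvent(0, 0.0, 1000.0, OTHER, "Other"),
        StayEvent(0, 1000.0, 2000.0, UNKNOWN, "NA"),
        StayEvent(0, 2000.0, 86400.0, OTHER, "Other"),
    ]
    v = binarize_activity(events, 86400.0)
    assert (v[100:200] == MISSING).all()


# -- synchrony -------------------------------------------------------------

def test_identical_vectors_count_everything():
    a = np.zeros(100, dtype=np.int8)
    assert count_synchrony(a, a.copy()) == 100


def test_complementary_vectors_count_nothing():
    a = np.zeros(100, dtype=np.int8)
    b = np.ones(100, dtype=np.int8)
    assert count_synchrony(a, b) == 0


def test_synchrony_matches_brute_force_loop():
    rng = np.random.default_rng(0)
    a = rng.integers(-1, 2, 500).astype(np.int8)
    b = rng.integers(-1, 2, 500).astype(np.int8)
    expected = sum(
        1 for x, y in zip(a, b) if x != MISSING and y != MISSING and x == y
    )
    assert count_synchrony(a, b) == expected


def test_length_mismatch_raises():
    with pytest.raises(ValueError):
        count_synchrony(np.zeros(5, dtype=np.int8), np.zeros(6, dtype=np.int8))


def test_joint_shift_leaves_count_unchanged():
    """Exchangeability of the cyclic null: shifting both members by the
    same offset preserves the synchrony count."""
    rng = np.random.default_rng(1)
    a = rng.integers(0, 2, 300).astype(np.int8)
    b = rng.integers(0, 2, 300).astype(np.int8)
    base = count_synchrony(a, b)
    for off in (1, 17, 299):
        assert count_synchrony(np.roll(a, off), np.roll(b, off)) == base


def test_constant_vector_gives_undefined_index():
    a = np.zeros(200, dtype=np.int8)
    b = np.zeros(200, dtype=np.int8)
    res = synchrony_result(a, b, n_surrogates=49, seed=2)
    assert res.undefined
    assert res.klass == "ns"
    assert np.isnan(res.index)


def test_index_zero_when_actual_equals_surrogate_mean():
    """A perfectly periodic pair: every cyclic shift with matching parity
    gives the same count, so a manufactured symmetric case centers at 0."""
    a = np.tile([0, 1], 100).astype(np.int8)
    b = np.tile([0, 1], 100).astype(np.int8)
    res = synchrony_result(a, b, n_surrogates=500, seed=3)
    # shifts alternate between full match and zero match; the observed 200
    # sits at the top tail, index = (200 - mean)/sd with mean ~100
    assert res.n_actual == 200
    assert res.surrogate_mean == pytest.approx(100.0, rel=0.15)


# -- proximity -------------------------------------------------------------

def test_proximity_counts_shared_non_nest_cells():
    n = 1000
    loc_a = np.full(n, OTHER, dtype=np.int16)
    loc_b = np.full(n, OTHER, dtype=np.int16)
    act = np.zeros(n, dtype=np.int8)
    nest = np.full(n, NEST, dtype=np.int16)
    ra, rb = proximity_restriction(loc_a, loc_b, act, act, nest)
    assert ra.size == n
    assert np.count_nonzero(ra == rb) == n


def test_never_jointly_outside_nest_is_undefined():
    n = 100
    loc_a = np.full(n, NEST, dtype=np.int16)
    loc_b = np.full(n, OTHER, dtype=np.int16)
    act = np.zeros(n, dtype=np.int8)
    nest = np.full(n, NEST, dtype=np.int16)
    res = proximity_result(loc_a, loc_b, act, act, nest, n_surrogates=49, seed=4)
    assert res.undefined


def test_proximity_matches_brute_force_tally():
    rng = np.random.default_rng(5)
    n = 500
    cells = np.array([NEST, OTHER, cell_code(0, 2), cell_code(4, 2)])
    loc_a = cells[rng.integers(0, 4, n)].astype(np.int16)
    loc_b = cells[rng.integers(0, 4, n)].astype(np.int16)
    act_a = rng.integers(0, 2, n).astype(np.int8)
    act_b = rng.integers(0, 2, n).astype(np.int8)
    nest = np.full(n, NEST, dtype=np.int16)
    ra, rb = proximity_restriction(loc_a, loc_b, act_a, act_b, nest)
    expected = sum(
        1
        for k in range(n)
        if act_a[k] == 0 and act_b[k] == 0
        and loc_a[k] != NEST and loc_b[k] != NEST
        and loc_a[k] == loc_b[k]
    )
    assert int(np.count_nonzero(ra == rb)) == expected


# -- movements and follows -------------------------------------------------

def test_static_series_has_no_movements():
    cells = np.full(1000, NEST, dtype=np.int16)
    t, p = extract_movements(cells)
    assert t.size == 0


def test_back_and_forth_produces_two_events():
    cells = np.concatenate([
        np.full(10, cell_code(2, 2), dtype=np.int16),
        np.full(10, cell_code(2, 3), dtype=np.int16),
        np.full(10, cell_code(2, 2), dtype=np.int16),
    ])
    t, p = extract_movements(cells)
    assert t.size == 2
    assert p[0] == cell_code(2, 2) * 25 + cell_code(2, 3)
    assert p[1] == cell_code(2, 3) * 25 + cell_code(2, 2)


def test_movements_match_truth_crossing_list(layout, colony_day):
    """Movement events from a noise-free trajectory equal the simulator's
    changepoint list."""
    _, _, truth = colony_day
    i = 5
    t, p = extract_movements(truth.trajectory(i), truth.tick_s)
    ticks, cells = truth.changepoints[i]
    assert t.size == ticks.size - 1
    assert np.allclose(t, ticks[1:] * truth.tick_s)


def test_unknown_transitions_produce_no_event():
    cells = np.concatenate([
        np.full(10, NEST, dtype=np.int16),
        np.full(10, UNKNOWN, dtype=np.int16),
        np.full(10, OTHER, dtype=np.int16),
    ])
    t, _ = extract_movements(cells)
    assert t.size == 0


def _events(pairs):
    t = np.array([p[0] for p in pairs], dtype=float)
    paths = np.array([p[1] * 25 + p[2] for p in pairs], dtype=np.int32)
    return t, paths


def test_follow_directionality():
    te, pe = _events([(10.0, 1, 2)])
    tf, pf = _events([(11.0, 1, 2)])
    assert count_follows(te, pe, tf, pf) == 1  # follower repeats within 1 s
    assert count_follows(tf, pf, te, pe) == 0  # reverse direction: nothing


def test_follow_window_boundaries():
    te, pe = _events([(10.0, 1, 2)])
    assert count_follows(te, pe, *_events([(13.5, 1, 2)])) == 0  # beyond 3 s
    assert count_follows(te, pe, *_events([(13.0, 1, 2)])) == 1  # exactly 3 s
    assert count_follows(te, pe, *_events([(10.0, 1, 2)])) == 0  # window is open at t


def test_each_followee_event_counts_at_most_once():
    te, pe = _events([(10.0, 1, 2)])
    tf, pf = _events([(10.5, 1, 2), (11.0, 1, 2), (12.0, 1, 2)])
    assert count_follows(te, pe, tf, pf) == 1


def test_follow_count_matches_brute_force():
    rng = np.random.default_rng(6)
    te = np.sort(rng.uniform(0, 1000, 300))
    pe = rng.integers(0, 8, 300).astype(np.int32)
    tf = np.sort(rng.uniform(0, 1000, 300))
    pf = rng.integers(0, 8, 300).astype(np.int32)
    expected = sum(
        1
        for t, p in zip(te, pe)
        if np.any((tf > t) & (tf <= t + 3.0) & (pf == p))
    )
    assert count_follows(te, pe, tf, pf) == expected


def test_planted_follow_is_significant_in_one_direction(layout):
    from burrowtrack import ColonyConfig, simulate_colony

    follow = np.zeros((2, 2))
    follow[0, 1] = 0.9
    cfg = ColonyConfig(
        n_individuals=2, duration_s=43200.0, miss_rate=0.0, seed=31,
        disturbance_rate_per_day=0.0, follow=follow,
        rest_bout_mean_s=1800.0, active_bout_mean_s=3600.0,
    )
    _, truth = simulate_colony(cfg, layout)
    mov = {i: extract_movements(truth.trajectory(i), truth.tick_s) for i in (0, 1)}
    fwd = follow_result(*mov[1], *mov[0], pair=(0, 1), n_surrogates=199, seed=7)
    rev = follow_result(*mov[0], *mov[1], pair=(1, 0), n_surrogates=199, seed=8)
    assert fwd.klass == "significant_high"
    assert rev.klass != "significant_high"


# -- index transform -------------------------------------------------------

def test_transformed_indices_are_standardized():
    rng = np.random.default_rng(9)
    x = rng.exponential(2.0, 500)
    z = transform_follow_indices(x)
    assert z.mean() == pytest.approx(0.0, abs=1e-9)
    assert z.std() == pytest.approx(1.0, abs=1e-9)


def test_transform_preserves_order_and_propagates_nan():
    x = np.array([0.5, np.nan, 2.0, 1.0, 3.0])
    z = transform_follow_indices(x)
    assert np.isnan(z[1])
    finite = z[np.isfinite(z)]
    assert (np.diff(finite[np.argsort(x[np.isfinite(x)])]) > 0).all()


def test_transform_rejects_identical_input():
    with pytest.raises(ValueError):
        transform_follow_indices(np.full(10, 2.0))
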