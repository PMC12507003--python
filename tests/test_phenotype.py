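import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from burrowtrack.events import StayEvent
from burrowtrack.layout import cell_code
from burrowtrack.phenotype import (
    PARAM_COLUMNS,
    assign_representative_cluster,
    build_parameter_table,
    detect_embedding_outliers,
    extract_daily_parameters,
    normalize_parameters,
    segment_density,
)

NEST = cell_code(2, 2)
DAY = 86400.0


def test_single_all_day_rest_event():
    events = [StayEvent(0, 0.0, DAY, NEST, "Rest")]
    row = extract_daily_parameters(events, 0.0, DAY)
    assert row["sum_rest"] == pytest.approx(DAY)
    assert row["n_rest"] == 1
    assert row["mean_rest"] == pytest.approx(DAY)
    for col in PARAM_COLUMNS:
        if "rest" not in col:
            assert row[col] == 0.0


def test_relative_parameters_arithmetic():
    toilet = cell_code(0, 0)
    other = cell_code(2, 0)
    events = [
        StayEvent(0, 0.0, 10.0, toilet, "Toilet"),
        StayEvent(0, 10.0, 970.0, other, "Other"),
        StayEvent(0, 970.0, 1000.0, toilet, "Toilet"),
        StayEvent(0, 1000.0, DAY, NEST, "Rest"),
    ]
    row = extract_daily_parameters(events, 0.0, DAY)
    assert row["n_toilet"] == 2
    assert row["mean_toilet"] == pytest.approx(20.0)
    assert row["active_duration_s"] == pytest.approx(1000.0)
    assert row["sum_rel_toilet"] == pytest.approx(0.04)
    assert row["n_rel_toilet"] == pytest.approx(2 / 1000.0)


def test_sum_equals_n_times_mean_identity(colony_day_dataset):
    table = build_parameter_table(colony_day_dataset.events, n_days=1)
    for cat in ("rest", "nest", "toilet", "garbage", "other"):
        n = table[f"n_{cat}"]
        lhs = table[f"sum_{cat}"]
        rhs = n * table[f"mean_{cat}"]
        assert np.allclose(lhs, rhs)


def test_parameters_match_brute_force_tally(colony_day_dataset):
    """An independent per-event tally reproduces the table row."""
    ds = colony_day_dataset
    ind = 3
    table = build_parameter_table({ind: ds.events[ind]}, n_days=1)
    row = table.iloc[0]
    tally: dict = {}
    for ev in ds.events[ind]:
        if ev.category in (None, "NA"):
            continue
        d = min(ev.end_s, DAY) - max(ev.start_s, 0.0)
        if d > 0:
            tally.setdefault(ev.category, []).append(d)
    active = sum(sum(v) for c, v in tally.items() if c != "Rest")
    for cat, durs in tally.items():
        key = cat.lower()
        assert row[f"sum_{key}"] == pytest.approx(sum(durs))
        assert row[f"n_{key}"] == len(durs)
        if cat != "Rest":
            assert row[f"sum_rel_{key}"] == pytest.approx(sum(durs) / active)


def test_zero_active_duration_sets_relative_to_zero():
    events = [StayEvent(0, 0.0, DAY, NEST, "Rest")]
    row = extract_daily_parameters(events, 0.0, DAY)
    assert all(row[c] == 0.0 for c in PARAM_COLUMNS if "rel" in c)


def test_normalization_postconditions():
    rng = np.random.default_rng(2)
    rows = []
    for colony in (0, 1):
        for ind in range(8):
            for day in range(5):
                row = {c: float(rng.lognormal(2.0, 1.0)) for c in PARAM_COLUMNS}
                row.update({"colony": colony, "individual": ind, "day": day})
                rows.append(row)
    table = pd.DataFrame(rows)
    out = normalize_parameters(table)
    for (_, _), grp in out.groupby(["colony", "day"]):
        block = grp[list(PARAM_COLUMNS)].to_numpy()
        assert np.allclose(block.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(block.std(axis=0), 1.0, atol=1e-9)


def test_constant_column_zeroed_with_warning():
    rows = []
    for ind in range(4):
        for day in range(3):
            row = {c: float(ind + day + 1) for c in PARAM_COLUMNS}
            row["sum_rest"] = 5.0  # constant within the colony
            row.update({"colony": 0, "individual": ind, "day": day})
            rows.append(row)
    with pytest.warns(UserWarning, match="constant column"):
        out = normalize_parameters(pd.DataFrame(rows))
    assert (out["sum_rest"] == 0.0).all()


# -- density segmentation --------------------------------------------------

def test_two_separated_blobs_segment_cleanly():
    rng = np.random.default_rng(3)
    a = rng.normal([0, 0], 0.5, (150, 2))
    b = rng.normal([10, 10], 0.5, (150, 2))
    cmap = segment_density(np.vstack([a, b]), raster=256, blur_sigma=6.0)
    assert cmap.n_clusters == 2
    labels_a, labels_b = cmap.labels[:150], cmap.labels[150:]
    assert len(set(labels_a)) == 1
    assert len(set(labels_b)) == 1
    assert labels_a[0] != labels_b[0]


def test_three_blob_recovery_ari():
    rng = np.random.default_rng(4)
    pts = np.vstack([
        rng.normal([0, 0], 0.6, (100, 2)),
        rng.normal([8, 0], 0.6, (100, 2)),
        rng.normal([4, 7], 0.6, (100, 2)),
    ])
    truth = np.repeat([0, 1, 2], 100)
    cmap = segment_density(pts, raster=256, blur_sigma=6.0)
    assert adjusted_rand_score(truth, cmap.labels) >= 0.9


def test_extreme_minima_suppression_gives_one_cluster():
    rng = np.random.default_rng(5)
    pts = np.vstack([
        rng.normal([0, 0], 0.5, (100, 2)),
        rng.normal([10, 10], 0.5, (100, 2)),
    ])
    cmap = segment_density(pts, raster=256, blur_sigma=6.0, hmin_frac=1e9)
    assert cmap.n_clusters == 1
    assert (cmap.labels == 1).all()


def test_degenerate_embedding_warns_single_cluster():
    pts = np.zeros((20, 2))
    with pytest.warns(UserWarning, match="degenerate"):
        cmap = segment_density(pts)
    assert cmap.n_clusters == 1


def test_cluster_ids_ordered_by_size():
    rng = np.random.default_rng(6)
    pts = np.vstack([
        rng.normal([0, 0], 0.5, (200, 2)),
        rng.normal([10, 10], 0.5, (50, 2)),
    ])
    cmap = segment_density(pts, raster=256, blur_sigma=6.0)
    assert cmap.n_clusters == 2
    counts = np.bincount(cmap.labels)
    assert counts[1] > counts[2]


# -- outliers --------------------------------------------------------------

def test_no_outliers_flagged_in_clean_embedding():
    rng = np.random.default_rng(7)
    emb = rng.normal(0, 1, (300, 2))
    inds = np.repeat(np.arange(10), 30)
    excl, who = detect_embedding_outliers(emb, inds)
    assert len(excl) == 0 and who == []


def test_displaced_individual_is_excluded():
    rng = np.random.default_rng(8)
    emb = rng.normal(0, 1, (300, 2))
    inds = np.repeat(np.arange(10), 30)
    iqr = np.percentile(np.linalg.norm(emb - np.median(emb, 0), axis=1), 75) - \
        np.percentile(np.linalg.norm(emb - np.median(emb, 0), axis=1), 25)
    emb[inds == 4] += 10 * iqr * 10  # well beyond 10 IQRs
    excl, who = detect_embedding_outliers(emb, inds)
    assert who == [4]
    assert set(excl) == set(np.flatnonzero(inds == 4))


def test_infinite_threshold_flags_nothing():
    rng = np.random.default_rng(9)
    emb = rng.normal(0, 1, (100, 2))
    emb[0] += 100
    excl, who = detect_embedding_outliers(emb, np.arange(100), iqr_factor=np.inf)
    assert len(excl) == 0 and who == []


# -- representative cluster ------------------------------------------------

def _assignments(rows):
    return pd.DataFrame(rows, columns=["individual", "day", "cluster"])


def test_modal_cluster():
    rows = [(0, d, 2) for d in range(20)] + [(0, d + 20, 5) for d in range(10)]
    assert assign_representative_cluster(_assignments(rows), 0) == 2


def test_tie_goes_to_globally_rarer_cluster():
    rows = [(0, d, 1) for d in range(15)] + [(0, 15 + d, 4) for d in range(15)]
    rows += [(1, d, 1) for d in range(30)]  # cluster 1 globally commoner
    assert assign_representative_cluster(_assignments(rows), 0) == 4


def test_single_day_assignment():
    assert assign_representative_cluster(_assignments([(0, 0, 3)]), 0) == 3


def test_no_assignments_raises():
    with pytest.raises(ValueError):
        assign_representative_cluster(_assignments([(1, 0, 3)]), 0)
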