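"""Daily behavior vectors and density-based phenotype clustering.

Each individual-day is summarized by 23 parameters: total duration (Sum),
event count (N) and mean duration (Mean) for each of the five stay-event
categories, plus Sum and N normalized by the day's active (non-Rest)
duration for the four non-Rest categories.  Vectors are Box-Cox
transformed per colony and z-scored per colony-day, embedded with UMAP
(n_neighbors=5, min_dist=0.1), rasterized into a Gaussian-smoothed
density map, and segmented into clusters by watershed with depth-based
minima suppression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .events import CATEGORIES, NA, REST, StayEvent

PARAM_COLUMNS = (
    [f"sum_{c.lower()}" for c in CATEGORIES]
    + [f"n_{c.lower()}" for c in CATEGORIES]
    + [f"mean_{c.lower()}" for c in CATEGORIES]
    + [f"sum_rel_{c.lower()}" for c in CATEGORIES if c != REST]
    + [f"n_rel_{c.lower()}" for c in CATEGORIES if c != REST]
)
assert len(PARAM_COLUMNS) == 23


def _clip_to_window(
    events: Sequence[StayEvent], lo: float, hi: float,
    exclusions: Sequence[tuple[float, float]] = (),
) -> list[tuple[str, float]]:
    """(category, remaining duration) of events overlapping [lo, hi).

    Excluded intervals (disturbance phases) are cut out of the durations;
    events whose remaining duration is zero are dropped.  Event counts are
    taken over the surviving events, so a disturbance splitting an event
    never inflates N.
    """
    out = []
    for ev in events:
        if ev.category in (None, NA):
            continue
        a, b = max(ev.start_s, lo), min(ev.end_s, hi)
        if b <= a:
            continue
        dur = (b - a) - _excluded_overlap(a, b, exclusions)
        if dur > 0:
            out.append((ev.category, dur))
    return out


def _excluded_overlap(lo: float, hi: float, exclusions: Sequence[tuple[float, float]]) -> float:
    return sum(max(0.0, min(hi, e) - max(lo, s)) for s, e in exclusions)


def extract_daily_parameters(
    events: Sequence[StayEvent],
    day_start_s: float,
    day_end_s: float,
    exclusions: Sequence[tuple[float, float]] = (),
) -> dict[str, float]:
    """The 23 parameters for one individual over [day_start_s, day_end_s)."""
    clipped = _clip_to_window(events, day_start_s, day_end_s, exclusions)
    sums = {c: 0.0 for c in CATEGORIES}
    counts = {c: 0 for c in CATEGORIES}
    for cat, dur in clipped:
        sums[cat] += dur
        counts[cat] += 1
    row: dict[str, float] = {}
    for c in CATEGORIES:
        key = c.lower()
        row[f"sum_{key}"] = sums[c]
        row[f"n_{key}"] = float(counts[c])
        row[f"mean_{key}"] = sums[c] / counts[c] if counts[c] else 0.0
    active = sum(sums[c] for c in CATEGORIES if c != REST)
    for c in CATEGORIES:
        if c == REST:
            continue
        key = c.lower()
        if active > 0:
            row[f"sum_rel_{key}"] = sums[c] / active
            row[f"n_rel_{key}"] = counts[c] / active
        else:
            row[f"sum_rel_{key}"] = 0.0
            row[f"n_rel_{key}"] = 0.0
    row["active_duration_s"] = active
    return row


def build_parameter_table(
    events_by_individual: Mapping[object, Sequence[StayEvent]],
    n_days: int,
    day_length_s: float = 86400.0,
    exclusions: Sequence[tuple[float, float]] = (),
    colony: object = 0,
) -> pd.DataFrame:
    """One row per individual-day with the 23 named parameter columns."""
    rows = []
    for ind, evs in events_by_individual.items():
        for day in range(n_days):
            row = extract_daily_parameters(
                evs, day * day_length_s, (day + 1) * day_length_s, exclusions
            )
            row.update({"individual": ind, "day": day, "colony": colony})
            rows.append(row)
    cols = ["colony", "individual", "day", *PARAM_COLUMNS, "active_duration_s"]
    return pd.DataFrame(rows)[cols]


def normalize_parameters(table: pd.DataFrame) -> pd.DataFrame:
    """Box-Cox (per colony, values shifted by +1) then z-score per colony-day.

    Constant columns within a colony (Box-Cox) or colony-day (z) are left
    at zero with a warning.
    """
    out = table.copy()
    for colony, idx in out.groupby("colony").groups.items():
        for col in PARAM_COLUMNS:
            x = out.loc[idx, col].to_numpy(dtype=float) + 1.0
            if np.ptp(x) == 0:
                out.loc[idx, col] = 0.0
                warnings.warn(f"constant column {col!r} in colony {colony!r}", stacklevel=2)
                continue
            out.loc[idx, col], _ = stats.boxcox(x)
    for (_, _), idx in out.groupby(["colony", "day"]).groups.items():
        block = out.loc[idx, list(PARAM_COLUMNS)].to_numpy(dtype=float)
        mean = block.mean(axis=0)
        sd = block.std(axis=0)
        zero = sd == 0
        if zero.any():
            warnings.warn("constant column within a colony-day; z set to 0", stacklevel=2)
        sd[zero] = 1.0
        block = (block - mean) / sd
        block[:, zero] = 0.0
        out.loc[idx, list(PARAM_COLUMNS)] = block
    return out


@dataclass
class ClusterMap:
    """2-D embedding plus its watershed segmentation."""

    embedding: np.ndarray  # (n, 2)
    density: np.ndarray  # (raster, raster)
    extent: tuple[float, float, float, float]  # (xmin, xmax, ymin, ymax)
    labels: np.ndarray  # (n,) cluster ids 1..K, ordered by descending size
    n_clusters: int


def embed(
    matrix: np.ndarray,
    n_neighbors: int = 5,
    min_dist: float = 0.1,
    seed: int = 20,
) -> np.ndarray:
    """UMAP 2-D embedding with a pinned random state."""
    import umap  # deferred: heavy import

    if matrix.shape[0] < 2:
        raise ValueError("need at least two samples to embed")
    reducer = umap.UMAP(
        n_neighbors=min(n_neighbors, matrix.shape[0] - 1),
        min_dist=min_dist,
        n_components=2,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(reducer.fit_transform(matrix), dtype=float)


def auto_blur_sigma(points: np.ndarray, raster: int) -> float:
    """Sample-size-aware smoothing bandwidth for the density raster.

    Scott's factor ``n**(-1/6)`` applied to the smaller marginal standard
    deviation, expressed in raster pixels.  Scales the blur down as the
    embedding fills in, so sparse embeddings are not shattered into
    spurious density peaks.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    span = np.ptp(pts, axis=0)
    extent = span + 2 * 0.05 * np.where(span > 0, span, 1.0)
    std_px = np.std(pts, axis=0) / np.where(extent > 0, extent, 1.0) * raster
    sigma = float(n ** (-1 / 6) * std_px.min())
    return max(sigma, 2.0)


def segment_density(
    points: np.ndarray,
    raster: int = 512,
    blur_sigma: float | None = None,
    hmin_frac: float = 0.05,
) -> ClusterMap:
    """Watershed segmentation of the rasterized point density.

    The bounding box is padded by 5%, points are binned into a
    ``raster`` x ``raster`` histogram and smoothed isotropically with
    ``blur_sigma`` pixels (default: :func:`auto_blur_sigma`).  Watershed
    runs on the negated density after suppressing minima shallower than
    ``hmin_frac`` of the density maximum; clusters are renumbered 1..K
    by descending size.
    """
    from skimage.morphology import h_minima
    from skimage.segmentation import watershed

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = pts.shape[0]
    span = np.ptp(pts, axis=0)
    if n < 2 or np.all(span == 0):
        warnings.warn("degenerate embedding: single cluster", stacklevel=2)
        density = np.zeros((raster, raster))
        return ClusterMap(pts, density, (0, 1, 0, 1), np.ones(n, dtype=int), 1)
    if blur_sigma is None:
        blur_sigma = auto_blur_sigma(pts, raster)
    pad = 0.05 * np.where(span > 0, span, 1.0)
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    ix = np.clip(((pts[:, 0] - lo[0]) / (hi[0] - lo[0]) * raster).astype(int), 0, raster - 1)
    iy = np.clip(((pts[:, 1] - lo[1]) / (hi[1] - lo[1]) * raster).astype(int), 0, raster - 1)
    hist = np.zeros((raster, raster))
    np.add.at(hist, (iy, ix), 1.0)
    density = ndimage.gaussian_filter(hist, blur_sigma)
    elevation = density.max() - density
    h = hmin_frac * density.max()
    markers_mask = h_minima(elevation, h) if h > 0 else elevation == elevation.min()
    markers, n_marks = ndimage.label(markers_mask)
    if n_marks <= 1:
        labels = np.ones(n, dtype=int)
        return ClusterMap(pts, density, (lo[0], hi[0], lo[1], hi[1]), labels, 1)
    seg = watershed(elevation, markers)
    labels = seg[iy, ix].astype(int)
    # renumber by descending cluster size (ties by old id)
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {int(old): new for new, old in enumerate(order, start=1)}
    labels = np.array([remap[int(v)] for v in labels], dtype=int)
    return ClusterMap(pts, density, (lo[0], hi[0], lo[1], hi[1]), labels, len(ids))


def embed_and_segment(
    matrix: np.ndarray,
    n_neighbors: int = 5,
    min_dist: float = 0.1,
    seed: int = 20,
    raster: int = 512,
    blur_sigma: float | None = None,
    hmin_frac: float = 0.05,
) -> ClusterMap:
    """UMAP embedding followed by density/watershed segmentation."""
    return segment_density(
        embed(matrix, n_neighbors, min_dist, seed), raster, blur_sigma, hmin_frac
    )


def detect_embedding_outliers(
    embedding: np.ndarray,
    individuals: Sequence,
    iqr_factor: float = 5.0,
    individual_frac: float = 0.8,
) -> tuple[np.ndarray, list]:
    """Samples lying far outside the main distribution.

    A sample is flagged when its distance from the embedding median
    exceeds ``median + iqr_factor * IQR`` of the distance distribution.
    When at least ``individual_frac`` of one individual's samples are
    flagged, *all* of that individual's samples are excluded (and the
    embedding should be recomputed without them).

    Returns ``(excluded sample indices, excluded individuals)``.
    """
    emb = np.asarray(embedding, dtype=float)
    inds = np.asarray(individuals)
    center = np.median(emb, axis=0)
    d = np.linalg.norm(emb - center, axis=1)
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    thr = med + iqr_factor * (q3 - q1)
    flagged = d > thr
    excluded_individuals = []
    for ind in pd.unique(inds):
        mask = inds == ind
        if flagged[mask].mean() >= individual_frac and mask.sum() > 0:
            excluded_individuals.append(ind)
    if not excluded_individuals:
        return np.array([], dtype=int), []
    excl = np.flatnonzero(np.isin(inds, excluded_individuals))
    return excl, excluded_individuals


def assignment_table(
    table: pd.DataFrame, labels: np.ndarray
) -> pd.DataFrame:
    """Attach cluster labels to the (colony, individual, day) index."""
    out = table[["colony", "individual", "day"]].copy()
    out["cluster"] = labels
    return out


def assign_representative_cluster(assignments: pd.DataFrame, individual) -> int:
    """Modal cluster of an individual over its assigned days.

    Ties go to the cluster with the lowest overall occurrence across all
    individuals within the tied clusters (then to the smallest id).
    """
    own = assignments.loc[assignments["individual"] == individual, "cluster"]
    if own.empty:
        raise ValueError(f"individual {individual!r} has no assignments")
    counts = own.value_counts()
    top = counts[counts == counts.max()].index
    if len(top) == 1:
        return int(top[0])
    overall = assignments["cluster"].value_counts()
    return int(min(top, key=lambda k: (overall.get(k, 0), k)))
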