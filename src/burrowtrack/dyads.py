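"""Dyadic synchrony, proximity and follow indices under cyclic-shift nulls.

For each (directed) dyad an observed count is compared with a surrogate
distribution built by circularly shifting one member's vector, which
preserves that individual's autocorrelation while destroying the
cross-relationship.  The index is the z-standardized deviation of the
observed count from the surrogate distribution; the p-value is the rank
of the observed count among observed + surrogates, with significance
declared in the top or bottom 2.5% tail.

Counts
------
* synchrony: samples (10-s grid) where both individuals are in the same
  Rest/Active state;
* proximity: samples where both are active, outside the nest, and in the
  same grid cell — evaluated on vectors rebuilt over exactly the samples
  where both are simultaneously active outside the nest;
* follow: movement events (transitions between adjacent cells) of the
  followee that the follower re-traces within 3 s.  Surrogates shift the
  follower's trajectory labels while preserving event timing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .layout import UNKNOWN
from .events import REST, StayEvent

#: activity-vector states
ACTIVE_STATE, REST_STATE, MISSING = 0, 1, -1


def binarize_activity(
    events: Sequence[StayEvent],
    duration_s: float,
    interval_s: float = 10.0,
    exclusions: Sequence[tuple[float, float]] = (),
) -> np.ndarray:
    """Per-sample Rest(1)/Active(0)/MISSING(-1) states for one individual.

    A sample is Rest iff it falls inside a Rest event; samples inside an
    unlocatable gap or an excluded (disturbance) interval are MISSING.
    """
    n = int(round(duration_s / interval_s))
    out = np.full(n, ACTIVE_STATE, dtype=np.int8)

    def _span(lo_s: float, hi_s: float) -> tuple[int, int]:
        lo = int(np.ceil(lo_s / interval_s - 1e-9))
        hi = int(np.ceil(hi_s / interval_s - 1e-9))
        return max(lo, 0), min(hi, n)

    for ev in events:
        if ev.category == REST:
            lo, hi = _span(ev.start_s, ev.end_s)
            out[lo:hi] = REST_STATE
        elif ev.cell == UNKNOWN:
            lo, hi = _span(ev.start_s, ev.end_s)
            out[lo:hi] = MISSING
    for s, e in exclusions:
        lo, hi = _span(s, e)
        out[lo:hi] = MISSING
    return out


def count_synchrony(a: np.ndarray, b: np.ndarray) -> int:
    """Samples at which both vectors are defined and in the same state."""
    if a.shape != b.shape:
        raise ValueError("activity vectors must have equal length")
    defined = (a != MISSING) & (b != MISSING)
    return int(np.count_nonzero(defined & (a == b)))


@dataclass
class DyadResult:
    """Observed count, surrogate summary, index (z), p and significance."""

    a: object
    b: object
    n_actual: int
    surrogate_mean: float
    surrogate_sd: float
    index: float  # (actual - mean) / sd; NaN when sd == 0
    p: float  # tail proportion of the rank of the observed count
    klass: str  # significant_high | significant_low | ns
    n_surrogates: int
    undefined: bool = False


def _rank_significance(actual: float, sims: np.ndarray) -> tuple[float, str]:
    """Rank-based p and 2.5%-per-tail significance class."""
    total = sims.size + 1
    ge = int(np.count_nonzero(sims >= actual)) + 1
    le = int(np.count_nonzero(sims <= actual)) + 1
    p_hi, p_lo = ge / total, le / total
    if p_hi <= 0.025:
        return p_hi, "significant_high"
    if p_lo <= 0.025:
        return p_lo, "significant_low"
    return min(p_hi, p_lo), "ns"


def _summarize(a, b, actual: int, sims: np.ndarray, undefined: bool = False) -> DyadResult:
    if undefined or sims.size == 0:
        return DyadResult(a, b, actual, np.nan, np.nan, np.nan, np.nan, "ns",
                          sims.size, undefined=True)
    mean = float(sims.mean())
    sd = float(sims.std())
    if sd == 0.0:
        return DyadResult(a, b, actual, mean, 0.0, np.nan, np.nan, "ns",
                          sims.size, undefined=True)
    p, klass = _rank_significance(actual, sims)
    return DyadResult(a, b, actual, mean, sd, (actual - mean) / sd, p, klass, sims.size)


def _offsets(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """Circular-shift offsets drawn uniformly with replacement from 1..L-1."""
    if length < 2:
        raise ValueError("vectors too short for cyclic surrogates")
    return rng.integers(1, length, size=n)


def synchrony_result(
    a_states: np.ndarray,
    b_states: np.ndarray,
    pair: tuple = (0, 1),
    n_surrogates: int = 9999,
    seed: int = 0,
) -> DyadResult:
    """Synchrony index for one unordered dyad.

    MISSING samples are removed pairwise before counting; surrogates are
    cyclic shifts of the second member's compressed vector over the same
    index mask.
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates")
    mask = (a_states != MISSING) & (b_states != MISSING)
    av, bv = a_states[mask], b_states[mask]
    if av.size < 2:
        return _summarize(pair[0], pair[1], 0, np.empty(0), undefined=True)
    actual = int(np.count_nonzero(av == bv))
    rng = np.random.default_rng(seed)
    sims = np.empty(n_surrogates)
    for k, off in enumerate(_offsets(rng, av.size, n_surrogates)):
        sims[k] = np.count_nonzero(av == np.roll(bv, int(off)))
    return _summarize(pair[0], pair[1], actual, sims)


def proximity_restriction(
    loc_a: np.ndarray,
    loc_b: np.ndarray,
    act_a: np.ndarray,
    act_b: np.ndarray,
    nest_codes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Location vectors rebuilt over samples where both individuals are
    simultaneously active and outside the (time-varying) nest."""
    mask = (
        (act_a == ACTIVE_STATE) & (act_b == ACTIVE_STATE)
        & (loc_a != UNKNOWN) & (loc_b != UNKNOWN)
        & (loc_a != nest_codes) & (loc_b != nest_codes)
    )
    return loc_a[mask], loc_b[mask]


def proximity_result(
    loc_a: np.ndarray,
    loc_b: np.ndarray,
    act_a: np.ndarray,
    act_b: np.ndarray,
    nest_codes: np.ndarray,
    pair: tuple = (0, 1),
    n_surrogates: int = 9999,
    seed: int = 0,
) -> DyadResult:
    """Proximity index for one unordered dyad (counts equal-cell samples)."""
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates")
    ra, rb = proximity_restriction(loc_a, loc_b, act_a, act_b, nest_codes)
    if ra.size < 2:
        return _summarize(pair[0], pair[1], 0, np.empty(0), undefined=True)
    actual = int(np.count_nonzero(ra == rb))
    rng = np.random.default_rng(seed)
    sims = np.empty(n_surrogates)
    for k, off in enumerate(_offsets(rng, ra.size, n_surrogates)):
        sims[k] = np.count_nonzero(ra == np.roll(rb, int(off)))
    return _summarize(pair[0], pair[1], actual, sims)


def extract_movements(cells: np.ndarray, tick_s: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Movement events from a per-tick location series.

    Returns ``(times_s, paths)`` where each path encodes an ordered pair
    of cells as ``from * 25 + to``.  Transitions into or out of UNKNOWN
    produce no event.
    """
    change = np.flatnonzero(np.diff(cells) != 0) + 1
    src = cells[change - 1]
    dst = cells[change]
    ok = (src != UNKNOWN) & (dst != UNKNOWN)
    times = change[ok] * tick_s
    paths = src[ok].astype(np.int32) * 25 + dst[ok].astype(np.int32)
    return times, paths


def count_follows(
    followee_times: np.ndarray,
    followee_paths: np.ndarray,
    follower_times: np.ndarray,
    follower_paths: np.ndarray,
    window_s: float = 3.0,
) -> int:
    """Followee movement events re-traced by the follower within (t, t+w].

    Each followee event contributes at most one count, regardless of how
    many matching follower events fall inside its window.
    """
    if followee_times.size == 0 or follower_times.size == 0:
        return 0
    span = max(followee_times.max(), follower_times.max()) + window_s + 1.0
    key_b = np.sort(follower_paths.astype(np.float64) * span + follower_times)
    lo = followee_paths.astype(np.float64) * span + followee_times
    idx = np.searchsorted(key_b, lo, side="right")
    hit = (idx < key_b.size) & (key_b[np.minimum(idx, key_b.size - 1)] <= lo + window_s + 1e-9)
    return int(np.count_nonzero(hit))


def follow_result(
    followee_times: np.ndarray,
    followee_paths: np.ndarray,
    follower_times: np.ndarray,
    follower_paths: np.ndarray,
    pair: tuple = (0, 1),
    window_s: float = 3.0,
    n_surrogates: int = 999,
    seed: int = 0,
) -> DyadResult:
    """Follow index for one directed dyad (pair = (follower, followee)).

    Surrogates preserve the follower's movement timing and circularly
    shift its trajectory labels.
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates")
    if follower_times.size < 2 or followee_times.size == 0:
        return _summarize(pair[0], pair[1], 0, np.empty(0), undefined=True)
    actual = count_follows(followee_times, followee_paths,
                           follower_times, follower_paths, window_s)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_surrogates)
    for k, off in enumerate(_offsets(rng, follower_paths.size, n_surrogates)):
        sims[k] = count_follows(
            followee_times, followee_paths,
            follower_times, np.roll(follower_paths, int(off)), window_s,
        )
    return _summarize(pair[0], pair[1], actual, sims)


def transform_follow_indices(indices: np.ndarray) -> np.ndarray:
    """Yeo-Johnson (MLE lambda) then z-transform across all directed dyads.

    NaN (undefined) entries propagate unchanged.
    """
    x = np.asarray(indices, dtype=float)
    finite = np.isfinite(x)
    vals = x[finite]
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ValueError("need at least two distinct finite indices")
    transformed, _ = stats.yeojohnson(vals)
    z = (transformed - transformed.mean()) / transformed.std()
    out = np.full_like(x, np.nan)
    out[finite] = z
    return out


# -- colony-level drivers --------------------------------------------------

def synchrony_results(
    activity: Mapping[object, np.ndarray],
    n_surrogates: int = 9999,
    seed: int = 0,
) -> list[DyadResult]:
    """Synchrony indices for every unordered dyad of a colony."""
    inds = list(activity)
    out = []
    for i, a in enumerate(inds):
        for j in range(i + 1, len(inds)):
            b = inds[j]
            s = int(np.random.SeedSequence((seed, i, j)).generate_state(1)[0]) >> 1
            out.append(synchrony_result(activity[a], activity[b], (a, b),
                                        n_surrogates, s))
    return out


def proximity_results(
    locations10: Mapping[object, np.ndarray],
    activity: Mapping[object, np.ndarray],
    nest_codes: np.ndarray,
    n_surrogates: int = 9999,
    seed: int = 0,
) -> list[DyadResult]:
    """Proximity indices for every unordered dyad of a colony."""
    inds = list(locations10)
    out = []
    for i, a in enumerate(inds):
        for j in range(i + 1, len(inds)):
            b = inds[j]
            s = int(np.random.SeedSequence((seed, i, j)).generate_state(1)[0]) >> 1
            out.append(
                proximity_result(locations10[a], locations10[b],
                                 activity[a], activity[b], nest_codes,
                                 (a, b), n_surrogates, s)
            )
    return out


def follow_results(
    movements: Mapping[object, tuple[np.ndarray, np.ndarray]],
    window_s: float = 3.0,
    n_surrogates: int = 999,
    seed: int = 0,
) -> list[DyadResult]:
    """Follow indices for every directed dyad (follower, followee)."""
    inds = list(movements)
    out = []
    for i, follower in enumerate(inds):
        for j, followee in enumerate(inds):
            if follower == followee:
                continue
            ft, fp = movements[follower]
            et, ep = movements[followee]
            s = int(np.random.SeedSequence((seed, i, j)).generate_state(1)[0]) >> 1
            out.append(follow_result(et, ep, ft, fp, (follower, followee),
                                     window_s, n_surrogates, s))
    return out
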