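"""Within-individual phenotype consistency and colony-level stability.

The consistency index of an individual is ``1 - H / ln K`` where ``H`` is
the Shannon entropy (nats) of its daily cluster-assignment frequencies
and ``K`` the number of clusters: 1 means always the same cluster, 0 a
uniform spread.  Significance comes from a Monte-Carlo null that re-draws
day labels i.i.d. from the pooled cluster frequencies.  Day-to-day
cluster stability is measured by cosine similarity of consecutive-day
membership vectors against a within-day shuffle null, and cluster
co-assignment by the ratio of empirical within-individual co-occurrence
to the independence baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .events import REST, StayEvent


def cluster_frequencies(assignments: pd.DataFrame, n_clusters: int) -> pd.DataFrame:
    """Per-individual assignment frequencies P_i(k), one row per individual."""
    rows = {}
    for ind, grp in assignments.groupby("individual", sort=False):
        counts = np.bincount(grp["cluster"].to_numpy() - 1, minlength=n_clusters)
        rows[ind] = counts / counts.sum()
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[k + 1 for k in range(n_clusters)])


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0 * ln 0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def consistency_index(p: np.ndarray, n_clusters: int) -> float:
    """``1 - H / ln K`` for one individual's assignment frequencies."""
    if n_clusters < 2:
        raise ValueError("need at least two clusters")
    return 1.0 - shannon_entropy(p) / np.log(n_clusters)


def _simulated_indices(
    mean_probs: np.ndarray, n_days: int, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    counts = rng.multinomial(n_days, mean_probs, size=n_sims)
    p = counts / n_days
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(p > 0, np.log(p), 0.0)
    h = -(p * logs).sum(axis=1)
    return 1.0 - h / np.log(mean_probs.size)


def consistency_null(
    mean_probs: np.ndarray,
    observed: np.ndarray | float,
    n_days: int = 30,
    n_sims: int = 10000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo null for the consistency index.

    Each simulation draws ``n_days`` i.i.d. cluster labels from
    ``mean_probs`` (the pooled assignment frequencies).  The null depends
    only on ``mean_probs``, so one simulated distribution is shared by all
    individuals.  p-values use the add-one convention
    ``p = (1 + #{sim >= obs}) / (1 + n_sims)``.

    Returns ``(simulated index values, p-values)``.
    """
    mean_probs = np.asarray(mean_probs, dtype=float)
    if not np.isclose(mean_probs.sum(), 1.0):
        raise ValueError("mean_probs must sum to 1")
    rng = np.random.default_rng(seed)
    sims = _simulated_indices(mean_probs, n_days, n_sims, rng)
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    ge = (sims[None, :] >= obs[:, None] - 1e-12).sum(axis=1)
    p = (1 + ge) / (1 + n_sims)
    return sims, p


def consistency_results(
    assignments: pd.DataFrame,
    n_clusters: int,
    n_sims: int = 10000,
    seed: int = 0,
    by_colony: bool = False,
) -> pd.DataFrame:
    """Consistency index, entropy and Monte-Carlo p per individual.

    The null draws from the pooled (global) cluster frequencies by
    default; ``by_colony=True`` uses colony-specific frequencies instead
    (requires a ``colony`` column).
    """
    freq = cluster_frequencies(assignments, n_clusters)
    n_days = int(assignments.groupby("individual")["day"].count().max())
    h = freq.apply(lambda r: shannon_entropy(r.to_numpy()), axis=1)
    index = 1.0 - h / np.log(n_clusters)

    def _null_probs(table: pd.DataFrame) -> np.ndarray:
        pooled = np.bincount(table["cluster"].to_numpy() - 1, minlength=n_clusters)
        return pooled / pooled.sum()

    p = pd.Series(np.nan, index=freq.index)
    if by_colony:
        if "colony" not in assignments.columns:
            raise ValueError("by_colony=True requires a 'colony' column")
        for colony, grp in assignments.groupby("colony"):
            members = [i for i in freq.index
                       if i in set(grp["individual"])]
            _, pc = consistency_null(_null_probs(grp),
                                     index.loc[members].to_numpy(),
                                     n_days, n_sims, seed)
            p.loc[members] = pc
    else:
        _, p[:] = consistency_null(_null_probs(assignments), index.to_numpy(),
                                   n_days, n_sims, seed)
    return pd.DataFrame({
        "individual": freq.index,
        "H": h.to_numpy(),
        "index": index.to_numpy(),
        "p": p.to_numpy(),
        "significant": p.to_numpy() <= 0.05,
    }).reset_index(drop=True)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0  # a day with an empty membership vector
    return float(a @ b / (na * nb))


def cluster_stability_cosine(
    assignments: pd.DataFrame,
    cluster: int,
    individuals: Sequence,
    n_shuffles: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Consecutive-day cosine similarity of one cluster's membership.

    Builds the binary individual-membership vector for each day and
    returns the observed consecutive-day cosine similarities together
    with the shuffle null (element shuffles within each day's vector,
    ``(n_days - 1) * n_shuffles`` values).
    """
    individuals = list(individuals)
    days = sorted(assignments["day"].unique())
    member = {(r.individual, r.day) for r in assignments.itertuples() if r.cluster == cluster}
    vectors = np.array(
        [[1.0 if (ind, day) in member else 0.0 for ind in individuals] for day in days]
    )
    observed = np.array([_cosine(vectors[d], vectors[d + 1]) for d in range(len(days) - 1)])
    rng = np.random.default_rng(seed)
    null = np.empty((len(days) - 1) * n_shuffles)
    k = 0
    for _ in range(n_shuffles):
        shuffled = np.array([rng.permutation(v) for v in vectors])
        for d in range(len(days) - 1):
            null[k] = _cosine(shuffled[d], shuffled[d + 1])
            k += 1
    return observed, null


@dataclass
class CoAssignmentMatrix:
    """Empirical vs independence-baseline within-individual co-assignment."""

    c_emp: np.ndarray
    c_ref: np.ndarray
    index: np.ndarray  # c_emp / c_ref; NaN where c_ref == 0
    n_individuals: int


def co_assignment(freq: pd.DataFrame) -> CoAssignmentMatrix:
    """Co-assignment index for every cluster pair.

    ``freq`` is the per-individual frequency table from
    :func:`cluster_frequencies`.  ``C_emp(k, l)`` is the mean over
    individuals of ``P_i(k) P_i(l)``; ``C_ref(k, l) = mean(P(k)) *
    mean(P(l))``; the index is their ratio.
    """
    p = freq.to_numpy(dtype=float)
    if p.shape[0] == 0:
        raise ValueError("no individuals with assignments")
    c_emp = (p[:, :, None] * p[:, None, :]).mean(axis=0)
    pbar = p.mean(axis=0)
    c_ref = np.outer(pbar, pbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        index = np.where(c_ref > 0, c_emp / c_ref, np.nan)
    return CoAssignmentMatrix(c_emp, c_ref, index, p.shape[0])


@dataclass
class LeadershipRecord:
    """Rank order of first rest-initiation in a newly designated nest."""

    event_id: int
    transition_time_s: float
    new_nest: int
    ranks: dict  # individual -> tie-averaged rank
    included: bool


def leadership_ranks(
    events_by_individual: Mapping[object, Sequence[StayEvent]],
    transitions: Sequence[tuple[float, int, int]],
    colony_size: int | None = None,
    pre_s: float = 7200.0,
    post_s: float = 43200.0,
    inclusion: float = 0.8,
) -> list[LeadershipRecord]:
    """Leadership ranks for each nest transition.

    For each transition (from :meth:`ChamberAnnotation.transitions`),
    individuals are ranked by the start of their first Rest event in the
    new nest within [T - 2 h, T + 12 h]; ties get averaged ranks.
    Transitions in which at most ``inclusion`` of the colony participates
    are recorded but flagged excluded.
    """
    if colony_size is None:
        colony_size = len(events_by_individual)
    out = []
    for eid, (t, _, new_nest) in enumerate(transitions):
        onsets = {}
        for ind, evs in events_by_individual.items():
            first = [
                ev.start_s
                for ev in evs
                if ev.category == REST and ev.cell == new_nest
                and t - pre_s <= ev.start_s <= t + post_s
            ]
            if first:
                onsets[ind] = min(first)
        included = len(onsets) > inclusion * colony_size
        inds = list(onsets)
        ranks = rankdata([onsets[i] for i in inds]) if inds else np.array([])
        out.append(
            LeadershipRecord(
                event_id=eid,
                transition_time_s=t,
                new_nest=new_nest,
                ranks={ind: float(r) for ind, r in zip(inds, ranks)},
                included=included,
            )
        )
    return out
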