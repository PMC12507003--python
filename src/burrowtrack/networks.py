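"""Significance-thresholded social networks and strength centrality.

Dyads classified significant-high form the edges of an undirected
(synchrony, proximity) or directed (follow, follower -> followee) weighted
network, with the index as the edge weight.  Strength centrality is the
sum of incident edge weights; for directed networks out-strength sums a
node's following edges and in-strength the edges by which it is followed.
Temporal robustness is assessed by re-running the full dyadic pipeline on
consecutive multi-day subsets of the recording.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dyads import (
    DyadResult,
    binarize_activity,
    follow_results,
    proximity_results,
    synchrony_results,
)
from .events import StayEvent


def build_network(
    results: Sequence[DyadResult],
    directed: bool = False,
    nodes: Sequence | None = None,
) -> nx.Graph | nx.DiGraph:
    """Weighted network over all individuals from classified dyad results.

    Only ``significant_high`` dyads contribute edges; for directed
    (follow) networks edges run follower -> followee.
    """
    g = nx.DiGraph() if directed else nx.Graph()
    if nodes is None:
        nodes = sorted({r.a for r in results} | {r.b for r in results}, key=str)
    g.add_nodes_from(nodes)
    for r in results:
        if r.klass == "significant_high" and np.isfinite(r.index):
            g.add_edge(r.a, r.b, weight=float(r.index))
    return g


def strength_centrality(
    net: nx.Graph | nx.DiGraph, mode: str = "all"
) -> dict:
    """Sum of incident edge weights per node (isolated nodes get 0).

    ``mode`` is ``all`` for undirected networks, ``in``/``out`` for
    directed ones (out = acting as follower, in = being followed).
    """
    directed = net.is_directed()
    if mode == "all":
        if directed:
            raise ValueError("mode='all' applies to undirected networks")
        deg = net.degree(weight="weight")
    elif mode in ("in", "out"):
        if not directed:
            raise ValueError("in/out-strength requires a directed network")
        deg = net.in_degree(weight="weight") if mode == "in" else net.out_degree(weight="weight")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {n: float(w) for n, w in deg}


def _clip_events(
    events: Sequence[StayEvent], lo: float, hi: float
) -> list[StayEvent]:
    out = []
    for ev in events:
        a, b = max(ev.start_s, lo), min(ev.end_s, hi)
        if b > a:
            out.append(StayEvent(ev.individual, a - lo, b - lo, ev.cell, ev.category))
    return out


def time_split_recompute(
    events_by_individual: Mapping[object, Sequence[StayEvent]],
    duration_s: float,
    relationship: str,
    n_subsets: int = 6,
    locations10: Mapping[object, np.ndarray] | None = None,
    nest_codes: np.ndarray | None = None,
    interval_s: float = 10.0,
    window_s: float = 3.0,
    n_surrogates: int | None = None,
    exclusions: Sequence[tuple[float, float]] = (),
    seed: int = 0,
    movements: Mapping[object, tuple[np.ndarray, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Strength centralities over consecutive equal subsets of the recording.

    The full dyadic pipeline — counts, surrogates, significance, network —
    is re-run independently within each subset, so significance thresholds
    are re-derived per subset.  Returns a long-form table with columns
    ``individual, subset, mode, value``.
    """
    if relationship not in ("synchrony", "proximity", "follow"):
        raise ValueError(f"unknown relationship {relationship!r}")
    if n_surrogates is None:
        n_surrogates = 9999 if relationship == "synchrony" else 999
    sub_len = duration_s / n_subsets
    inds = list(events_by_individual)
    rows = []
    for k in range(n_subsets):
        lo, hi = k * sub_len, (k + 1) * sub_len
        sub_excl = [(max(s, lo) - lo, min(e, hi) - lo) for s, e in exclusions
                    if min(e, hi) > max(s, lo)]
        if relationship == "follow":
            if movements is None:
                raise ValueError("follow recompute needs per-individual movements")
            sub_mov = {}
            for ind in inds:
                t, p = movements[ind]
                m = (t >= lo) & (t < hi)
                sub_mov[ind] = (t[m] - lo, p[m])
            res = follow_results(sub_mov, window_s, n_surrogates, seed + k)
            net = build_network(res, directed=True, nodes=inds)
            for mode in ("in", "out"):
                for ind, v in strength_centrality(net, mode).items():
                    rows.append({"individual": ind, "subset": k, "mode": mode, "value": v})
            continue
        sub_events = {ind: _clip_events(events_by_individual[ind], lo, hi) for ind in inds}
        activity = {
            ind: binarize_activity(sub_events[ind], hi - lo, interval_s, sub_excl)
            for ind in inds
        }
        if relationship == "synchrony":
            res = synchrony_results(activity, n_surrogates, seed + k)
        else:
            if locations10 is None or nest_codes is None:
                raise ValueError("proximity recompute needs locations10 and nest_codes")
            i0, i1 = int(round(lo / interval_s)), int(round(hi / interval_s))
            sub_loc = {ind: locations10[ind][i0:i1] for ind in inds}
            res = proximity_results(sub_loc, activity, nest_codes[i0:i1],
                                    n_surrogates, seed + k)
        net = build_network(res, directed=False, nodes=inds)
        for ind, v in strength_centrality(net, "all").items():
            rows.append({"individual": ind, "subset": k, "mode": "all", "value": v})
    return pd.DataFrame(rows, columns=["individual", "subset", "mode", "value"])
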