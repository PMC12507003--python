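"""End-to-end pipeline driver: simulate -> track -> events -> phenotype ->
stability -> dyads -> networks.

Every stage parameter lives in :class:`PipelineConfig` with the standard
default; unknown configuration keys are rejected.  All randomness flows
from the config seed, and a manifest with the seed, parameters and
per-stage record counts accompanies every run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as btio
from .dyads import binarize_activity, extract_movements, follow_results, \
    proximity_results, synchrony_results, transform_follow_indices
from .events import build_events, detect_disturbances, make_annotation, rest_fraction
from .layout import default_layout
from .networks import build_network, strength_centrality
from .phenotype import assignment_table, build_parameter_table, embed_and_segment, \
    normalize_parameters
from .simulate import ColonyConfig, simulate_colony
from .stability import cluster_frequencies, co_assignment, consistency_results
from .tracking import compute_error_rate, downsample, reconstruct_locations


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending context."""


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, with standard defaults."""

    out_dir: str = "burrowtrack_out"
    seed: int = 0
    # simulation
    n_individuals: int = 20
    duration_days: float = 2.0
    disturbance_rate_per_day: float = 2.0
    miss_rate: float = 0.02
    # tracking
    tick_s: float = 0.1
    redetect_s: float = 0.3
    # events
    rest_threshold_s: float = 600.0
    disturbance_low: float = 0.25
    disturbance_dip: float = 0.10
    # dyadic analysis
    interval_s: float = 10.0
    follow_window_s: float = 3.0
    n_surrogates_synchrony: int = 199
    n_surrogates_proximity: int = 199
    n_surrogates_follow: int = 199
    # clustering
    umap_neighbors: int = 5
    umap_min_dist: float = 0.1
    raster: int = 512
    blur_sigma: float | None = None  # None = sample-size-aware auto rule
    hmin_frac: float = 0.05

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(btio.load_yaml(path))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a simulated colony and write all artifacts.

    Returns a summary dict (also written as ``manifest.json``).  Results
    are deterministic given an identical config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = default_layout()
    duration_s = config.duration_days * 86400.0
    counts: dict[str, int] = {}

    sim_cfg = ColonyConfig(
        n_individuals=config.n_individuals,
        duration_s=duration_s,
        tick_s=config.tick_s,
        disturbance_rate_per_day=config.disturbance_rate_per_day,
        miss_rate=config.miss_rate,
        seed=config.seed,
    )
    log, truth = simulate_colony(sim_cfg, layout)
    btio.write_detections(log, out / "detections.csv")
    counts["detections"] = len(log)

    try:
        series = reconstruct_locations(
            log, layout, duration_s, config.tick_s, config.redetect_s,
            individuals=range(config.n_individuals),
        )
    except Exception as exc:
        raise PipelineError(f"stage 'track' failed: {exc}") from exc
    error_rate = compute_error_rate(series)

    annotation = make_annotation(series, layout, sim_cfg.toilet_cell, sim_cfg.garbage_cell)
    events = build_events(series, annotation, layout, duration_s, config.rest_threshold_s)
    btio.write_events(events, out / "events.csv")
    counts["stay_events"] = sum(len(v) for v in events.values())

    rf = rest_fraction(events, duration_s, config.interval_s)
    disturbances = detect_disturbances(rf, config.interval_s,
                                       config.disturbance_low, config.disturbance_dip)
    btio.write_table(
        pd.DataFrame(disturbances, columns=["start_s", "end_s"]),
        out / "disturbances.csv",
    )
    counts["disturbance_intervals"] = len(disturbances)

    n_days = max(int(round(config.duration_days)), 1)
    params = build_parameter_table(events, n_days, 86400.0, disturbances)
    btio.write_table(params, out / "parameters.csv")
    normalized = normalize_parameters(params)
    from .phenotype import PARAM_COLUMNS

    cmap = embed_and_segment(
        normalized[list(PARAM_COLUMNS)].to_numpy(),
        config.umap_neighbors, config.umap_min_dist, config.seed,
        config.raster, config.blur_sigma, config.hmin_frac,
    )
    assignments = assignment_table(params, cmap.labels)
    btio.write_table(assignments, out / "assignments.csv")
    counts["clusters"] = cmap.n_clusters

    if cmap.n_clusters >= 2:
        cons = consistency_results(assignments, cmap.n_clusters,
                                   n_sims=999, seed=config.seed)
        btio.write_table(cons, out / "consistency.csv")
        freq = cluster_frequencies(assignments, cmap.n_clusters)
        co = co_assignment(freq)
        k = co.index.shape[0]
        co_long = pd.DataFrame(
            [(i + 1, j + 1, co.index[i, j]) for i in range(k) for j in range(k)],
            columns=["cluster_k", "cluster_l", "index"],
        )
        btio.write_table(co_long, out / "co_assignment.csv")

    activity = {
        i: binarize_activity(events[i], duration_s, config.interval_s, disturbances)
        for i in events
    }
    sync = synchrony_results(activity, config.n_surrogates_synchrony, config.seed)
    btio.write_dyads(sync, out / "dyads_synchrony.csv")

    loc10 = {i: downsample(series[i], config.interval_s) for i in series}
    prox = proximity_results(loc10, activity, annotation.nest_code,
                             config.n_surrogates_proximity, config.seed)
    btio.write_dyads(prox, out / "dyads_proximity.csv")

    movements = {i: extract_movements(series[i].cells, config.tick_s) for i in series}
    fol = follow_results(movements, config.follow_window_s,
                         config.n_surrogates_follow, config.seed)
    fol_frame = btio.dyads_to_frame(fol)
    finite = np.isfinite(fol_frame["index"].to_numpy(dtype=float))
    if finite.sum() >= 2 and fol_frame.loc[finite, "index"].nunique() > 1:
        fol_frame["index_transformed"] = transform_follow_indices(
            fol_frame["index"].to_numpy(dtype=float)
        )
    btio.write_table(fol_frame, out / "dyads_follow.csv")

    nets = {
        "synchrony": build_network(sync, directed=False, nodes=list(events)),
        "proximity": build_network(prox, directed=False, nodes=list(events)),
        "follow": build_network(fol, directed=True, nodes=list(events)),
    }
    centrality_rows = []
    for name, net in nets.items():
        btio.write_graphml(net, out / f"network_{name}.graphml")
        modes = ("in", "out") if net.is_directed() else ("all",)
        for mode in modes:
            for ind, v in strength_centrality(net, mode).items():
                centrality_rows.append(
                    {"individual": ind, "network": name, "mode": mode, "value": v}
                )
    btio.write_table(pd.DataFrame(centrality_rows), out / "centrality.csv")
    counts["significant_edges"] = sum(n.number_of_edges() for n in nets.values())

    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "parameters": dataclasses.asdict(config),
        "record_counts": counts,
        "error_rate": error_rate,
        "n_clusters": cmap.n_clusters,
    }
    btio.write_manifest(out / "manifest.json", **summary)
    return summary
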