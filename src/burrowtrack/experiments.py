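"""Parameter-recovery and calibration experiments on synthetic colonies.

Because the raw colony recordings behind the method are not deposited,
the pipeline is validated by construction: simulate a colony with known
(planted) structure, run the full analysis, and measure how well each
stage recovers the truth.  These drivers are shared by the test suite
and the acceptance script; each takes an explicit seed and returns plain
dictionaries of measured quantities.

Problem sizes are desk-scale by design: colonies of 10-46 individuals
over 2 h - 10 days with 199 cyclic surrogates, which keeps every
experiment within minutes on one CPU while leaving all statistical
machinery identical to the full-scale analysis.
"""

from __future__ import annotations

import numpy as np

from .dyads import binarize_activity, follow_result, synchrony_result
from .layout import UNKNOWN, default_layout
from .simulate import ColonyConfig, emit_detection_log, simulate_colony
from .tracking import compute_error_rate, reconstruct_locations
from .workflow import process_colony


def tracking_fidelity(seed: int = 0, n_individuals: int = 10,
                      duration_s: float = 7200.0) -> dict:
    """Reconstruction vs ground truth on a noise-free log, and the NA
    error rate under 10% detection dropout checked against a brute-force
    tally.

    Returns defined-tick mismatch counts (exactness) and both error
    rates.
    """
    layout = default_layout()
    cfg = ColonyConfig(n_individuals=n_individuals, duration_s=duration_s,
                       miss_rate=0.0, disturbance_rate_per_day=0.0, seed=seed)
    log, truth = simulate_colony(cfg, layout)
    series = reconstruct_locations(log, layout, duration_s,
                                   individuals=range(n_individuals))
    mismatches = defined = 0
    for i in range(n_individuals):
        rec = series[i].cells
        mask = rec != UNKNOWN
        defined += int(mask.sum())
        mismatches += int((truth.trajectory(i)[mask] != rec[mask]).sum())
    clean_error = compute_error_rate(series)

    noisy_log = emit_detection_log(truth, layout, miss_rate=0.1, seed=seed + 1)
    noisy = reconstruct_locations(noisy_log, layout, duration_s,
                                  individuals=range(n_individuals))
    brute_na = sum(int(np.count_nonzero(s.cells == UNKNOWN)) for s in noisy.values())
    total = sum(s.cells.size for s in noisy.values())
    return {
        "defined_ticks": defined,
        "mismatched_ticks": mismatches,
        "clean_error_rate": clean_error,
        "noisy_error_rate": compute_error_rate(noisy),
        "brute_force_error_rate": brute_na / total,
    }


def synchrony_calibration(seed: int = 0, n_dyads: int = 200,
                          n_surrogates: int = 199,
                          duration_s: float = 43200.0) -> dict:
    """Type-I calibration of the cyclic-shift null on independent dyads.

    Simulates ``2 * n_dyads`` fully independent individuals, pairs them
    disjointly, and reports the significant fraction at the 2.5%+2.5%
    rule together with the index mean and sd across dyads.
    """
    layout = default_layout()
    n = 2 * n_dyads
    cfg = ColonyConfig(n_individuals=n, duration_s=duration_s, miss_rate=0.0,
                       disturbance_rate_per_day=0.0, seed=seed)
    log, _ = simulate_colony(cfg, layout)
    ds = process_colony(log, layout, duration_s, range(n))
    activity = {
        i: binarize_activity(ds.events[i], duration_s, exclusions=ds.disturbances)
        for i in range(n)
    }
    indices, significant = [], 0
    for k in range(n_dyads):
        r = synchrony_result(activity[2 * k], activity[2 * k + 1],
                             (2 * k, 2 * k + 1), n_surrogates, seed * 1000 + k)
        if r.undefined:
            continue
        indices.append(r.index)
        significant += r.klass != "ns"
    indices = np.asarray(indices)
    return {
        "n_dyads": n_dyads,
        "significant_fraction": significant / n_dyads,
        "index_mean": float(indices.mean()),
        "index_sd": float(indices.std()),
    }


def coupling_follow_recovery(base_seed: int = 0, n_seeds: int = 20,
                             n_surrogates: int = 199,
                             duration_s: float = 43200.0) -> dict:
    """Recovery of planted rest-coupling and directional follow relations.

    Each replicate simulates one colony holding ten rest-coupled pairs
    (coupling 0.9), ten independent pairs, and three follower-followee
    pairs (follow 1.0; shadowing followers do not self-rest).  Measures:

    * the fraction of replicates in which *every* coupled dyad's
      synchrony index exceeds the median of the independent dyads;
    * the fraction of planted follow pairs that come out significant in
      the planted direction and non-significant in the reverse.
    """
    layout = default_layout()
    n = 46
    coupling = np.zeros((n, n))
    for k in range(10):
        coupling[2 * k, 2 * k + 1] = coupling[2 * k + 1, 2 * k] = 0.9
    follow = np.zeros((n, n))
    active = np.full(n, 1800.0)
    for k in range(3):
        follow[40 + 2 * k, 41 + 2 * k] = 1.0
        active[40 + 2 * k] = 1e9
    seeds_all_above = 0
    follow_ok = follow_total = 0
    for r in range(n_seeds):
        seed = base_seed + r
        cfg = ColonyConfig(n_individuals=n, duration_s=duration_s, miss_rate=0.0,
                           disturbance_rate_per_day=0.0, seed=seed,
                           coupling=coupling, follow=follow,
                           active_bout_mean_s=active)
        log, _ = simulate_colony(cfg, layout)
        ds = process_colony(log, layout, duration_s, range(n))
        activity = {
            i: binarize_activity(ds.events[i], duration_s, exclusions=ds.disturbances)
            for i in range(n)
        }
        coupled = [
            synchrony_result(activity[2 * k], activity[2 * k + 1],
                             (2 * k, 2 * k + 1), n_surrogates,
                             seed * 1000 + k).index
            for k in range(10)
        ]
        independent = [
            synchrony_result(activity[20 + 2 * k], activity[21 + 2 * k],
                             (20 + 2 * k, 21 + 2 * k), n_surrogates,
                             seed * 1000 + 50 + k).index
            for k in range(10)
        ]
        median = float(np.median(independent))
        seeds_all_above += all(c > median for c in coupled)
        for k in range(3):
            a, b = 40 + 2 * k, 41 + 2 * k
            fwd = follow_result(*ds.movements[b], *ds.movements[a], (a, b),
                                n_surrogates=n_surrogates,
                                seed=seed * 1000 + 80 + k)
            rev = follow_result(*ds.movements[a], *ds.movements[b], (b, a),
                                n_surrogates=n_surrogates,
                                seed=seed * 1000 + 90 + k)
            follow_total += 1
            follow_ok += (fwd.klass == "significant_high"
                          and rev.klass != "significant_high")
    return {
        "n_seeds": n_seeds,
        "coupling_recovery_fraction": seeds_all_above / n_seeds,
        "follow_direction_fraction": follow_ok / follow_total,
    }


def phenotype_recovery(base_seed: int = 0, n_seeds: int = 5,
                       n_individuals: int = 30, n_days: int = 10) -> dict:
    """Recovery of three planted behavioral phenotypes by the full
    clustering pipeline (parameters -> Box-Cox/z -> UMAP -> watershed).

    Phenotypes differ in rest-bout scale, active-bout length and box
    dwell (hyperactive-mobile / average / hypoactive-sedentary).
    Reports the adjusted Rand index against the planted group per seed.
    """
    from sklearn.metrics import adjusted_rand_score

    from .phenotype import (PARAM_COLUMNS, build_parameter_table,
                            embed_and_segment, normalize_parameters)

    layout = default_layout()
    g = n_individuals // 3
    rest = np.concatenate([np.full(g, 2200.0), np.full(g, 5169.0), np.full(g, 9000.0)])
    active = np.concatenate([np.full(g, 3600.0), np.full(g, 1800.0), np.full(g, 700.0)])
    dwell = np.concatenate([np.full(g, 12.0), np.full(g, 30.0), np.full(g, 80.0)])
    aris, ks = [], []
    for r in range(n_seeds):
        seed = base_seed + r
        cfg = ColonyConfig(n_individuals=n_individuals,
                           duration_s=n_days * 86400.0, miss_rate=0.0,
                           disturbance_rate_per_day=1.0, seed=seed,
                           rest_bout_mean_s=rest, active_bout_mean_s=active,
                           dwell_mean_s=dwell)
        log, _ = simulate_colony(cfg, layout)
        ds = process_colony(log, layout, cfg.duration_s, range(n_individuals))
        params = build_parameter_table(ds.events, n_days, 86400.0, ds.disturbances)
        normalized = normalize_parameters(params)
        cmap = embed_and_segment(normalized[list(PARAM_COLUMNS)].to_numpy(),
                                 seed=seed)
        truth_labels = params["individual"].to_numpy() // g
        aris.append(float(adjusted_rand_score(truth_labels, cmap.labels)))
        ks.append(cmap.n_clusters)
    return {
        "n_seeds": n_seeds,
        "ari_per_seed": aris,
        "min_ari": min(aris),
        "clusters_per_seed": ks,
    }
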