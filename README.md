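# burrowtrack

Quantitative ethology for RFID-tracked burrow colonies of eusocial
rodents (naked mole-rat style housing: nine boxes on a 3×3 lattice
joined by pipes, with ring-antenna RFID readers at both pipe ends).
The package turns raw detection logs into per-individual grid
trajectories, classified stay events, daily behavioral phenotypes, and
dyadic social networks — and ships a ground-truthed colony simulator so
that every stage can be validated by parameter recovery.

## Who this is for

Researchers analyzing long-term multi-animal RFID tracking in
structured enclosures: behavioral phenotyping of whole social groups,
and inference of pairwise social structure (activity-rhythm synchrony,
spatial proximity, directional following) with permutation-based
significance.

## The pipeline

1. **Tracking** (`burrowtrack.tracking`) — detections `(time, tag,
   reader)` become per-tick (0.1 s) grid locations. A detection places
   the animal in the reader's pipe; between detections the interval gets
   the unique cell *between* the readers (shared pipe, else the box
   flanked by both pipes); a same-reader re-detection within 0.3 s means
   the animal stayed in the pipe, a longer gap means the adjacent box;
   non-adjacent readers leave the interval unknown (NA). The NA fraction
   is the tracking error rate.
2. **Stay events** (`burrowtrack.events`) — maximal single-cell
   occupancies, classified Rest / Nest / Toilet / Garbage / Other. The
   nest is the box with the highest mean occupancy over a centered 6-h
   window; nest stays longer than 600 s are Rest. Cleaning rules
   reclassify long nest-adjacent-pipe stays and sub-nest stays as Rest,
   fill >30-min NA gaps as Rest in the nest, and flag colony-wide
   disturbances (resting fraction < 25% with a dip below 10%) for
   exclusion.
3. **Phenotypes** (`burrowtrack.phenotype`) — 23 parameters per
   individual-day (Sum / N / Mean per category, plus active-duration
   relative terms), Box-Cox per colony + z per colony-day, UMAP
   (n_neighbors = 5, min_dist = 0.1), Gaussian density raster, watershed
   segmentation into behavioral clusters.
4. **Consistency** (`burrowtrack.stability`) — per individual with
   cluster frequencies `P_i(k)`:

       H_i = -Σ_k P_i(k) ln P_i(k),     consistency(i) = 1 - H_i / ln K

   with a Monte-Carlo null that redraws days i.i.d. from the pooled
   frequencies; day-to-day cosine stability per cluster against a
   within-day shuffle null; and the co-assignment ratio
   `C_emp(k,l) / C_ref(k,l)` for cluster pairs.
5. **Dyadic indices** (`burrowtrack.dyads`) — counts per (directed)
   dyad: `N_Synchrony` (same Rest/Active state at 10-s samples),
   `N_Proximity` (same non-nest cell while both active), `N_Follow`
   (movements re-traced within 3 s). Each count is compared with
   cyclic-shift surrogates of one member's vector:

       Index = (N_actual - mean(N_surrogate)) / sd(N_surrogate)

   with rank p-values and a 2.5%-per-tail significance rule.
6. **Networks** (`burrowtrack.networks`) — significant-high dyads form
   weighted networks (directed follower→followee for following);
   strength centrality = summed incident weights; robustness via
   re-running the full pipeline on consecutive multi-day subsets.
7. **Simulator** (`burrowtrack.simulate`) — an agent-based colony with
   planted rest-coupling, co-location and follow matrices, bimodal nest
   stays, disturbance episodes and detection dropout; `SimulationTruth`
   carries complete trajectories for oracle comparisons.

## Worked example

```python
import numpy as np
from burrowtrack import ColonyConfig, simulate_colony, default_layout, process_colony
from burrowtrack.dyads import binarize_activity, synchrony_result

layout = default_layout()
coupling = np.zeros((12, 12))
coupling[0, 1] = coupling[1, 0] = 0.9          # plant one rest-coupled pair
cfg = ColonyConfig(n_individuals=12, duration_s=86400.0, miss_rate=0.02,
                   coupling=coupling, seed=42)
log, truth = simulate_colony(cfg, layout)

ds = process_colony(log, layout, cfg.duration_s, range(12))
act = {i: binarize_activity(ds.events[i], cfg.duration_s,
                            exclusions=ds.disturbances) for i in range(12)}
print(synchrony_result(act[0], act[1], (0, 1), n_surrogates=199, seed=7))
```

This prints (abridged):

```
19897 detections from 12 individuals over 1 day
tracking error rate: 3.49%
disturbance intervals detected: 2 (planted: 2)
coupled dyad (0,1):     index=+7.97  p=0.005  significant_high
uncoupled dyad (2,3):   index=+2.26  p=0.005  significant_high
```

The planted pair's synchrony index (+7.97) towers over the uncoupled
pair's (+2.26). The uncoupled dyad is still mildly significant: twice a
day the whole colony is roused at once by a disturbance, and that shared
rhythm is real synchrony — the same reason most dyads in a real colony
synchronize to some degree. The error rate (3.49%) is dominated by the
pre-first-detection interval of each individual; long NA gaps inside the
recording are reclassified by the cleaning rules.

A command-line interface mirrors the library
(`burrowtrack simulate|track|events|phenotype|stability|dyads|networks|run`);
`burrowtrack run --seed 1 --out demo/` executes the whole chain on a
simulated colony and writes every artifact as CSV/GraphML plus a
manifest.

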