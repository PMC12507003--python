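# Methods

This note documents the models, rules and numerical choices behind
`burrowtrack`, stage by stage, including the places where the design was
genuinely open and what the synthetic-data validation does and does not
establish.

## Burrow geometry and location reconstruction

The enclosure is modelled as a 5×5 grid: nine boxes at the even (row,
col) positions, twelve pipes between orthogonally adjacent boxes, four
void diagonal cells. Each pipe carries one ring-antenna reader at each
end, so a reader identifies a (pipe, end-box) pair. Time is discretized
at 0.1-s ticks; intervals are half-open `[t_i, t_{i+1})`.

Reconstruction rules, per individual:

* at a detection the animal is in the reader's pipe;
* two readers on one pipe → the pipe; readers on two different pipes →
  the unique box adjacent to both (each adjacent box pair is joined by
  exactly one pipe, so the shared box is unique when it exists);
* same reader twice: gap ≤ 0.3 s → the pipe (a quick pass through the
  antenna), gap > 0.3 s → the box at that reader's end. The boundary is
  inclusive ("within 0.3 s" read as ≤);
* readers with no shared pipe or box → the interval is unknown (NA);
* ticks before the first detection are NA; ticks after the last
  detection carry the last reader's end box (the settled interpretation;
  leaving them NA would inflate the error rate at the boundary for no
  information gain);
* simultaneous duplicate detections of one tag keep the earlier record,
  with a warning.

The tracking error rate is the pooled NA fraction. It is dominated in
practice by the pre-first-detection interval of each individual (an
animal that starts the recording resting produces no detections for
hours); NA runs longer than 30 min inside the recording are later
reclassified as Rest in the nest (below).

## Stay events, chamber functions, cleaning

A stay event is a maximal constant-cell run. Chamber functions: the
nest is occupancy-derived — at 10-s samples, the box with the highest
mean occupant count over a centered 6-hour window (clipped at the
recording edges; exact ties go to the lowest (row, col); an
all-unknown window carries the previous nest forward). Toilet and
garbage are manual annotations (fixed cells in the simulator).

Classification: nest stays > 600 s are Rest, shorter nest stays are
Nest; toilet/garbage stays take their chamber's label regardless of
duration; pipes and unannotated boxes are Other. The chamber function
is evaluated at the event midpoint so an event spanning a nest move is
attributed once. The 600-s threshold is fixed rather than re-derived
from the data-driven duration antimode; `find_duration_modes` (KDE on
log-durations, Silverman bandwidth) is provided as a diagnostic to
verify the bimodal nest-stay regime that motivates the threshold.

Cleaning rules (idempotent, applied after classification):

* stays > 600 s in a pipe adjacent to the currently annotated nest →
  Rest ("nest-adjacent tunnels" is read as pipes touching the current
  nest only);
* a non-nest box where ≥ 5 individuals co-reside continuously (every
  10-s sample) for > 600 s is a sub-nest; stays > 600 s overlapping the
  sub-nest period by > 600 s → Rest;
* NA gaps > 30 min → relocated to the nest and classified Rest.

Disturbance phases are maximal intervals with colony resting fraction
below 25% containing at least one sample below 10%, sampled at 10 s.
They are excluded globally from downstream analyses (binarized activity
samples inside them are missing; parameter extraction subtracts the
excluded time from event durations without splitting event counts).

## Daily behavior vectors and clustering

23 parameters per individual-day: Sum, N, Mean for each of Rest, Nest,
Toilet, Garbage, Other, plus Sum and N for the four non-Rest categories
relative to the day's active (non-Rest) duration. An absent category
has Mean 0 with N 0; a day with zero active duration reports zero
relative terms.

Normalization: Box-Cox with per-parameter maximum-likelihood λ within
each colony, on values shifted by +1 (durations and counts can be 0);
then z-scoring within each colony-day. Constant columns pass through
as zeros with a warning.

Embedding and segmentation: UMAP with n_neighbors = 5, min_dist = 0.1,
pinned random state (UMAP is otherwise non-deterministic). The 2-D
points are binned into a 512×512 histogram over the 5%-padded bounding
box, smoothed with an isotropic Gaussian, and segmented by watershed on
the negated density after h-minima suppression at 5% of the density
maximum. Clusters are renumbered by descending size; cluster identities
are data-specific and carry no meaning across runs.

The smoothing bandwidth is the one genuinely open choice (the original
procedure tuned blurring by eye). The default is a sample-size-aware
Scott-type rule — `n^(-1/6)` times the smaller marginal standard
deviation of the embedding, expressed in raster pixels (≈ 26 px at
n = 300, ≈ 30 px at n ≈ 3000, floored at 2 px) — because any fixed
pixel value is only correct at one point density: an 8-px blur that
suits a ~3000-sample embedding shatters a 300-sample embedding into
spurious density peaks. `blur_sigma` remains exposed for manual
override, as does `hmin_frac`.

Embedding outliers: samples farther from the embedding median than
`median + 5 × IQR` of the distance distribution are flagged; when ≥ 80%
of one individual's samples are flagged, all of that individual's
samples are excluded and the embedding should be recomputed without
them.

Representative cluster per individual: the modal cluster over its days;
ties go to the cluster with the lowest overall occurrence among the
tied clusters, then the smallest id.

## Consistency, stability, co-assignment, leadership

Consistency index: `1 − H_i / ln K` with `H_i` the Shannon entropy
(nats, `0·ln 0 = 0`) of the individual's cluster frequencies. The
Monte-Carlo null redraws `n_days` i.i.d. labels from the pooled
(global) cluster frequencies; since the null depends only on those
frequencies, one simulated distribution (default 10,000 draws) is
shared by all individuals. p-values use the add-one convention
`p = (1 + #{sim ≥ obs}) / (1 + n_sims)`, which cannot return 0.

Colony-level stability: per colony and cluster, the binary
individual-membership vector of each day; cosine similarity between
consecutive days (a day with an all-zero vector contributes similarity
0); the null shuffles elements within each day's vector (100 shuffle
sets by default). Rank-sum comparison of observed vs null is left to
the caller.

Co-assignment: `C_emp(k,l)` is the mean over individuals of
`P_i(k) P_i(l)`; `C_ref(k,l) = P̄(k) P̄(l)`; the index is their ratio
(undefined where `C_ref = 0`). Note an analytic property of this
estimator: because `P_i` are empirical proportions over `n_days`, the
diagonal satisfies `E[P_i(k)²] = p² + p(1−p)/n_days`, so under fully
independent assignment the diagonal index converges to
`1 + (1−p)/(n_days·p)` — about 1.2 for p = 1/7 and 30 days — while
off-diagonal indices converge to `(n_days−1)/n_days ≈ 1`. Identical
pairings therefore sit above 1 even without any behavioral consistency;
only the off-diagonal entries have an independence limit of exactly 1.

Leadership: for each nest transition (a change in the annotated nest),
individuals are ranked by the start of their first Rest event in the new
nest within a window from 2 h before to 12 h after the transition; tied
onsets get averaged ranks; transitions where at most 80% of the colony
participates are flagged excluded. Downstream ordinal modeling of the
ranks is out of scope; the ranks are exported.

## Dyadic indices and the cyclic-shift null

Activity vectors: Rest/Active at 10-s samples (Rest iff inside a Rest
event); samples in NA gaps or disturbances are missing. Missing samples
are removed pairwise, and surrogates are cyclic shifts of the second
member's *compressed* vector, so actual and surrogate counts run over
the same index set. Offsets are drawn uniformly with replacement from
`{1, …, L−1}`; only one member of a dyad is shifted.

Proximity restricts to samples where both members are active, located,
and outside the current nest, then counts equal cells; the surrogate
shifts act on the restricted vectors. The sampling interval is 10 s
and exposed as a parameter. A dyad with an empty restriction is
reported undefined.

Follow: movement events are transitions between adjacent cells (pairs
of cells encoded as ordered paths); a followee event at `t` counts as
followed if the follower has an identical-path event in `(t, t + 3]`
(closed right endpoint), at most once per followee event. Surrogates
preserve the follower's event times and cyclically shift its path
labels.

Index = (actual − surrogate mean) / surrogate sd (undefined when the
sd is 0, e.g. a constant activity vector). The p-value is the rank of
the observed count among observed + surrogates, as the proportion
equal-or-more-extreme in its tail; a dyad is significant-high
(synchronous / proximal / frequently following) in the top 2.5%,
significant-low in the bottom 2.5%. 9999 surrogates for synchrony and
proximity and 999 for follow at full scale; validation experiments use
199, which makes the finest achievable p 1/200 — comfortably below the
2.5% tails.

Follow indices can additionally be Yeo-Johnson-transformed (MLE λ) and
z-scored across all directed dyads; undefined entries propagate.

## Networks

Significant-high dyads form the edges (weight = index) of an undirected
(synchrony, proximity) or directed (follow; follower → followee)
network over all individuals. Strength centrality sums incident
weights; in-strength is "being followed", out-strength "following".
Temporal robustness: the recording is split into consecutive equal
subsets (six 5-day subsets at full scale) and the complete dyadic
pipeline — including fresh surrogate distributions and significance
thresholds — is re-run per subset.

## The synthetic colony

The simulator is an assumption-bearing stand-in for undeposited colony
recordings, not a kinematic model of the animals. It emulates exactly
the statistical structure the pipeline assumes, with all randomness
drawn from per-individual generators seeded by `(seed, individual)` so
results are reproducible and independent of colony size.

Movement: each individual alternates active bouts (exponential, mean
1800 s) and rest bouts spent in the nest (lognormal, log-sd 0.6, mean
5169 s); while active it random-walks over boxes with exponential
dwells (mean 30 s), except in the nest where visits are short
(lognormal, mean 6.3 s). The two nest-stay populations produce the
bimodal log-duration distribution (second-scale visits vs hour-scale
rests) that the 600-s Rest threshold relies on; lognormal rest/visit
durations are used instead of exponentials because they produce the
clean two-mode, one-valley KDE shape. Pipe transits take a fixed
0.2 s and box dwells at least 0.4 s, which makes the 0.3-s same-reader
rule exact: on a noise-free log the reconstruction equals the true
trajectory at every defined tick, the property the tracking oracle
tests exploit.

Interactions:

* **Rest coupling** — when an individual spontaneously begins a rest it
  emits a "rest call"; each partner answers with probability equal to
  the planted coupling: an active partner joins with the same onset and
  a jittered copy of the caller's rest end; a resting partner re-aligns
  its rest end to the caller's (huddling). The alignment of resting
  partners matters: without it a pair whose phases happen to be opposed
  can fail to lock for the whole recording.
* **Co-location** — at each destination choice the individual heads one
  step toward a partner with the planted probability, else wanders
  uniformly.
* **Follow** — when a followee starts a box-to-box traversal, a
  follower whose (pending) position is the traversal's origin re-traces
  the same path with the planted probability, 0.4–0.8 s later (within
  the 3-s window for both movement events of the traversal). Re-traces
  queue if the follower is mid-move; a resting follower is roused by
  the followee's departure from the shared box; a shadowing follower
  that has caught up idles on the normal dwell timescale instead of
  wandering. Strong followers therefore trail their followee tightly,
  and the planted direction is asymmetric: the follower's identical
  moves come strictly after the followee's.

Disturbances arrive as a Poisson process (default 2/day) and force
10–30 min of colony-wide activity: resting individuals are roused and
leave the nest (nest dwells are short while active), then resume their
rests afterwards. This reproduces the signature the disturbance
detector looks for — a resting-fraction collapse below 10% inside a
sub-25% interval.

Detections: one record per reader-gate crossing (each box↔pipe
transition crosses exactly one antenna), each dropped independently
with probability `miss_rate`.

What the simulator does *not* emulate: sub-cell positioning, repeated
antenna reads while an animal sits inside a ring (real logs contain
many), physiological structure (feeding, thermoregulation, castes),
nest relocations (the nest box is fixed unless occupancy actually
shifts), and correlated reader failures. Consequently, passing the
recovery experiments establishes that the pipeline's inference is
correct *given its own data model* — reconstruction rules, event
definitions, null construction — not that the biological conclusions of
any particular colony analysis are right.

## Validation experiments and problem sizes

The validation suite (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs at desk scale, chosen so the whole suite
completes in minutes on one CPU while exercising the identical code
paths as a full-scale analysis:

* tracking fidelity: 10 individuals, 2 h, noise-free (exact truth
  match) and 10% dropout (error rate equals an independent brute-force
  NA tally);
* type-I calibration: 400 independent individuals over 12 h paired into
  200 disjoint dyads, 199 surrogates — the significant fraction under
  the 2.5%+2.5% rule, and the index mean/sd across dyads;
* coupling/follow recovery: 20 replicates of a 46-individual colony
  holding ten coupled pairs (0.9), ten independent pairs and three
  follower–followee pairs (follow 1.0, followers without spontaneous
  rest so their movement is purely followee-driven);
* phenotype recovery: 30 individuals × 10 days with three planted bout
  phenotypes (hyperactive-mobile / average / hypoactive-sedentary),
  full clustering pipeline, adjusted Rand index against the planted
  grouping over 5 replicates;
* consistency null: 2000 null individuals against a 999-draw null;
* network identities: handshake (Σ strengths = 2 Σ weights) and
  directed flow conservation (Σ in = Σ out = Σ weights), plus the
  single-subset split reproducing the full-period network.

## Known limitations

* The reconstruction assigns the post-final-detection interval to the
  last reader's end box; a recording that genuinely ends with the
  animal elsewhere is mis-assigned for that tail.
* Box-Cox λ is fit per colony on pooled days; strong day effects shift
  λ. Constant parameters within a colony-day are zeroed rather than
  dropped.
* Watershed cluster count is sensitive to the blur bandwidth by
  construction; the automatic rule targets the regimes exercised here
  and is not a universal bandwidth selector.
* The cyclic-shift null preserves autocorrelation but not shared
  colony-wide phase: genuinely shared rhythms (e.g. disturbance-driven
  arousal that survives exclusion) appear as real synchrony, in the
  data as in the original analysis.
* Leadership ranks and centrality tables are exported for external
  modeling; no mixed-model inference is performed in this package.
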