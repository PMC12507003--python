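"""Agent-based generator of ground-truthed colony movement and RFID detections.

The simulator emulates the data regime of a tracked eusocial rodent colony
living in the 3x3-box burrow: ~20 individuals whose nest stays are strongly
bimodal (second-scale visits versus hour-scale rests), colony-wide
disturbance episodes that empty the nest, dyad-level coupling of rest
rhythms, shared-destination (co-location) preferences, directional follow
behavior on a seconds timescale, and RFID detection dropout producing
unlocatable intervals.

Movement model
--------------
Each individual alternates between an *active* bout (exponential duration)
and a *rest* bout (lognormal duration, spent in the nest box).  While
active it performs a random walk over boxes with exponential box dwells;
dwells in the nest box during active bouts are short (lognormal, mean of a
few seconds), which together with the long rests produces the bimodal
nest-stay distribution.  Pipe transits take a fixed 0.2 s and box dwells
are at least 0.4 s, so the same-reader 0.3-s disambiguation rule used in
reconstruction is exact on noise-free logs.

Interactions
------------
* coupling: when individual *i* spontaneously begins a rest, every other
  *j* answers the "rest call" with probability ``coupling[i, j]`` — an
  active *j* joins with the same onset and near-same end, a resting *j*
  re-aligns its rest end to the caller's (huddling), so coupled pairs
  lock onto a shared rhythm regardless of phase.
* co_location: at each destination choice, *i* heads one step toward
  partner *j* with probability ``co_location[i, j]``.
* follow: whenever *j* starts a box-to-box traversal, a co-located *i*
  re-traces the same path within ``follow_lag_s`` with probability
  ``follow[i, j]`` (queued if *i* is mid-move; a resting follower is
  roused by the followee's departure).  Strong followers suppress their
  own wandering and shadow their followee instead.

All event times are integers on the tick grid, and every source of
randomness flows from per-individual generators derived from
``(seed, individual)``, so results are reproducible and independent of
colony size.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .layout import GridLayout, cell_code, cell_coords, default_layout

TRANSIT_TICKS = 2  # pipe traversal time, in ticks (0.2 s at the 0.1-s tick)
MIN_DWELL_TICKS = 4  # minimum box dwell, keeps the 0.3-s reader rule exact

REST_SIGMA = 0.6  # lognormal log-sd of rest-bout durations
VISIT_SIGMA = 0.8  # lognormal log-sd of short nest visits


class ConfigError(ValueError):
    """Raised when a :class:`ColonyConfig` field is invalid."""


def _as_matrix(value, n: int, name: str, symmetric: bool) -> np.ndarray:
    if value is None:
        return np.zeros((n, n))
    m = np.asarray(value, dtype=float)
    if m.shape != (n, n):
        raise ConfigError(f"{name}: expected shape ({n}, {n}), got {m.shape}")
    if np.any((m < 0) | (m > 1)):
        raise ConfigError(f"{name}: entries must lie in [0, 1]")
    if symmetric and not np.allclose(m, m.T):
        raise ConfigError(f"{name}: matrix must be symmetric")
    m = m.copy()
    np.fill_diagonal(m, 0.0)
    return m


def _per_individual(value, n: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
    if np.any(arr <= 0):
        raise ConfigError(f"{name}: durations must be positive")
    return arr


@dataclass
class ColonyConfig:
    """Parameters of a simulated colony.

    Bout parameters may be scalars or per-individual arrays, which is how
    distinct behavioral phenotypes are planted.  ``coupling`` and
    ``co_location`` are symmetric [0, 1] matrices; ``follow[i, j]`` is the
    probability that *i* re-traces *j*'s movements (directed).  Diagonals
    are ignored.
    """

    n_individuals: int = 20
    duration_s: float = 86400.0
    tick_s: float = 0.1
    rest_bout_mean_s: float | Sequence[float] = 5169.0
    active_bout_mean_s: float | Sequence[float] = 1800.0
    dwell_mean_s: float | Sequence[float] = 30.0
    nest_visit_mean_s: float | Sequence[float] = 6.3
    nest_cell: tuple[int, int] = (2, 2)
    toilet_cell: tuple[int, int] = (0, 0)
    garbage_cell: tuple[int, int] = (4, 4)
    coupling: np.ndarray | None = None
    co_location: np.ndarray | None = None
    follow: np.ndarray | None = None
    follow_lag_s: float = 3.0
    disturbance_rate_per_day: float = 2.0
    miss_rate: float = 0.0
    seed: int = 0

    def validate(self, layout: GridLayout) -> None:
        n = self.n_individuals
        if n < 1:
            raise ConfigError("n_individuals: must be >= 1")
        if self.tick_s <= 0:
            raise ConfigError("tick_s: must be positive")
        n_ticks = self.duration_s / self.tick_s
        if self.duration_s <= 0 or abs(n_ticks - round(n_ticks)) > 1e-6:
            raise ConfigError("duration_s: must be a positive integer multiple of tick_s")
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ConfigError("miss_rate: must lie in [0, 1]")
        if self.follow_lag_s <= 2 * TRANSIT_TICKS * self.tick_s:
            raise ConfigError("follow_lag_s: too short for a pipe traversal")
        if self.disturbance_rate_per_day < 0:
            raise ConfigError("disturbance_rate_per_day: must be >= 0")
        for name in ("nest_cell", "toilet_cell", "garbage_cell"):
            code = cell_code(*getattr(self, name))
            if not layout.is_box(code):
                raise ConfigError(f"{name}: {getattr(self, name)} is not a box cell")
        _as_matrix(self.coupling, n, "coupling", symmetric=True)
        _as_matrix(self.co_location, n, "co_location", symmetric=True)
        _as_matrix(self.follow, n, "follow", symmetric=False)
        for name in ("rest_bout_mean_s", "active_bout_mean_s", "dwell_mean_s", "nest_visit_mean_s"):
            _per_individual(getattr(self, name), n, name)


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the detection log.

    Trajectories are stored as per-individual changepoint lists
    ``(ticks, cells)`` meaning the individual occupies ``cells[k]`` from
    tick ``ticks[k]`` (inclusive) until the next changepoint.  Truth is
    complete: there are no unknown values.
    """

    tick_s: float
    n_ticks: int
    individuals: tuple[int, ...]
    changepoints: dict[int, tuple[np.ndarray, np.ndarray]]
    rest_intervals: dict[int, list[tuple[int, int]]]
    crossings: dict[int, list[tuple[int, str]]]
    disturbance_intervals: list[tuple[float, float]]
    nest_cell: int
    coupling: np.ndarray
    co_location: np.ndarray
    follow: np.ndarray

    def trajectory(self, individual: int) -> np.ndarray:
        """Per-tick true cell codes for one individual."""
        ticks, cells = self.changepoints[individual]
        out = np.empty(self.n_ticks, dtype=np.int16)
        bounds = np.append(ticks, self.n_ticks)
        for k in range(len(cells)):
            out[bounds[k] : bounds[k + 1]] = cells[k]
        return out

    def rest_schedule(self, individual: int) -> np.ndarray:
        """Per-tick boolean rest flag for one individual."""
        out = np.zeros(self.n_ticks, dtype=bool)
        for start, end in self.rest_intervals[individual]:
            out[start:end] = True
        return out


class _Agent:
    __slots__ = (
        "i", "rng", "box", "transit_until", "mode", "resting", "rest_end",
        "active_until", "version", "resume_rest", "saved_rest_end",
        "rest_start_tick", "followee", "p_follow", "retrace_queue",
    )

    def __init__(self, i: int, rng: np.random.Generator, box: int):
        self.i = i
        self.rng = rng
        self.box = box
        self.transit_until = -1
        self.mode = "active"  # "active" | "rest" (rest = resting or heading to nest)
        self.resting = False
        self.rest_end = 0
        self.active_until = 0
        self.version = 0
        self.resume_rest = False
        self.saved_rest_end = 0
        self.rest_start_tick = -1
        self.followee = -1
        self.p_follow = 0.0
        self.retrace_queue: list[tuple[int, int]] = []


class _Simulator:
    """Discrete-event engine; see module docstring for the model."""

    def __init__(self, config: ColonyConfig, layout: GridLayout):
        config.validate(layout)
        self.cfg = config
        self.layout = layout
        self.tick = config.tick_s
        self.n_ticks = int(round(config.duration_s / config.tick_s))
        n = config.n_individuals
        self.n = n
        self.nest = cell_code(*config.nest_cell)
        self.coupling = _as_matrix(config.coupling, n, "coupling", True)
        self.co_location = _as_matrix(config.co_location, n, "co_location", True)
        self.follow = _as_matrix(config.follow, n, "follow", False)
        self.follow_lag_ticks = int(round(config.follow_lag_s / config.tick_s))
        self.rest_mean = _per_individual(config.rest_bout_mean_s, n, "rest")
        self.active_mean = _per_individual(config.active_bout_mean_s, n, "active")
        self.dwell_mean = _per_individual(config.dwell_mean_s, n, "dwell")
        self.visit_mean = _per_individual(config.nest_visit_mean_s, n, "visit")
        ss = np.random.SeedSequence(config.seed)
        self.colony_rng = np.random.default_rng(ss.spawn(1)[0])
        self.agents = [
            _Agent(i, np.random.default_rng(np.random.SeedSequence((config.seed, i))), self.nest)
            for i in range(n)
        ]
        self.followers_of: list[list[int]] = [
            [j for j in range(n) if self.follow[j, i] > 0] for i in range(n)
        ]
        self.heap: list[tuple[int, int, str, tuple]] = []
        self.seq = 0
        self.disturbed = False
        self.traj_ticks: list[list[int]] = [[0] for _ in range(n)]
        self.traj_cells: list[list[int]] = [[self.nest] for _ in range(n)]
        self.rest_intervals: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        self.crossings: list[list[tuple[int, str]]] = [[] for _ in range(n)]
        self.disturbances: list[tuple[int, int]] = []

    # -- random draws (ticks) ---------------------------------------------
    def _ticks(self, seconds: float, minimum: int = MIN_DWELL_TICKS) -> int:
        return max(minimum, int(round(seconds / self.tick)))

    def draw_rest(self, a: _Agent) -> int:
        median = self.rest_mean[a.i] / math.exp(REST_SIGMA**2 / 2)
        return self._ticks(median * math.exp(a.rng.normal(0.0, REST_SIGMA)))

    def draw_active(self, a: _Agent) -> int:
        return self._ticks(a.rng.exponential(self.active_mean[a.i]))

    def draw_dwell(self, a: _Agent) -> int:
        if a.box == self.nest and not a.resting:
            median = self.visit_mean[a.i] / math.exp(VISIT_SIGMA**2 / 2)
            return self._ticks(median * math.exp(a.rng.normal(0.0, VISIT_SIGMA)))
        return self._ticks(a.rng.exponential(self.dwell_mean[a.i]))

    # -- event queue -------------------------------------------------------
    def push(self, t: int, kind: str, payload: tuple) -> None:
        self.seq += 1
        heapq.heappush(self.heap, (t, self.seq, kind, payload))

    # -- movement ----------------------------------------------------------
    def _step_toward(self, a: _Agent, target_box: int) -> int:
        """Neighbor box one step toward ``target_box`` (random tie-break)."""
        r0, c0 = cell_coords(a.box)
        rt, ct = cell_coords(target_box)
        options = []
        for _, nb in self.layout.box_neighbors(a.box):
            r, c = cell_coords(nb)
            if abs(r - rt) + abs(c - ct) < abs(r0 - rt) + abs(c0 - ct):
                options.append(nb)
        if not options:
            return a.box
        return options[int(a.rng.integers(len(options)))]

    def traverse(self, a: _Agent, t: int, dest: int) -> None:
        arrival = t + TRANSIT_TICKS
        if arrival + 1 >= self.n_ticks:
            return  # never end the recording mid-pipe
        origin = a.box
        pipe = self.layout.pipe_between(origin, dest)
        if pipe is None:  # pragma: no cover - guarded by callers
            raise RuntimeError("traverse between non-adjacent boxes")
        self.crossings[a.i].append((t, self.layout.reader_at(pipe, origin)))
        self.crossings[a.i].append((arrival, self.layout.reader_at(pipe, dest)))
        self.traj_ticks[a.i].extend((t, arrival))
        self.traj_cells[a.i].extend((pipe, dest))
        a.box = dest
        a.transit_until = arrival
        self.push(arrival, "plan", (a.i,))
        # follow triggers: followers whose pending position matches the
        # origin queue a re-trace of this path
        for j in self.followers_of[a.i]:
            f = self.agents[j]
            vbox = f.retrace_queue[-1][1] if f.retrace_queue else f.box
            if vbox != origin or len(f.retrace_queue) >= 8:
                continue
            if f.rng.random() < self.follow[j, a.i]:
                if f.resting:
                    # the followee's departure rouses a co-located follower
                    f.resting = False
                    self.rest_intervals[j].append((f.rest_start_tick, t))
                    f.rest_start_tick = -1
                    f.mode = "active"
                    f.active_until = t + self.draw_active(f)
                f.retrace_queue.append((origin, dest))
                if len(f.retrace_queue) == 1:
                    f.version += 1
                    if f.transit_until > t:
                        start = f.transit_until + MIN_DWELL_TICKS
                    else:
                        hi = max(min(self.follow_lag_ticks - TRANSIT_TICKS, 8),
                                 MIN_DWELL_TICKS)
                        start = t + int(f.rng.integers(MIN_DWELL_TICKS, hi + 1))
                    self.push(start, "retrace", (j, f.version))

    # -- behavioral logic --------------------------------------------------
    def begin_rest(self, a: _Agent, t: int, rest_end: int, broadcast: bool) -> None:
        a.mode = "rest"
        a.rest_end = rest_end
        a.retrace_queue.clear()
        if broadcast:
            for j in range(self.n):
                if j == a.i:
                    continue
                p = self.coupling[a.i, j]
                if p <= 0.0:
                    continue
                b = self.agents[j]
                if self.disturbed:
                    continue
                if b.rng.random() < p:
                    jitter = int(b.rng.integers(0, int(round(30.0 / self.tick)) + 1))
                    if b.resting:
                        # already asleep: align the rest end (huddling), so
                        # the next onsets of the pair are shared
                        b.rest_end = max(rest_end + jitter, t + MIN_DWELL_TICKS)
                        b.version += 1
                        self.push(b.rest_end, "wake", (j, b.version))
                        continue
                    b.mode = "rest"
                    b.rest_end = rest_end + jitter
                    b.retrace_queue.clear()
                    b.version += 1
                    if b.transit_until <= t:
                        delay = int(b.rng.integers(MIN_DWELL_TICKS, MIN_DWELL_TICKS + 27))
                        self.push(t + delay, "act", (j, b.version))
        self.plan(a, t)

    def plan(self, a: _Agent, t: int) -> None:
        """Decide the next action for an agent idle in a box at tick t."""
        if a.mode == "rest" and not self.disturbed:
            if a.box == self.nest:
                if not a.resting:
                    a.resting = True
                    a.rest_start_tick = t
                a.version += 1
                self.push(max(a.rest_end, t + 1), "wake", (a.i, a.version))
                return
            a.version += 1
            delay = max(MIN_DWELL_TICKS, self._ticks(a.rng.exponential(2.0)))
            self.push(t + delay, "act", (a.i, a.version))
            return
        if a.retrace_queue:  # pending follow re-traces take priority
            a.version += 1
            self.push(t + MIN_DWELL_TICKS, "retrace", (a.i, a.version))
            return
        # active (or disturbed): dwell, then move
        if a.mode == "active" and t >= a.active_until and not self.disturbed:
            self.begin_rest(a, t, t + self.draw_rest(a), broadcast=True)
            return
        a.version += 1
        self.push(t + self.draw_dwell(a), "act", (a.i, a.version))

    def choose_destination(self, a: _Agent, t: int) -> int | None:
        """Destination box for a wandering move; None means wait in place."""
        if a.p_follow > 0.0 and a.rng.random() < a.p_follow:
            target = self.agents[a.followee]
            tbox = self.nest if target.resting else target.box
            if tbox == a.box:
                return None  # glued to the followee: wait for it to move
            return self._step_toward(a, tbox)
        partners = np.flatnonzero(self.co_location[a.i] > 0)
        if partners.size:
            order = a.rng.permutation(partners)
            for j in order:
                if a.rng.random() < self.co_location[a.i, j]:
                    tbox = self.agents[j].box
                    if tbox != a.box:
                        return self._step_toward(a, tbox)
                    return None
        nbrs = self.layout.box_neighbors(a.box)
        return nbrs[int(a.rng.integers(len(nbrs)))][1]

    # -- event handlers ----------------------------------------------------
    def on_act(self, t: int, a: _Agent, version: int) -> None:
        if version != a.version or a.resting or a.transit_until > t:
            return
        if a.mode == "rest" and not self.disturbed:
            if a.box == self.nest:
                self.plan(a, t)
                return
            self.traverse(a, t, self._step_toward(a, self.nest))
            return
        if a.mode == "active" and t >= a.active_until and not self.disturbed:
            self.begin_rest(a, t, t + self.draw_rest(a), broadcast=True)
            return
        dest = self.choose_destination(a, t)
        if dest is None or dest == a.box:
            # waiting (e.g. shadowing a co-located followee): idle on the
            # normal dwell timescale before re-checking
            a.version += 1
            self.push(t + self.draw_dwell(a), "act", (a.i, a.version))
            return
        self.traverse(a, t, dest)

    def on_retrace(self, t: int, a: _Agent, version: int) -> None:
        if version != a.version or a.resting or a.transit_until > t:
            return
        while a.retrace_queue:
            origin, dest = a.retrace_queue.pop(0)
            if a.box == origin:
                self.traverse(a, t, dest)
                return
        self.plan(a, t)

    def on_wake(self, t: int, a: _Agent, version: int) -> None:
        if version != a.version or not a.resting:
            return
        a.resting = False
        self.rest_intervals[a.i].append((a.rest_start_tick, t))
        a.rest_start_tick = -1
        a.mode = "active"
        a.active_until = t + self.draw_active(a)
        self.plan(a, t)

    def on_disturbance_start(self, t: int) -> None:
        self.disturbed = True
        for a in self.agents:
            if a.resting:
                a.resting = False
                self.rest_intervals[a.i].append((a.rest_start_tick, t))
                a.rest_start_tick = -1
                a.resume_rest = True
                a.saved_rest_end = a.rest_end
            elif a.mode == "rest":
                a.resume_rest = True
                a.saved_rest_end = a.rest_end
            a.mode = "active"
            a.active_until = self.n_ticks + 1  # no spontaneous rest while disturbed
            a.version += 1
            if a.transit_until <= t:
                delay = int(a.rng.integers(MIN_DWELL_TICKS, MIN_DWELL_TICKS + 47))
                self.push(t + delay, "act", (a.i, a.version))

    def on_disturbance_end(self, t: int) -> None:
        self.disturbed = False
        min_resume = self._ticks(600.0)
        for a in self.agents:
            a.version += 1
            if a.resume_rest:
                a.resume_rest = False
                a.mode = "rest"
                a.rest_end = max(a.saved_rest_end, t + min_resume)
            else:
                a.mode = "active"
                a.active_until = t + self.draw_active(a)
            if a.transit_until <= t:
                delay = int(a.rng.integers(MIN_DWELL_TICKS, MIN_DWELL_TICKS + 27))
                self.push(t + delay, "act", (a.i, a.version))

    # -- main loop ---------------------------------------------------------
    def run(self) -> SimulationTruth:
        # initial state: everyone resting in the nest with staggered wake times
        for a in self.agents:
            a.mode = "rest"
            a.resting = True
            a.rest_start_tick = 0
            a.rest_end = self._ticks(float(a.rng.uniform(0.2, 1.0)) * self.rest_mean[a.i])
            a.followee = int(np.argmax(self.follow[a.i])) if self.follow[a.i].any() else -1
            a.p_follow = float(self.follow[a.i].max())
            a.version += 1
            self.push(a.rest_end, "wake", (a.i, a.version))
        # disturbance schedule: Poisson arrivals, 10-30 min forced activity
        rate = self.cfg.disturbance_rate_per_day / 86400.0
        if rate > 0:
            t = 0.0
            while True:
                t += self.colony_rng.exponential(1.0 / rate)
                start = int(round(t / self.tick))
                if start >= self.n_ticks:
                    break
                dur = self._ticks(float(self.colony_rng.uniform(600.0, 1800.0)))
                end = min(start + dur, self.n_ticks)
                if self.disturbances and start <= self.disturbances[-1][1]:
                    self.disturbances[-1] = (self.disturbances[-1][0], end)
                else:
                    self.disturbances.append((start, end))
                t = end * self.tick
        for start, end in self.disturbances:
            self.push(start, "dist_start", ())
            self.push(end, "dist_end", ())

        while self.heap:
            t, _, kind, payload = heapq.heappop(self.heap)
            if t >= self.n_ticks:
                continue
            if kind == "act":
                self.on_act(t, self.agents[payload[0]], payload[1])
            elif kind == "plan":
                self.plan(self.agents[payload[0]], t)
            elif kind == "wake":
                self.on_wake(t, self.agents[payload[0]], payload[1])
            elif kind == "retrace":
                self.on_retrace(t, self.agents[payload[0]], payload[1])
            elif kind == "dist_start":
                self.on_disturbance_start(t)
            elif kind == "dist_end":
                self.on_disturbance_end(t)

        for a in self.agents:
            if a.resting and a.rest_start_tick >= 0:
                self.rest_intervals[a.i].append((a.rest_start_tick, self.n_ticks))
        changepoints = {
            i: (np.asarray(self.traj_ticks[i], dtype=np.int64),
                np.asarray(self.traj_cells[i], dtype=np.int16))
            for i in range(self.n)
        }
        return SimulationTruth(
            tick_s=self.tick,
            n_ticks=self.n_ticks,
            individuals=tuple(range(self.n)),
            changepoints=changepoints,
            rest_intervals={i: self.rest_intervals[i] for i in range(self.n)},
            crossings={i: self.crossings[i] for i in range(self.n)},
            disturbance_intervals=[(s * self.tick, e * self.tick) for s, e in self.disturbances],
            nest_cell=self.nest,
            coupling=self.coupling,
            co_location=self.co_location,
            follow=self.follow,
        )


def simulate_colony(
    config: ColonyConfig, layout: GridLayout | None = None
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a colony and emit its RFID detection log.

    Returns ``(detections, truth)`` where ``detections`` is a DataFrame
    with columns ``time_s, tag, reader`` sorted by (time, tag, reader) and
    ``truth`` holds the complete trajectories, rest schedule, planted
    matrices and disturbance intervals.
    """
    if layout is None:
        layout = default_layout()
    truth = _Simulator(config, layout).run()
    log = emit_detection_log(truth, layout, config.miss_rate, config.seed + 1)
    return log, truth


def emit_detection_log(
    truth: SimulationTruth,
    layout: GridLayout,
    miss_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Turn true reader crossings into a detection log.

    Each crossing is dropped independently with probability ``miss_rate``;
    records are sorted by (time, tag, reader).
    """
    if not 0.0 <= miss_rate <= 1.0:
        raise ConfigError("miss_rate: must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    times, tags, readers = [], [], []
    for i in truth.individuals:
        rows = truth.crossings[i]
        if not rows:
            continue
        keep = rng.random(len(rows)) >= miss_rate
        for (t, rid), k in zip(rows, keep):
            if k:
                times.append(t * truth.tick_s)
                tags.append(i)
                readers.append(rid)
    df = pd.DataFrame({"time_s": times, "tag": tags, "reader": readers})
    return df.sort_values(["time_s", "tag", "reader"], kind="mergesort").reset_index(drop=True)


def expected_index_ranking(truth: SimulationTruth) -> dict[str, list[tuple[tuple[int, int], float]]]:
    """Planted dyads ranked by strength, the recovery oracle per relationship.

    Returns ``{"coupling": [...], "co_location": [...], "follow": [...]}``
    with dyads sorted by descending planted strength; zero-strength dyads
    are omitted.  Follow dyads are directed ``(follower, followee)``.
    """
    out: dict[str, list[tuple[tuple[int, int], float]]] = {}
    for name, matrix, directed in (
        ("coupling", truth.coupling, False),
        ("co_location", truth.co_location, False),
        ("follow", truth.follow, True),
    ):
        entries = []
        n = matrix.shape[0]
        for i in range(n):
            for j in range(n):
                if i == j or matrix[i, j] <= 0:
                    continue
                if not directed and i > j:
                    continue
                entries.append(((i, j), float(matrix[i, j])))
        entries.sort(key=lambda e: (-e[1], e[0]))
        out[name] = entries
    return out
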