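"""Agent-based herd simulator with attraction-repulsion social forces.

The simulator is a validation harness for the downstream pipeline, not a
claim about equine locomotion. It produces what a UWB real-time location
system would record — 1 Hz dyadic distance streams with technical-replicate
asymmetry and sensor artifacts — together with ground truth for every
quantity the pipeline estimates: true positions, injected artifact samples,
and the exact windows of choreographed agonistic episodes.

Movement model (overdamped, 1 s Euler steps):

* hard-core repulsion below 1 m (collision avoidance, 1 m/s push);
* linear repulsion between 1 m and the per-dyad equilibrium distance;
* weak linear attraction beyond the equilibrium, scaled by the square of
  the dyadic affinity, so strongly bonded pairs cohere near their
  equilibrium while weakly bonded pairs disperse across the enclosure;
* an Ornstein-Uhlenbeck wander velocity per agent (default sd 0.15 m/s, a
  calm grazing pace);
* reflective enclosure boundaries; non-event speed capped at 3 m/s.

The per-dyad equilibrium distance is ``equilibrium_dist_m * (2 - affinity)``:
affinity 1 pairs equilibrate at the configured distance, affinity 0 pairs
at twice it (and feel essentially no attraction).

Agonistic episodes — scripted or spontaneously triggered by crowding —
override the forces for the involved dyad: a setup leg steers the pair to a
3.2 m standoff with wall clearance and clear approach/escape corridors, the
aggressor then closes at the configured approach speed until the dyad is
below 1.5 m, and the target finally flees for three seconds at 1.3 m/s
(high-intensity) or 0.6 m/s (low-intensity). Hard positional floors — 2.2 m
from every uninvolved animal and exact standoff/approach distances — are
maintained throughout, so by construction every completed episode satisfies
the four approach criteria and exactly one of the two retreat definitions,
and no choreography leg can masquerade as an event on any other dyad.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import dyad_key

# Epoch of the first sample (2025-01-01T00:00:00Z); arbitrary but fixed so
# identical configs give byte-identical output files.
EPOCH0 = 1_735_689_600

# Movement-model constants (m, m/s). See module docstring.
HARD_CORE_M = 1.0
HARD_CORE_PUSH = 1.0
REPULSION_GAIN = 0.4
ATTRACTION_GAIN = 0.15
ATTRACTION_CAP = 0.3
# attraction dead zone: weakly bonded dyads tolerate a wide neutral band
# before group cohesion pulls them back, so a herd spreads out in a large
# field while strong associates stay near their equilibrium distance
ATTRACTION_DEADZONE_M = 50.0
SPEED_CAP = 3.0
WANDER_THETA = 0.3

# Episode choreography (m, m/s). Setup walking speeds stay below the 0.85 m/s
# approach-speed floor so that a setup leg can never register as an approach
# against any dyad, including third parties the walker passes.
SETUP_WALK_SPEED = 0.8
SETUP_TARGET_DIST = 3.2
APPROACH_STOP = 1.5
APPROACH_FLOOR = 1.2
RETREAT_STEPS = 3
RETREAT_SPEED_HIGH = 1.3
RETREAT_SPEED_LOW = 0.6
WALL_CLEARANCE = 4.0
WALL_MARGIN = 0.2

KIND_HIGH = "approach_then_high_retreat"
KIND_LOW = "approach_then_low_retreat"


@dataclass
class NoiseConfig:
    """UWB sensor-noise model.

    ``jitter_sd_cm`` is common-mode measurement noise shared by the two
    directed channels of a dyad (e.g. multipath affecting the pair geometry);
    ``replicate_sd_cm`` is independent per-channel noise, so the sd of the
    A→B minus B→A difference is sqrt(2) * replicate_sd_cm.
    """

    jitter_sd_cm: float = 2.0
    replicate_sd_cm: float = 3.0
    p_spike: float = 0.001
    p_under5: float = 0.0005
    frozen_segments: list = field(default_factory=list)  # (dyad, t_start, length_s)

    def __post_init__(self) -> None:
        for name in ("p_spike", "p_under5"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.jitter_sd_cm < 0 or self.replicate_sd_cm < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @classmethod
    def off(cls) -> "NoiseConfig":
        return cls(jitter_sd_cm=0.0, replicate_sd_cm=0.0, p_spike=0.0, p_under5=0.0)


@dataclass
class ScriptedEvent:
    """One choreographed agonistic episode."""

    t_start_s: int
    aggressor: str
    target: str
    kind: str = KIND_HIGH
    approach_speed_cm_s: float = 100.0

    def __post_init__(self) -> None:
        if self.aggressor == self.target:
            raise ValueError("aggressor and target must differ")
        if self.kind not in (KIND_HIGH, KIND_LOW):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.approach_speed_cm_s < 85.0:
            raise ValueError("approach_speed_cm_s must be >= 85 cm/s")


@dataclass
class SpontaneousAggression:
    """Crowding-triggered episodes.

    While a free dyad intrudes into its own social tolerance — closer than
    ``intrusion_factor`` times the dyad's equilibrium distance (and below the
    absolute ``trigger_max_cm`` cap) — it initiates an episode with this
    per-second hazard. Tying the trigger to the dyad's equilibrium makes
    aggression a personal-space violation: bonded pairs tolerate proximity,
    loose dyads do not. The hazard additionally scales with how many other
    animals crowd the dyad (within ``crowd_radius_m``), so a cramped pen
    generates more violations than an open field under identical social
    structure."""

    rate_per_pair_s: float = 0.02
    trigger_min_cm: float = 300.0
    trigger_max_cm: float = 500.0
    intrusion_factor: float = 0.85
    crowd_radius_m: float = 8.0
    p_high: float = 0.15


@dataclass
class SimConfig:
    enclosure_length_m: float
    enclosure_width_m: float
    n_agents: int
    duration_s: int
    seed: int = 0
    affinity: Optional[np.ndarray] = None
    equilibrium_dist_m: float = 3.0
    feeder_xy: Optional[tuple[float, float]] = None
    event_schedule: list = field(default_factory=list)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    spontaneous: Optional[SpontaneousAggression] = None
    wander_sd_m_s: float = 0.15
    agent_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("need at least 2 agents")
        if self.duration_s < 60:
            raise ValueError("duration_s must be >= 60")
        if self.enclosure_length_m <= 0 or self.enclosure_width_m <= 0:
            raise ValueError("enclosure dimensions must be positive")
        if self.agent_ids is None:
            self.agent_ids = [f"h{i + 1:02d}" for i in range(self.n_agents)]
        if len(self.agent_ids) != self.n_agents:
            raise ValueError("agent_ids length must equal n_agents")
        if self.affinity is None:
            self.affinity = default_affinity(self.n_agents, self.seed)
        self.affinity = np.asarray(self.affinity, dtype=float)
        if self.affinity.shape != (self.n_agents, self.n_agents):
            raise ValueError("affinity must be n_agents x n_agents")
        if not np.allclose(self.affinity, self.affinity.T):
            raise ValueError("affinity matrix must be symmetric")
        off = self.affinity[~np.eye(self.n_agents, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ValueError("affinities must lie in [0, 1]")
        if self.feeder_xy is not None:
            fx, fy = self.feeder_xy
            if not (0 <= fx <= self.enclosure_length_m and 0 <= fy <= self.enclosure_width_m):
                raise ValueError("feeder_xy must lie inside the enclosure")
        roster = set(self.agent_ids)
        for ev in self.event_schedule:
            if ev.aggressor not in roster or ev.target not in roster:
                raise ValueError(f"event agents {ev.aggressor}/{ev.target} not in roster")
            if ev.t_start_s + 10 > self.duration_s:
                raise ValueError("scripted event does not fit in duration_s")
        if self.event_schedule or self.spontaneous is not None:
            if min(self.enclosure_length_m, self.enclosure_width_m) < 9.0:
                raise ValueError("enclosure too narrow for choreographed episodes (need >= 9 m)")

    def to_yaml(self, path) -> None:
        doc = {
            "enclosure_length_m": self.enclosure_length_m,
            "enclosure_width_m": self.enclosure_width_m,
            "n_agents": self.n_agents,
            "duration_s": self.duration_s,
            "seed": self.seed,
            "equilibrium_dist_m": self.equilibrium_dist_m,
            "wander_sd_m_s": self.wander_sd_m_s,
            "agent_ids": list(self.agent_ids),
            "affinity": np.asarray(self.affinity).tolist(),
            "feeder_xy": list(self.feeder_xy) if self.feeder_xy else None,
            "noise": {
                "jitter_sd_cm": self.noise.jitter_sd_cm,
                "replicate_sd_cm": self.noise.replicate_sd_cm,
                "p_spike": self.noise.p_spike,
                "p_under5": self.noise.p_under5,
            },
            "event_schedule": [
                {
                    "t_start_s": ev.t_start_s,
                    "aggressor": ev.aggressor,
                    "target": ev.target,
                    "kind": ev.kind,
                    "approach_speed_cm_s": ev.approach_speed_cm_s,
                }
                for ev in self.event_schedule
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class TrueEvent:
    """Ground-truth record of one episode: the approach leg window and the
    retreat leg window, in epoch seconds (matching the sensor-table clock)."""

    kind: str
    aggressor: str
    target: str
    approach_t0: int
    approach_t1: int
    retreat_t0: int
    retreat_t1: int

    @property
    def dyad(self) -> tuple[str, str]:
        return dyad_key(self.aggressor, self.target)

    @property
    def retreat_kind(self) -> str:
        return "high_retreat" if self.kind == KIND_HIGH else "low_retreat"


@dataclass
class GroundTruth:
    times: np.ndarray  # epoch seconds, shape (T,)
    positions: np.ndarray  # metres, shape (T, n, 2)
    agent_ids: list[str]
    events: list[TrueEvent] = field(default_factory=list)
    injected_artifacts: list[dict] = field(default_factory=list)


@dataclass
class SimResult:
    config: SimConfig
    ground_truth: GroundTruth

    @property
    def positions(self) -> np.ndarray:
        return self.ground_truth.positions

    @property
    def times(self) -> np.ndarray:
        return self.ground_truth.times


def default_affinity(n: int, seed: int = 0) -> np.ndarray:
    """Pair-bonded affinity structure: consecutive agents are paired as
    strong associates (affinity ~0.9); all other dyads draw from [0.1, 0.4].
    An odd roster leaves the last agent with moderate bonds only."""
    rng = np.random.default_rng(seed)
    aff = rng.uniform(0.1, 0.4, size=(n, n))
    aff = (aff + aff.T) / 2.0
    for i in range(0, n - 1, 2):
        aff[i, i + 1] = aff[i + 1, i] = rng.uniform(0.85, 0.95)
    np.fill_diagonal(aff, 0.0)
    return aff


class _Episode:
    __slots__ = (
        "aggressor", "target", "kind", "approach_speed_m",
        "phase", "approach_t0", "approach_t1", "retreat_t0",
        "retreat_steps", "setup_steps", "retreat_dir", "scripted", "attempts",
    )

    def __init__(
        self,
        aggressor: int,
        target: int,
        kind: str,
        approach_speed_cm_s: float,
        scripted: bool = False,
        attempts: int = 0,
    ):
        self.aggressor = aggressor
        self.target = target
        self.kind = kind
        self.approach_speed_m = approach_speed_cm_s / 100.0
        self.phase = "setup"
        self.approach_t0 = -1
        self.approach_t1 = -1
        self.retreat_t0 = -1
        self.retreat_steps = 0
        self.setup_steps = 0
        self.retreat_dir = None
        self.scripted = scripted
        self.attempts = attempts


def _unit(vec: np.ndarray) -> np.ndarray:
    norm = float(np.hypot(vec[0], vec[1]))
    if norm < 1e-9:
        return np.array([1.0, 0.0])
    return vec / norm


def simulate_herd(config: SimConfig) -> SimResult:
    """Run the simulation; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_agents
    L, W = config.enclosure_length_m, config.enclosure_width_m
    T = int(config.duration_s)
    eq = config.equilibrium_dist_m * (2.0 - config.affinity)  # per-dyad equilibrium
    aff2 = config.affinity ** 2
    att_from = eq + ATTRACTION_DEADZONE_M * (1.0 - config.affinity) ** 2
    clearance_req = min(WALL_CLEARANCE, min(L, W) / 2.0 - 0.5)

    pos = _initial_positions(rng, n, L, W)
    wander = np.zeros((n, 2))
    positions = np.empty((T, n, 2))
    mode = np.zeros(n, dtype=int)  # 0 free, 1 episode, 2 feeder bout
    feeder_state: dict[int, int] = {}  # agent -> dwell seconds remaining (-1 walking)
    episodes: list[_Episode] = []
    finished: list[TrueEvent] = []
    pending = [(ev, ev.t_start_s, 0) for ev in sorted(config.event_schedule, key=lambda e: e.t_start_s)]
    source_of: dict[int, object] = {}
    idx_of = {a: i for i, a in enumerate(config.agent_ids)}
    centre = np.array([L / 2.0, W / 2.0])
    feeder = np.asarray(config.feeder_xy, dtype=float) if config.feeder_xy is not None else None

    for t in range(T):
        positions[t] = pos
        if t == T - 1:
            break

        # start scripted episodes (deferred until both agents are free)
        still_pending = []
        for ev, t_start, attempts in pending:
            i, j = idx_of[ev.aggressor], idx_of[ev.target]
            if t_start <= t and mode[i] == 0 and mode[j] == 0:
                ep = _Episode(i, j, ev.kind, ev.approach_speed_cm_s, scripted=True, attempts=attempts)
                episodes.append(ep)
                source_of[id(ep)] = ev
                mode[i] = mode[j] = 1
            else:
                still_pending.append((ev, t_start, attempts))
        pending = still_pending

        # spontaneous crowding-triggered episodes
        sp = config.spontaneous
        if sp is not None:
            diff = pos[:, None, :] - pos[None, :, :]
            dist_m = np.hypot(diff[..., 0], diff[..., 1])
            for i in range(n):
                if mode[i] != 0:
                    continue
                for j in range(i + 1, n):
                    if mode[j] != 0:
                        continue
                    d_cm = dist_m[i, j] * 100.0
                    upper = min(sp.trigger_max_cm, sp.intrusion_factor * eq[i, j] * 100.0)
                    if sp.trigger_min_cm <= d_cm <= upper:
                        # hazard grows with the number of animals crowding the pair
                        near = int(
                            np.sum(
                                (dist_m[i] < sp.crowd_radius_m) | (dist_m[j] < sp.crowd_radius_m)
                            )
                        ) - 2
                        crowd = near / max(n - 2, 1)
                        if rng.random() < sp.rate_per_pair_s * (0.2 + 0.8 * crowd):
                            kind = KIND_HIGH if rng.random() < sp.p_high else KIND_LOW
                            aggressor, target = (i, j) if rng.random() < 0.5 else (j, i)
                            episodes.append(_Episode(aggressor, target, kind, 100.0))
                            mode[i] = mode[j] = 1
                            break

        new_pos = pos.copy()

        # social forces + wander for free agents (feeder agents: hard-core only)
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(dist, np.inf)
        with np.errstate(invalid="ignore"):
            unit = diff / dist[..., None]
        unit = np.nan_to_num(unit)

        finite = np.isfinite(dist)
        dist_safe = np.where(finite, dist, 0.0)
        hard = np.where(dist < HARD_CORE_M, HARD_CORE_PUSH * (HARD_CORE_M - dist_safe) / HARD_CORE_M, 0.0)
        rep = np.where(
            (dist >= HARD_CORE_M) & (dist < eq),
            REPULSION_GAIN * (eq - dist_safe) / eq,
            0.0,
        )
        att = np.where(
            finite & (dist > att_from), ATTRACTION_GAIN * aff2 * (dist_safe - att_from), 0.0
        )
        att = np.minimum(att, ATTRACTION_CAP)
        # positive magnitude pushes i away from j; attraction pulls toward j
        magnitude = np.where(finite, hard + rep - att, 0.0)
        # bystanders give an ongoing confrontation a wide berth: a gentle
        # (< 0.4 m/s) push keeps free agents from drifting into the episode
        busy = mode == 1
        if busy.any():
            avoid = np.where(
                busy[None, :] & finite & (dist < 3.5), 0.4 * (3.5 - dist_safe) / 3.5, 0.0
            )
            magnitude = magnitude + avoid
        vel_soc = (magnitude[..., None] * unit).sum(axis=1)

        wander = (1.0 - WANDER_THETA) * wander + math.sqrt(
            WANDER_THETA * (2.0 - WANDER_THETA)
        ) * config.wander_sd_m_s * rng.standard_normal((n, 2))

        for i in range(n):
            if mode[i] == 1:
                continue
            if mode[i] == 2:
                v = (hard[i][:, None] * unit[i]).sum(axis=0) + 0.05 * rng.standard_normal(2)
                dwell = feeder_state[i]
                if dwell < 0:  # walking to the feeder
                    to_feeder = feeder - pos[i]
                    if np.hypot(*to_feeder) <= 1.0:
                        feeder_state[i] = 120
                    else:
                        v = v + 0.8 * _unit(to_feeder)
                else:
                    feeder_state[i] = dwell - 1
                    if dwell == 0:
                        del feeder_state[i]
                        mode[i] = 0
            else:
                v = vel_soc[i] + wander[i]
                if feeder is not None and rng.random() < 1.0 / 900.0:
                    mode[i] = 2
                    feeder_state[i] = -1
            speed = float(np.hypot(v[0], v[1]))
            if speed > SPEED_CAP:
                v = v * (SPEED_CAP / speed)
            new_pos[i] = pos[i] + v

        # choreographed episodes override motion for their dyad
        done = []
        for ep in episodes:
            _step_episode(ep, new_pos, pos, t, centre, L, W, clearance_req)
            if ep.phase == "done":
                done.append(ep)
                finished.append(
                    TrueEvent(
                        kind=ep.kind,
                        aggressor=config.agent_ids[ep.aggressor],
                        target=config.agent_ids[ep.target],
                        approach_t0=EPOCH0 + ep.approach_t0,
                        approach_t1=EPOCH0 + ep.approach_t1,
                        retreat_t0=EPOCH0 + ep.retreat_t0,
                        retreat_t1=EPOCH0 + t + 1,
                    )
                )
                mode[ep.aggressor] = mode[ep.target] = 0
            elif ep.phase == "aborted":
                # setup could not find clear corridors: free the agents and,
                # for scripted episodes, retry shortly (spontaneous ones are
                # opportunistic and simply lapse)
                done.append(ep)
                mode[ep.aggressor] = mode[ep.target] = 0
                src = source_of.pop(id(ep), None)
                if src is not None and t + 15 + 10 <= T:
                    pending.append((src, t + 15, ep.attempts + 1))
        for ep in done:
            episodes.remove(ep)
            source_of.pop(id(ep), None)

        # reflective boundaries
        new_pos[:, 0] = _reflect(new_pos[:, 0], L)
        new_pos[:, 1] = _reflect(new_pos[:, 1], W)
        pos = new_pos

    finished.sort(key=lambda e: e.approach_t0)
    gt = GroundTruth(
        times=EPOCH0 + np.arange(T, dtype=np.int64),
        positions=positions,
        agent_ids=list(config.agent_ids),
        events=finished,
    )
    return SimResult(config=config, ground_truth=gt)


def _initial_positions(rng, n: int, L: float, W: float) -> np.ndarray:
    pos = np.empty((n, 2))
    for i in range(n):
        for _ in range(200):
            cand = rng.uniform([1.0, 1.0], [L - 1.0, W - 1.0])
            if i == 0 or np.hypot(*(pos[:i] - cand).T).min() > 1.5:
                break
        pos[i] = cand
    return pos


def _reflect(x: np.ndarray, upper: float) -> np.ndarray:
    x = np.abs(x)
    over = x > upper
    x[over] = 2.0 * upper - x[over]
    return np.clip(x, 0.0, upper)


def _point_segment_distance(p: np.ndarray, s0: np.ndarray, s1: np.ndarray) -> float:
    seg = s1 - s0
    denom = float(seg @ seg)
    u = 0.0 if denom < 1e-12 else float(np.clip((p - s0) @ seg / denom, 0.0, 1.0))
    proj = s0 + u * seg
    return float(np.hypot(*(p - proj)))


def _staging_point(p_t: np.ndarray, p_a: np.ndarray, others: np.ndarray, L: float, W: float) -> np.ndarray:
    """Point at SETUP_TARGET_DIST from the target whose approach corridor AND
    the opposite escape lane stay as clear of third parties as possible
    (ties favour the nearest azimuth)."""
    best, best_score = None, -np.inf
    for k in range(16):
        ang = 2.0 * math.pi * k / 16.0
        u = np.array([math.cos(ang), math.sin(ang)])
        cand = p_t + SETUP_TARGET_DIST * u
        if not (WALL_MARGIN <= cand[0] <= L - WALL_MARGIN and WALL_MARGIN <= cand[1] <= W - WALL_MARGIN):
            continue
        clear_in = min((_point_segment_distance(o, cand, p_t) for o in others), default=np.inf)
        flee_end = p_t - 4.2 * u
        clear_out = min((_point_segment_distance(o, p_t, flee_end) for o in others), default=np.inf)
        score = min(clear_in, clear_out, 6.0) - 0.05 * float(np.hypot(*(p_a - cand)))
        if score > best_score:
            best, best_score = cand, score
    return best if best is not None else p_t + SETUP_TARGET_DIST * _unit(p_a - p_t)


def _flee_direction(
    p_t: np.ndarray, p_a: np.ndarray, others: np.ndarray, speed: float, L: float, W: float
) -> np.ndarray:
    """Flight direction near straight-away from the aggressor that keeps the
    flight path clearest of third parties (so a retreat cannot masquerade as
    an approach toward an uninvolved animal). Prefers a clear lane within
    ±45° — which keeps the per-step distance gain above the flight class's
    thresholds — and widens to ±60° only when boxed in."""
    base = _unit(p_t - p_a)
    base_ang = math.atan2(base[1], base[0])
    cands = []
    for deg in range(-60, 61, 5):
        ang = base_ang + math.radians(deg)
        u = np.array([math.cos(ang), math.sin(ang)])
        end = p_t + RETREAT_STEPS * speed * u
        if not (WALL_MARGIN <= end[0] <= L - WALL_MARGIN and WALL_MARGIN <= end[1] <= W - WALL_MARGIN):
            continue
        clear = min((_point_segment_distance(o, p_t, end) for o in others), default=np.inf)
        cands.append((deg, u, clear))
    if not cands:
        return base
    good = [c for c in cands if c[2] >= 2.35 and abs(c[0]) <= 45]
    if good:
        return min(good, key=lambda c: abs(c[0]))[1]
    return max(cands, key=lambda c: (min(c[2], 2.35), -abs(c[0])))[1]


def _walk(p: np.ndarray, goal: np.ndarray, others: np.ndarray, speed: float) -> np.ndarray:
    """One walking step toward ``goal`` at ≤ ``speed``, steering around third
    parties."""
    v = min(speed, float(np.hypot(*(goal - p)))) * _unit(goal - p)
    for o in others:
        gap = float(np.hypot(*(p - o)))
        if gap < 2.5:
            v = v + (2.5 - gap) * _unit(p - o)
    s = float(np.hypot(*v))
    if s > speed:
        v = v * (speed / s)
    return p + v


def _ring_position(
    p: np.ndarray,
    centre: np.ndarray,
    radius: float,
    others: np.ndarray,
    min_other: float,
    L: float,
    W: float,
) -> np.ndarray:
    """Nearest point (by angle) on the circle (centre, radius) to ``p`` that
    stays in bounds and ≥ ``min_other`` from every third party. A plain
    radial snap can land inside a third party's exclusion circle; sliding
    along the ring resolves the conflict without compromising the exact
    distance to the circle's centre. Falls back to the radial snap when the
    whole ring is blocked."""
    base = math.atan2(p[1] - centre[1], p[0] - centre[0])
    for k in range(37):
        for sign in ((1,) if k == 0 else (1, -1)):
            ang = base + sign * math.radians(5 * k)
            cand = centre + radius * np.array([math.cos(ang), math.sin(ang)])
            if not (WALL_MARGIN <= cand[0] <= L - WALL_MARGIN and WALL_MARGIN <= cand[1] <= W - WALL_MARGIN):
                continue
            if all(float(np.hypot(*(cand - o))) >= min_other - 1e-9 for o in others):
                return cand
    return centre + radius * _unit(p - centre)


def _enforce_standoffs(
    p: np.ndarray, others: np.ndarray, min_other: float, anchor=None, min_anchor: float = 0.0
) -> np.ndarray:
    """Project ``p`` out of every exclusion circle: ≥ ``min_other`` from each
    third party and (applied last, so it always holds exactly) ≥
    ``min_anchor`` from ``anchor``. These positional floors guarantee that no
    choreography leg can end a window below the approach end-distance
    against any dyad, whatever the instantaneous speeds."""
    for _ in range(4):
        moved = False
        for o in others:
            gap = float(np.hypot(*(p - o)))
            if gap < min_other:
                p = o + min_other * _unit(p - o)
                moved = True
        if anchor is not None and float(np.hypot(*(p - anchor))) < min_anchor:
            p = anchor + min_anchor * _unit(p - anchor)
            moved = True
        if not moved:
            break
    return p


def _step_episode(
    ep: _Episode, new_pos, pos, t: int, centre, L: float, W: float, clearance_req: float
) -> None:
    a, g = ep.aggressor, ep.target
    p_a, p_t = pos[a].copy(), pos[g].copy()
    third = [i for i in range(len(pos)) if i not in (a, g)]
    others = np.array([pos[i] for i in third])
    # positional floors are enforced against where third parties END UP this
    # tick, so the per-sample distance of any (mover, third) dyad stays above
    # the approach end-distance whatever the concurrent motion
    others_next = np.array([new_pos[i] for i in third])

    if ep.phase == "setup":
        ep.setup_steps += 1
        clearance = min(p_t[0], L - p_t[0], p_t[1], W - p_t[1])
        if clearance < clearance_req:
            p_t = _walk(p_t, centre, others, SETUP_WALK_SPEED)
            p_t = _enforce_standoffs(p_t, others_next, 2.2)
            clearance = min(p_t[0], L - p_t[0], p_t[1], W - p_t[1])
        staging = _staging_point(p_t, p_a, others, L, W)
        p_a = _walk(p_a, staging, others, SETUP_WALK_SPEED)
        p_a = _enforce_standoffs(p_a, others_next, 2.2)
        if float(np.hypot(*(p_a - p_t))) < SETUP_TARGET_DIST:
            # sliding along the standoff ring keeps both floors exact
            p_a = _ring_position(p_a, p_t, SETUP_TARGET_DIST, others_next, 2.2, L, W)
        new_pos[a], new_pos[g] = p_a, p_t
        # launch the dive only once staged, wall-clear, with a clear corridor
        # to the target AND a clear escape lane behind it — otherwise the
        # flight could be boxed in and fail the rise its class promises
        if float(np.hypot(*(p_a - staging))) < 0.3 and clearance >= clearance_req:
            corridor = min(
                (_point_segment_distance(o, p_a, p_t) for o in others), default=np.inf
            )
            flee_end = p_t + 4.2 * _unit(p_t - p_a)
            escape = min(
                (_point_segment_distance(o, p_t, flee_end) for o in others), default=np.inf
            )
            if (corridor >= 3.0 and escape >= 2.6) or ep.attempts >= 3:
                ep.phase = "approach"
                ep.approach_t0 = t + 1
        if ep.setup_steps > 40 and ep.phase == "setup":
            ep.phase = "aborted"
        return

    if ep.phase == "approach":
        d = float(np.hypot(*(p_a - p_t)))
        new_d = max(d - ep.approach_speed_m, APPROACH_FLOOR)
        p_a = p_t + new_d * _unit(p_a - p_t)
        # the approach criteria constrain only the distance to the target, so
        # the diver may slide around the exact-distance circle to hold the
        # third-party floor while the distance profile stays exact
        if any(float(np.hypot(*(p_a - o))) < 2.5 for o in others_next):
            p_a = _ring_position(p_a, p_t, new_d, others_next, 2.5, L, W)
        new_pos[a], new_pos[g] = p_a, p_t
        if new_d < APPROACH_STOP:
            ep.phase = "retreat"
            ep.approach_t1 = t + 1
            ep.retreat_t0 = t + 1
        return

    if ep.phase == "retreat":
        speed = RETREAT_SPEED_HIGH if ep.kind == KIND_HIGH else RETREAT_SPEED_LOW
        # re-aim every step: avoidance deflection must not erode the rise
        ep.retreat_dir = _flee_direction(p_t, p_a, others, speed, L, W)
        p_t = p_t + speed * ep.retreat_dir
        p_t = _enforce_standoffs(p_t, others_next, 2.2)
        p_t = np.clip(p_t, WALL_MARGIN, [L - WALL_MARGIN, W - WALL_MARGIN])
        ep.retreat_steps += 1
        new_pos[a], new_pos[g] = p_a, p_t
        if ep.retreat_steps >= RETREAT_STEPS:
            ep.phase = "done"


def trajectories_to_distances(
    sim: SimResult,
    noise: Optional[NoiseConfig] = None,
    seed: int = 0,
    include_feeder: bool = True,
) -> pd.DataFrame:
    """Turn true trajectories into the raw sensor table.

    Emits both ordered channels (A→B and B→A) per dyad in cm at 1 Hz, an
    optional feeder channel per agent, and injects artifacts per the noise
    model, logging every injected sample into the ground truth.
    """
    cfg = sim.config
    if noise is None:
        noise = cfg.noise
    rng = np.random.default_rng(seed)
    gt = sim.ground_truth
    T = len(gt.times)
    ids = gt.agent_ids
    diag_cm = 100.0 * math.hypot(cfg.enclosure_length_m, cfg.enclosure_width_m)

    frames = []
    frozen_by_dyad: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for entry in noise.frozen_segments:
        dyad, t_start, length = entry
        frozen_by_dyad.setdefault(dyad_key(*dyad), []).append((int(t_start), int(length)))

    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            true_cm = 100.0 * np.hypot(
                gt.positions[:, i, 0] - gt.positions[:, j, 0],
                gt.positions[:, i, 1] - gt.positions[:, j, 1],
            )
            common = rng.normal(0.0, noise.jitter_sd_cm, T) if noise.jitter_sd_cm > 0 else 0.0
            for a_id, b_id in ((ids[i], ids[j]), (ids[j], ids[i])):
                vals = true_cm + common
                if noise.replicate_sd_cm > 0:
                    vals = vals + rng.normal(0.0, noise.replicate_sd_cm, T)
                vals = np.maximum(vals, 5.0)  # sensor floor: clean readings never dip below range
                if noise.p_spike > 0:
                    spike_mask = rng.random(T) < noise.p_spike
                    vals[spike_mask] = rng.uniform(1.02 * diag_cm, 1.4 * diag_cm, int(spike_mask.sum()))
                    for tt in np.nonzero(spike_mask)[0]:
                        gt.injected_artifacts.append(
                            {"class": "spike", "sensor_a": a_id, "sensor_b": b_id, "t": int(gt.times[tt])}
                        )
                else:
                    spike_mask = np.zeros(T, dtype=bool)
                if noise.p_under5 > 0:
                    u5_mask = (rng.random(T) < noise.p_under5) & ~spike_mask
                    vals[u5_mask] = rng.uniform(0.5, 4.9, int(u5_mask.sum()))
                    for tt in np.nonzero(u5_mask)[0]:
                        gt.injected_artifacts.append(
                            {"class": "under5", "sensor_a": a_id, "sensor_b": b_id, "t": int(gt.times[tt])}
                        )
                for t_start, length in frozen_by_dyad.get(dyad_key(a_id, b_id), ()):
                    stop = min(t_start + length, T)
                    vals[t_start:stop] = vals[t_start]
                frames.append(
                    pd.DataFrame(
                        {"t": gt.times, "sensor_a": a_id, "sensor_b": b_id, "distance_cm": vals}
                    )
                )
    for dyad, segs in frozen_by_dyad.items():
        for t_start, length in segs:
            gt.injected_artifacts.append(
                {
                    "class": "frozen",
                    "sensor_a": dyad[0],
                    "sensor_b": dyad[1],
                    "t": int(gt.times[0]) + t_start,
                    "length": length,
                }
            )

    if include_feeder and cfg.feeder_xy is not None:
        fx, fy = cfg.feeder_xy
        for i, a_id in enumerate(ids):
            vals = 100.0 * np.hypot(gt.positions[:, i, 0] - fx, gt.positions[:, i, 1] - fy)
            if noise.jitter_sd_cm > 0:
                vals = vals + rng.normal(0.0, noise.jitter_sd_cm, T)
            vals = np.maximum(vals, 5.0)
            frames.append(
                pd.DataFrame({"t": gt.times, "sensor_a": a_id, "sensor_b": "feeder", "distance_cm": vals})
            )

    return pd.concat(frames, ignore_index=True)


def write_distance_csv(table: pd.DataFrame, path) -> None:
    """Write the long-format sensor table with ISO-8601 timestamps."""
    out = table.copy()
    out["timestamp"] = pd.to_datetime(out.pop("t"), unit="s", utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out[["timestamp", "sensor_a", "sensor_b", "distance_cm"]].to_csv(path, index=False)


def write_ground_truth(gt: GroundTruth, path) -> None:
    """JSON sidecar with events and injected artifacts (positions stay in memory)."""
    doc = {
        "agent_ids": gt.agent_ids,
        "t0_epoch": int(gt.times[0]),
        "events": [
            {
                "kind": ev.kind,
                "aggressor": ev.aggressor,
                "target": ev.target,
                "approach_t0": ev.approach_t0,
                "approach_t1": ev.approach_t1,
                "retreat_t0": ev.retreat_t0,
                "retreat_t1": ev.retreat_t1,
                "retreat_kind": ev.retreat_kind,
            }
            for ev in gt.events
        ],
        "injected_artifacts": gt.injected_artifacts,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def schedule_events(
    n_events: int,
    duration_s: int,
    agent_ids: Sequence[str],
    seed: int = 0,
    spacing_s: int = 60,
    p_high: float = 0.5,
) -> list[ScriptedEvent]:
    """Evenly spaced scripted episodes over random dyads (test/validation aid).

    The default spacing keeps episodes strictly sequential even with a long
    setup walk, so no two choreographed events can overlap in time."""
    rng = np.random.default_rng(seed)
    first = 30
    if first + (n_events - 1) * spacing_s + 30 > duration_s:
        raise ValueError("duration too short for the requested schedule")
    out = []
    for k in range(n_events):
        a, b = rng.choice(len(agent_ids), size=2, replace=False)
        kind = KIND_HIGH if rng.random() < p_high else KIND_LOW
        out.append(
            ScriptedEvent(
                t_start_s=first + k * spacing_s,
                aggressor=agent_ids[a],
                target=agent_ids[b],
                kind=kind,
            )
        )
    return out
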