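"""Discrete-time simulator for the Team Spirit paddle game.

Two paddles move along a horizontal line near the bottom of an 800x600
frame and deflect balls that fall from the top at constant velocity.
Vertical 40-px side panels carry a secondary detection-response task
(DRT); the playable span is the region between them.  A ball that
rebounds off a paddle is a *hit*; a ball that crosses the bottom edge is
a *miss*.  Group conditions differ in ball ownership and scoring:

``separate``
    each player has their own set of balls (red for player A, blue for
    player B); a ball passes through the other player's paddle and only
    the owner is credited or debited.
``collaborative``
    balls are purple, either paddle can deflect any ball, and hits add
    to a single team score.
``competitive``
    balls are purple and shared, but hits add to individual scores;
    simultaneous hits are split equally.

The *workload* of a trial is the number of balls kept concurrently in
play per processing unit: a separate-condition trial spawns ``workload``
balls for each player, a team trial spawns ``workload`` shared balls.
Missed balls are replaced after a fixed delay so the nominal workload
holds for the whole trial; balls that rebound past the top edge re-enter
as a fresh descent of the same ball id (the hit has already been
credited).  Trials run for exactly ``tick_rate * trial_duration`` frames
and balls still descending at the final frame are censored (neither hit
nor miss).

Everything is deterministic given (seed, config, policies).
"""

from __future__ import annotations

import hashlib
import json
import math
import random
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Sequence

import numpy as np

CONDITIONS = ("separate", "collaborative", "competitive")
TEAM_CONDITIONS = ("collaborative", "competitive")
WORKLOAD_NAMES = ("low", "medium", "high", "very_high")

ACTION_CODES = {"left": -1, "none": 0, "right": 1}

_EVENT_KINDS = ("spawn", "hit", "miss", "drt_onset", "drt_response")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GameConfig:
    """Geometry, kinematics and schedule of one Team Spirit game.

    Distances are in pixels, durations in seconds, speeds in px/s.
    ``workload_levels`` maps level names to concurrent ball counts per
    processing unit.  Defaults reproduce the study task: an 800x600
    frame with 40-px DRT panels (720-px playable span), 45-s trials, and
    ball counts 1/3/5/7 for the four workload levels.
    """

    frame_width: float = 800.0
    frame_height: float = 600.0
    drt_panel_width: float = 40.0
    paddle_width: float = 100.0
    paddle_speed: float = 400.0
    ball_speed: float = 300.0
    tick_rate: int = 60
    trial_duration: float = 45.0
    workload_levels: dict = field(
        default_factory=lambda: {"low": 1, "medium": 3, "high": 5, "very_high": 7}
    )
    seed: int = 0
    # secondary geometry / scheduling (not independently varied in the study)
    paddle_y: float = 560.0
    ball_radius: float = 10.0
    respawn_delay_s: float = 1.0
    max_launch_angle_deg: float = 60.0
    drt_isi_range_s: tuple = (3.0, 5.0)
    drt_window_s: float = 2.5

    def __post_init__(self) -> None:
        if min(self.paddle_width, self.paddle_speed, self.ball_speed,
               self.trial_duration, self.tick_rate) <= 0:
            raise ValueError("all speeds, widths and durations must be > 0")
        if self.playable_span <= self.paddle_width:
            raise ValueError("playable span must exceed the paddle width")
        wl = self.workload_levels
        if list(wl) != list(WORKLOAD_NAMES):
            raise ValueError(f"workload_levels must have keys {WORKLOAD_NAMES}")
        if wl["low"] != 1 or wl["medium"] != 3:
            raise ValueError("workload_levels must fix low=1 and medium=3")
        counts = list(wl.values())
        if any(b <= a for a, b in zip(counts, counts[1:])):
            raise ValueError("workload levels must be strictly increasing")
        if not 0 < self.paddle_y < self.frame_height:
            raise ValueError("paddle_y must lie inside the frame")

    # playable span between the DRT panels
    @property
    def left_bound(self) -> float:
        return self.drt_panel_width

    @property
    def right_bound(self) -> float:
        return self.frame_width - self.drt_panel_width

    @property
    def playable_span(self) -> float:
        return self.frame_width - 2.0 * self.drt_panel_width

    @property
    def n_frames(self) -> int:
        return int(round(self.tick_rate * self.trial_duration))

    def paddle_bounds(self) -> tuple:
        half = self.paddle_width / 2.0
        return (self.left_bound + half, self.right_bound - half)

    def workload_count(self, workload) -> int:
        """Resolve a workload level name (or a raw ball count) to a count."""
        if isinstance(workload, str):
            try:
                return self.workload_levels[workload]
            except KeyError:
                raise ValueError(f"unknown workload level {workload!r}") from None
        n = int(workload)
        if n < 0:
            raise ValueError("ball count must be >= 0")
        return n

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.md5(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# game objects
# ---------------------------------------------------------------------------

class Ball:
    __slots__ = ("ball_id", "x", "y", "vx", "vy", "color", "alive", "rng")

    def __init__(self, ball_id, x, y, vx, vy, color, alive=True, rng=None):
        self.ball_id = ball_id
        self.x = x
        self.y = y
        self.vx = vx
        self.vy = vy
        self.color = color
        self.alive = alive
        # each ball carries its own random stream so one player's balls
        # evolve independently of when the other player's balls terminate
        self.rng = rng if rng is not None else random.Random(0)

    def as_dict(self) -> dict:
        return {"id": self.ball_id, "x": self.x, "y": self.y,
                "vx": self.vx, "vy": self.vy, "color": self.color,
                "alive": self.alive}

    def __repr__(self):  # pragma: no cover - debugging aid
        return (f"Ball({self.ball_id}, x={self.x:.1f}, y={self.y:.1f}, "
                f"vx={self.vx:.1f}, vy={self.vy:.1f}, {self.color})")


@dataclass(frozen=True)
class GameEvent:
    """One discrete game event; ``t`` is in seconds from trial start."""

    t: float
    kind: str
    ball_id: int | None = None
    players: tuple = ()


class GameState:
    """Mutable state of a trial in progress.

    Player A owns the red paddle, player B the blue one.  In the
    separate condition ball ownership follows paddle color; in team
    conditions all balls are purple and shared.
    """

    def __init__(self, config: GameConfig, condition: str, workload,
                 rng: random.Random, solo: bool = False):
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        self.config = config
        self.condition = condition
        self.workload = workload
        self.n_balls = config.workload_count(workload)
        self.rng = rng
        self.solo = solo
        self.t = 0  # frame index
        lo, hi = config.paddle_bounds()
        mid = 0.5 * (lo + hi)
        quarter = 0.25 * (hi - lo)
        self.paddle_x = {"A": mid - quarter, "B": mid + quarter}
        self.balls: list[Ball] = []
        self.pending: list = []  # (due_frame, color) respawns after misses
        self.events: list[GameEvent] = []
        self.scores = {"A": 0.0, "B": 0.0, "team": 0.0}
        self.hits = {"A": 0.0, "B": 0.0, "team": 0.0}
        self.misses = {"A": 0.0, "B": 0.0, "team": 0.0}
        self.n_spawned = 0
        self._next_ball_id = 0
        self._spawn_initial()

    # -- spawning -----------------------------------------------------------

    def _spawn_initial(self) -> None:
        if self.condition == "separate":
            colors = ["red"] * self.n_balls
            if not self.solo:
                colors += ["blue"] * self.n_balls
        else:
            colors = ["purple"] * self.n_balls
        for c in colors:
            self._spawn(c)

    def _launch(self, ball: Ball) -> None:
        """(Re)start a descent from the top edge at a random x and angle."""
        cfg = self.config
        r = cfg.ball_radius
        rng = ball.rng
        ball.x = rng.uniform(cfg.left_bound + r, cfg.right_bound - r)
        ball.y = 0.0
        ang = math.radians(rng.uniform(-cfg.max_launch_angle_deg,
                                       cfg.max_launch_angle_deg))
        ball.vx = cfg.ball_speed * math.sin(ang)
        ball.vy = cfg.ball_speed * math.cos(ang)
        ball.alive = True
        self.n_spawned += 1

    def _spawn(self, color: str) -> Ball:
        ball = Ball(self._next_ball_id, 0.0, 0.0, 0.0, 0.0, color,
                    rng=random.Random(self.rng.randrange(2 ** 31)))
        self._next_ball_id += 1
        self._launch(ball)
        self.balls.append(ball)
        return ball

    # -- stepping -----------------------------------------------------------

    def step(self, action_a: int, action_b: int = 0) -> list:
        """Advance one frame; returns the events emitted on this frame.

        Actions are -1 (left), 0 (none), +1 (right).
        """
        cfg = self.config
        dt = 1.0 / cfg.tick_rate
        step_px = cfg.paddle_speed * dt
        lo, hi = cfg.paddle_bounds()
        px = self.paddle_x
        if action_a:
            x = px["A"] + action_a * step_px
            px["A"] = lo if x < lo else (hi if x > hi else x)
        if action_b and not self.solo:
            x = px["B"] + action_b * step_px
            px["B"] = lo if x < lo else (hi if x > hi else x)

        frame_events: list[GameEvent] = []
        left, right = cfg.left_bound, cfg.right_bound
        pad_y = cfg.paddle_y
        reach = cfg.paddle_width / 2.0 + cfg.ball_radius
        bottom = cfg.frame_height
        t_s = (self.t + 1) * dt
        separate = self.condition == "separate"

        for ball in self.balls:
            if not ball.alive:
                continue
            y0 = ball.y
            x = ball.x + ball.vx * dt
            y = y0 + ball.vy * dt
            # side-wall reflection (at most one per frame at game speeds)
            if x < left:
                x = 2.0 * left - x
                ball.vx = -ball.vx
            elif x > right:
                x = 2.0 * right - x
                ball.vx = -ball.vx
            if ball.vy > 0.0 and y0 <= pad_y < y:
                # descending ball crosses the paddle line this frame
                if separate:
                    hitters = ()
                    owner = "A" if ball.color == "red" else "B"
                    if abs(x - px[owner]) <= reach:
                        hitters = (owner,)
                else:
                    a_hit = abs(x - px["A"]) <= reach
                    b_hit = False if self.solo else abs(x - px["B"]) <= reach
                    hitters = (("A",) if a_hit else ()) + (("B",) if b_hit else ())
                if hitters:
                    y = 2.0 * pad_y - y
                    ball.vy = -ball.vy
                    ev = GameEvent(t_s, "hit", ball.ball_id, hitters)
                    frame_events.append(ev)
                    self._credit_hit(hitters)
            if y >= bottom:
                ball.alive = False
                owner = ("A" if ball.color == "red" else "B") if separate else "team"
                ev = GameEvent(t_s, "miss", ball.ball_id, (owner,))
                frame_events.append(ev)
                self.misses[owner] += 1.0
                self.pending.append((self.t + 1 + int(cfg.respawn_delay_s * cfg.tick_rate),
                                     ball.color, ball))
            elif y < 0.0 and ball.vy < 0.0:
                # rebounded ball leaves the top: re-enters as a new descent
                self._launch(ball)
                continue
            else:
                ball.x = x
                ball.y = y

        if self.pending:
            due = [p for p in self.pending if p[0] <= self.t + 1]
            if due:
                self.pending = [p for p in self.pending if p[0] > self.t + 1]
                for _, color, ball in due:
                    self._launch(ball)

        self.t += 1
        self.events.extend(frame_events)
        return frame_events

    def _credit_hit(self, hitters: tuple) -> None:
        share = 1.0 / len(hitters)
        cond = self.condition
        if cond == "collaborative":
            self.scores["team"] += 1.0
            self.hits["team"] += 1.0
        elif cond == "competitive":
            for p in hitters:
                self.scores[p] += share
            self.hits["team"] += 1.0
        else:
            for p in hitters:
                self.scores[p] += share
                self.hits[p] += share

    def censored_count(self) -> int:
        return sum(1 for b in self.balls if b.alive and b.vy > 0.0)


def credit_hit(condition: str, overlap: Sequence[str]) -> dict:
    """Score deltas for a hit by the players in ``overlap``.

    Separate and competitive conditions credit individual scores (split
    equally on a simultaneous hit); the collaborative condition credits
    the shared team score with a single point regardless of who hit.
    """
    hitters = tuple(overlap)
    if not hitters or any(p not in ("A", "B") for p in hitters):
        raise ValueError(f"invalid overlap set {overlap!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    deltas = {"A": 0.0, "B": 0.0, "team": 0.0}
    if condition == "collaborative":
        deltas["team"] = 1.0
    else:
        for p in hitters:
            deltas[p] += 1.0 / len(hitters)
    return deltas


def step_game(state: GameState, actions: dict, config: GameConfig | None = None) -> list:
    """Advance ``state`` one frame under per-player symbolic actions.

    ``actions`` maps player ids to ``"left" | "right" | "none"``.
    Returns the events emitted on this frame.  Thin validated wrapper
    over :meth:`GameState.step`, which takes -1/0/+1 action codes.
    """
    if config is not None and config is not state.config:
        raise ValueError("config does not match the one the state was built with")
    codes = {}
    for player in ("A", "B"):
        sym = actions.get(player, "none")
        if sym not in ACTION_CODES:
            raise ValueError(f"malformed action symbol {sym!r} for player {player}")
        codes[player] = ACTION_CODES[sym]
    return state.step(codes["A"], codes["B"])


# ---------------------------------------------------------------------------
# trial logs
# ---------------------------------------------------------------------------

@dataclass
class TrialLog:
    """Frame-by-frame record of one trial plus its event stream."""

    trial_id: str
    condition: str
    workload: str | int
    workload_balls: int
    seed: int
    config_digest: str
    xA: np.ndarray
    xB: np.ndarray | None
    ball_frames: list | None  # per-frame list of ball dicts, or None
    events: list
    scores: dict
    hits: dict
    misses: dict
    n_spawned: int
    n_censored: int
    drt: dict

    @property
    def n_frames(self) -> int:
        return 0 if self.xA is None else len(self.xA)

    def unit_counts(self, unit: str) -> tuple:
        """(hits, misses) for a processing unit ('A', 'B' or 'team')."""
        return self.hits[unit], self.misses[unit]

    def event_counts(self) -> dict:
        out = {k: 0 for k in _EVENT_KINDS}
        for ev in self.events:
            out[ev.kind] += 1
        return out

    def __eq__(self, other):
        if not isinstance(other, TrialLog):
            return NotImplemented
        same_xb = ((self.xB is None and other.xB is None)
                   or (self.xB is not None and other.xB is not None
                       and np.array_equal(self.xB, other.xB)))
        return (self.trial_id == other.trial_id
                and self.condition == other.condition
                and str(self.workload) == str(other.workload)
                and self.workload_balls == other.workload_balls
                and self.seed == other.seed
                and self.config_digest == other.config_digest
                and np.array_equal(self.xA, other.xA)
                and same_xb
                and self.ball_frames == other.ball_frames
                and self.events == other.events
                and self.scores == other.scores
                and self.hits == other.hits
                and self.misses == other.misses
                and self.n_spawned == other.n_spawned
                and self.n_censored == other.n_censored
                and self.drt == other.drt)


def run_trial(policy_a, policy_b, condition: str, workload, config: GameConfig,
              seed: int, record: str = "positions", trial_id: str = "trial") -> TrialLog:
    """Simulate one 45-s trial and return its :class:`TrialLog`.

    ``policy_b`` may be ``None`` for a solo run (one paddle playing its
    own balls; only meaningful with ``condition='separate'``).
    ``record`` controls frame logging: ``"full"`` stores ball states for
    every frame, ``"positions"`` stores paddle traces only, ``"none"``
    stores neither (events and counters are always kept).
    """
    if record not in ("full", "positions", "none"):
        raise ValueError(f"unknown record mode {record!r}")
    solo = policy_b is None
    if solo and condition != "separate":
        raise ValueError("solo trials are only defined for the separate condition")
    rng = random.Random(seed)
    state = GameState(config, condition, workload, rng, solo=solo)
    n_frames = config.n_frames

    policy_a.reset("A", condition, config, rng.randrange(2 ** 31))
    if not solo:
        policy_b.reset("B", condition, config, rng.randrange(2 ** 31))
    ep_a = getattr(policy_a, "decision_epoch", 1)
    ep_b = 1 if solo else getattr(policy_b, "decision_epoch", 1)

    drt_events, drt_summary = _schedule_drt(
        config, rng.randrange(2 ** 31),
        {"A": getattr(policy_a, "drt_accuracy", None),
         "B": None if solo else getattr(policy_b, "drt_accuracy", None)})
    drt_iter = iter(drt_events + [None])
    next_drt = next(drt_iter)

    keep_pos = record in ("full", "positions")
    xA = np.empty(n_frames) if keep_pos else None
    xB = np.empty(n_frames) if (keep_pos and not solo) else None
    ball_frames = [] if record == "full" else None

    act_a = policy_a.act
    act_b = None if solo else policy_b.act
    a = b = 0
    for t in range(n_frames):
        if t % ep_a == 0:
            a = act_a(state, "A")
        if act_b is not None and t % ep_b == 0:
            b = act_b(state, "B")
        state.step(a, b)
        while next_drt is not None and next_drt.t <= state.t / config.tick_rate:
            state.events.append(next_drt)
            next_drt = next(drt_iter)
        if keep_pos:
            xA[t] = state.paddle_x["A"]
            if xB is not None:
                xB[t] = state.paddle_x["B"]
        if ball_frames is not None:
            ball_frames.append([bl.as_dict() for bl in state.balls if bl.alive])

    state.events.sort(key=lambda ev: (ev.t, _EVENT_KINDS.index(ev.kind)))
    return TrialLog(
        trial_id=trial_id, condition=condition, workload=workload,
        workload_balls=state.n_balls, seed=seed, config_digest=config.digest(),
        xA=xA, xB=xB, ball_frames=ball_frames, events=list(state.events),
        scores=dict(state.scores), hits=dict(state.hits),
        misses=dict(state.misses), n_spawned=state.n_spawned,
        n_censored=state.censored_count(), drt=drt_summary)


def _schedule_drt(config: GameConfig, seed: int, accuracies: dict) -> tuple:
    """DRT onsets (uniform 3-5 s ISI) and probabilistic responses.

    Responses land within the 2.5-s window with each player's hit
    probability; the DRT stream is logged but not analysed beyond the
    per-player accuracy used by the exclusion rule.
    """
    rng = random.Random(seed)
    lo, hi = config.drt_isi_range_s
    events = []
    summary = {p: {"onsets": 0, "responses": 0, "accuracy": None}
               for p, acc in accuracies.items() if acc is not None}
    t = rng.uniform(lo, hi)
    while t < config.trial_duration:
        events.append(GameEvent(round(t, 6), "drt_onset", None, ()))
        for p, acc in accuracies.items():
            if acc is None:
                continue
            summary[p]["onsets"] += 1
            if rng.random() < acc:
                rt = rng.uniform(0.25, config.drt_window_s * 0.9)
                if t + rt < config.trial_duration:
                    events.append(GameEvent(round(t + rt, 6), "drt_response", None, (p,)))
                    summary[p]["responses"] += 1
        t += rng.uniform(lo, hi)
    for p in summary:
        n = summary[p]["onsets"]
        summary[p]["accuracy"] = summary[p]["responses"] / n if n else None
    return events, summary


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

@dataclass
class DyadSpec:
    """One dyad's composition: two policies plus labelling metadata."""

    dyad_id: str
    team_type: str  # "HH" or "HM"
    policy_a: object
    policy_b: object
    block_order: tuple = ("separate", "collaborative", "competitive")
    agent_specs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.team_type not in ("HH", "HM"):
            raise ValueError("team_type must be 'HH' or 'HM'")
        if sorted(self.block_order) != sorted(CONDITIONS):
            raise ValueError("block_order must be a permutation of the three conditions")


@dataclass
class DyadRecord:
    """A dyad's full session: 3 blocks x 12 trials with labels."""

    dyad_id: str
    team_type: str
    block_order: tuple
    trials: list
    agent_specs: dict
    seed: int


def run_session(dyad_spec: DyadSpec, config: GameConfig, seed: int,
                record: str = "positions") -> DyadRecord:
    """Simulate a full 36-trial session (3 blocks x 12 trials).

    Each block runs one group condition and presents every workload
    level three times in seeded-random order.
    """
    rng = random.Random(seed)
    trials = []
    for b_idx, condition in enumerate(dyad_spec.block_order):
        order = [w for w in WORKLOAD_NAMES for _ in range(3)]
        rng.shuffle(order)
        for t_idx, workload in enumerate(order):
            trial_seed = rng.randrange(2 ** 31)
            tid = f"{dyad_spec.dyad_id}-b{b_idx}-t{t_idx}"
            trials.append(run_trial(dyad_spec.policy_a, dyad_spec.policy_b,
                                    condition, workload, config, trial_seed,
                                    record=record, trial_id=tid))
    return DyadRecord(dyad_id=dyad_spec.dyad_id, team_type=dyad_spec.team_type,
                      block_order=tuple(dyad_spec.block_order), trials=trials,
                      agent_specs=dict(dyad_spec.agent_specs), seed=seed)


# ---------------------------------------------------------------------------
# trial-log serialisation (JSON Lines)
# ---------------------------------------------------------------------------

_HEADER_FIELDS = ("trial_id", "condition", "workload", "workload_balls",
                  "seed", "config_digest")


def write_trial_log(log: TrialLog, path, tick_rate: int = 60) -> None:
    """Write a TrialLog as JSON Lines.

    Line 1 is a header object; subsequent lines are frame records
    ``{"t": ..., "xA": ..., "xB": ..., "balls": [...]}`` interleaved
    (by time) with event records ``{"t": ..., "kind": ..., ...}``.
    Event times are seconds; frame records carry their frame index.
    """
    with open(path, "w") as fh:
        header = {k: getattr(log, k) for k in _HEADER_FIELDS}
        header.update({"scores": log.scores, "hits": log.hits,
                       "misses": log.misses, "n_spawned": log.n_spawned,
                       "n_censored": log.n_censored, "drt": log.drt,
                       "tick_rate": tick_rate,
                       "record": ("full" if log.ball_frames is not None
                                  else ("positions" if log.xA is not None else "none"))})
        fh.write(json.dumps(header) + "\n")
        ev_iter = iter(log.events + [None])
        ev = next(ev_iter)
        n = log.n_frames if log.xA is not None else 0
        for t in range(n):
            while ev is not None and ev.t <= (t + 1) / tick_rate:
                fh.write(json.dumps({"t": ev.t, "kind": ev.kind,
                                     "ball_id": ev.ball_id,
                                     "players": list(ev.players)}) + "\n")
                ev = next(ev_iter)
            rec = {"t": t, "xA": log.xA[t]}
            if log.xB is not None:
                rec["xB"] = log.xB[t]
            if log.ball_frames is not None:
                rec["balls"] = log.ball_frames[t]
            fh.write(json.dumps(rec) + "\n")
        while ev is not None:
            fh.write(json.dumps({"t": ev.t, "kind": ev.kind,
                                 "ball_id": ev.ball_id,
                                 "players": list(ev.players)}) + "\n")
            ev = next(ev_iter)


class TrialLogParseError(ValueError):
    """Raised when a trial-log file violates the JSON-Lines schema."""


def read_trial_log(path) -> TrialLog:
    """Read a JSON-Lines trial log written by :func:`write_trial_log`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise TrialLogParseError("empty file: missing header line")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise TrialLogParseError(f"unparseable header line: {exc}") from None
    for k in _HEADER_FIELDS + ("record",):
        if k not in header:
            raise TrialLogParseError(f"header missing field {k!r}")
    frames, events = [], []
    for i, line in enumerate(lines[1:], start=2):
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise TrialLogParseError(f"line {i}: unparseable record: {exc}") from None
        if "kind" in rec:
            for k in ("t", "kind"):
                if k not in rec:
                    raise TrialLogParseError(f"line {i}: event missing field {k!r}")
            events.append(GameEvent(rec["t"], rec["kind"], rec.get("ball_id"),
                                    tuple(rec.get("players", []))))
        else:
            for k in ("t", "xA"):
                if k not in rec:
                    raise TrialLogParseError(f"line {i}: frame missing field {k!r}")
            frames.append(rec)
    record = header["record"]
    if record == "none":
        xA = xB = ball_frames = None
    else:
        xA = np.array([f["xA"] for f in frames])
        xB = (np.array([f["xB"] for f in frames])
              if frames and "xB" in frames[0] else None)
        ball_frames = [f["balls"] for f in frames] if record == "full" else None
    return TrialLog(
        trial_id=header["trial_id"], condition=header["condition"],
        workload=header["workload"], workload_balls=header["workload_balls"],
        seed=header["seed"], config_digest=header["config_digest"],
        xA=xA, xB=xB, ball_frames=ball_frames, events=events,
        scores=header["scores"], hits=header["hits"], misses=header["misses"],
        n_spawned=header["n_spawned"], n_censored=header["n_censored"],
        drt=header["drt"])
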