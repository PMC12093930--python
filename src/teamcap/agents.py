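"""Machine-agent and human-surrogate policies for the paddle game.

Three machine-agent designs are provided:

* a tabular Q-learning agent trained with hits as reward,
* a *simple ideal observer* that acts on analytically computed ball
  floor-intercept points and times until interception, and
* a *considerate ideal observer* that additionally avoids balls headed
  for the partner's position in the collaborative condition.

A parameterised noisy human surrogate (ideal-observer core plus
condition-dependent strategy biases) stands in for human players in
synthetic cohorts.  ``calibrate_policy`` tunes a single noise scalar so
that a policy's solo miss rates match target values at the low and
very-high workload levels; the study's agents were tuned to human-like
averages of 0.05 and 0.65.

All policies share one interface: ``reset(player_id, condition, config,
seed)`` then ``act(state, player_id) -> -1 | 0 | +1`` (left / none /
right).  Policies re-decide every ``decision_epoch`` frames (default 5,
~83 ms at 60 Hz) and can queue decisions through a reaction delay.
"""

from __future__ import annotations

import math
import random
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .simulator import GameConfig, GameState, run_trial

POLICY_KINDS = ("q_learning", "ideal_observer_simple",
                "ideal_observer_considerate", "human_surrogate")

DECISION_EPOCH = 5  # frames between decisions (~83 ms at 60 Hz)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class PolicySpec:
    """Serializable description of a policy: kind + parameters + seed."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in POLICY_KINDS:
            raise ValueError(f"unknown policy kind {self.kind!r}")
        for key in ("lapse_prob", "share_bias", "monitor_weight", "drt_accuracy"):
            v = self.params.get(key)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{key} must lie in [0, 1], got {v}")
        for key in ("reaction_delay_s", "motor_noise_px"):
            v = self.params.get(key)
            if v is not None and v < 0:
                raise ValueError(f"{key} must be >= 0, got {v}")


@dataclass
class CalibrationTarget:
    """Solo miss rates the calibration must reach at two workloads."""

    workload_low_missrate: float = 0.05
    workload_veryhigh_missrate: float = 0.65
    tolerance: float = 0.02
    n_trials: int = 300

    def __post_init__(self):
        if not (0 <= self.workload_low_missrate <= 1
                and 0 <= self.workload_veryhigh_missrate <= 1):
            raise ValueError("target miss rates must lie in [0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


# ---------------------------------------------------------------------------
# intercept geometry
# ---------------------------------------------------------------------------

def floor_intercept(x, y, vx, vy, config: GameConfig):
    """Analytic (x, time) where a descending ball meets the paddle line.

    Linear extrapolation with elastic side-wall reflections, computed by
    unfolding: the free-flight abscissa is folded into the playable span
    by reflecting at the walls.  Returns ``(intercept_x,
    time_to_floor)``; requires ``vy > 0``.
    """
    if vy <= 0:
        raise ValueError("ball is not descending")
    tf = (config.paddle_y - y) / vy
    raw = x + vx * tf
    left, right = config.left_bound, config.right_bound
    width = right - left
    m = (raw - left) % (2.0 * width)
    ix = (left + m) if m <= width else (left + 2.0 * width - m)
    return ix, tf


# ---------------------------------------------------------------------------
# ideal observers
# ---------------------------------------------------------------------------

class IdealObserverPolicy:
    """Targets the soonest-landing ball and steers to its intercept.

    Per decision epoch the policy extrapolates every eligible descending
    ball to the paddle line and steers toward the intercept of the one
    with minimum time-to-floor.  With ``triage=True`` it first restricts
    attention to balls still reachable in time
    (|intercept - paddle| <= paddle_speed * time_to_floor + paddle_width/2)
    and only chases unreachable balls when nothing else is in the air;
    the default (no triage) commits to the soonest ball regardless,
    which yields the human-like error pattern across workloads.
    Noise enters as a Gaussian aim error (resampled when the target
    changes), episodic attentional lapses (no action for
    ``lapse_duration_s``, triggered with ``lapse_prob`` per decision),
    and a reaction delay applied to emitted decisions.
    """

    kind = "ideal_observer_simple"

    def __init__(self, reaction_delay_s=0.15, motor_noise_px=0.0,
                 lapse_prob=0.0, lapse_duration_s=0.0, triage=False,
                 decision_epoch=DECISION_EPOCH):
        if motor_noise_px < 0 or reaction_delay_s < 0 or lapse_duration_s < 0:
            raise ValueError("noise, delay and lapse duration must be >= 0")
        if not 0.0 <= lapse_prob <= 1.0:
            raise ValueError("lapse_prob must lie in [0, 1]")
        self.reaction_delay_s = reaction_delay_s
        self.motor_noise_px = motor_noise_px
        self.lapse_prob = lapse_prob
        self.lapse_duration_s = lapse_duration_s
        self.triage = triage
        self.decision_epoch = decision_epoch

    def params(self) -> dict:
        return {"reaction_delay_s": self.reaction_delay_s,
                "motor_noise_px": self.motor_noise_px,
                "lapse_prob": self.lapse_prob,
                "lapse_duration_s": self.lapse_duration_s}

    def reset(self, player_id, condition, config: GameConfig, seed):
        self.rng = random.Random(seed)
        self.condition = condition
        self.config = config
        self._own_color = "red" if player_id == "A" else "blue"
        self._deadband = (config.paddle_speed * self.decision_epoch
                          / config.tick_rate / 2.0)
        delay_epochs = int(round(self.reaction_delay_s * config.tick_rate
                                 / self.decision_epoch))
        self._queue = deque([0] * delay_epochs)
        self._last_target = None
        self._aim_err = 0.0
        self._decision = 0
        self._lapse_until = 0
        # a lapse freezes the policy for at least one decision epoch
        self._lapse_epochs = max(1, int(round(self.lapse_duration_s
                                              * config.tick_rate
                                              / self.decision_epoch)))

    # candidate = (time_to_floor, intercept_x, ball_id, interceptable)
    def _candidates(self, state: GameState, own_x):
        cfg = self.config
        separate = state.condition == "separate"
        reach0 = cfg.paddle_width / 2.0
        speed = cfg.paddle_speed
        out = []
        for b in state.balls:
            if not b.alive or b.vy <= 0.0:
                continue
            if separate and b.color != self._own_color:
                continue
            ix, tf = floor_intercept(b.x, b.y, b.vx, b.vy, cfg)
            ok = abs(ix - own_x) <= speed * tf + reach0
            out.append((tf, ix, b.ball_id, ok))
        return out

    def _select_target(self, cands, own_x, partner_x):
        """Pick (tf, ix, ball_id) from candidates; None if empty."""
        if self.triage:
            cands = [c for c in cands if c[3]] or cands
        return min(cands) if cands else None

    def _aim_bias(self, aim, partner_x):
        return aim

    def act(self, state: GameState, player_id) -> int:
        decided = 0
        self._decision += 1
        lapsed = self._decision <= self._lapse_until
        if not lapsed and self.lapse_prob and self.rng.random() < self.lapse_prob:
            lapsed = True
            self._lapse_until = self._decision + self._lapse_epochs - 1
        if lapsed:
            self._last_target = None
        else:
            # steer from the position the paddle will occupy once the
            # already-queued (delayed) decisions have played out, else a
            # bang-bang controller with delay limit-cycles around the aim
            step_px = (self.config.paddle_speed * self.decision_epoch
                       / self.config.tick_rate)
            own_x = state.paddle_x[player_id] + step_px * sum(self._queue)
            partner_x = state.paddle_x["B" if player_id == "A" else "A"]
            cands = self._candidates(state, own_x)
            target = self._select_target(cands, own_x, partner_x)
            if target is not None:
                tf, ix, ball_id = target[0], target[1], target[2]
                if ball_id != self._last_target:
                    self._last_target = ball_id
                    self._aim_err = (self.rng.gauss(0.0, self.motor_noise_px)
                                     if self.motor_noise_px else 0.0)
                aim = self._aim_bias(ix + self._aim_err, partner_x)
                dx = aim - own_x
                if abs(dx) > self._deadband:
                    decided = 1 if dx > 0 else -1
            else:
                self._last_target = None
        self._queue.append(decided)
        return self._queue.popleft()


class ConsideratePolicy(IdealObserverPolicy):
    """Ideal observer that yields the partner's space when collaborating.

    In the collaborative condition, balls whose floor intercept falls
    within ``avoid_radius`` of the partner's current paddle position are
    deprioritised: they are targeted only when no other interceptable
    ball exists.  Outside the collaborative condition the policy is
    identical to the simple ideal observer.
    """

    kind = "ideal_observer_considerate"

    def __init__(self, avoid_radius_px=100.0, **kw):
        super().__init__(**kw)
        if avoid_radius_px < 0:
            raise ValueError("avoid_radius_px must be >= 0")
        self.avoid_radius_px = avoid_radius_px

    def params(self) -> dict:
        d = super().params()
        d["avoid_radius_px"] = self.avoid_radius_px
        return d

    def _select_target(self, cands, own_x, partner_x):
        if self.condition != "collaborative" or not cands:
            return super()._select_target(cands, own_x, partner_x)
        preferred = [c for c in cands if abs(c[1] - partner_x) > self.avoid_radius_px]
        return super()._select_target(preferred, own_x, partner_x) \
            or super()._select_target(cands, own_x, partner_x)


class HumanSurrogatePolicy(IdealObserverPolicy):
    """Noisy ideal observer with human-like team-strategy biases.

    ``share_bias`` (collaborative condition) is the per-decision
    probability of restricting targets to the player's own half of the
    playable span while a ball is headed there — an even division of the
    workspace.  ``monitor_weight`` (competitive condition) blends the
    aim point toward the partner's paddle — opponent monitoring, which
    drags the player out of position and shrinks paddle separation.
    With both at 0 this is exactly the noisy simple ideal observer.
    ``drt_accuracy`` is the probability of answering a DRT stimulus.
    """

    kind = "human_surrogate"

    def __init__(self, share_bias=0.0, monitor_weight=0.0, drt_accuracy=0.9,
                 **kw):
        super().__init__(**kw)
        for name, v in (("share_bias", share_bias),
                        ("monitor_weight", monitor_weight),
                        ("drt_accuracy", drt_accuracy)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        self.share_bias = share_bias
        self.monitor_weight = monitor_weight
        self.drt_accuracy = drt_accuracy

    def params(self) -> dict:
        d = super().params()
        d.update(share_bias=self.share_bias, monitor_weight=self.monitor_weight,
                 drt_accuracy=self.drt_accuracy)
        return d

    def reset(self, player_id, condition, config, seed):
        super().reset(player_id, condition, config, seed)
        self._own_half_left = player_id == "A"
        self._mid = 0.5 * (config.left_bound + config.right_bound)

    def _select_target(self, cands, own_x, partner_x):
        if (self.condition == "collaborative" and self.share_bias > 0.0 and cands
                and (self.share_bias >= 1.0
                     or self.rng.random() < self.share_bias)):
            own = [c for c in cands
                   if (c[1] < self._mid) == self._own_half_left]
            if own:
                cands = own
        return super()._select_target(cands, own_x, partner_x)

    def _aim_bias(self, aim, partner_x):
        if self.condition == "competitive" and self.monitor_weight > 0.0:
            return (1.0 - self.monitor_weight) * aim + self.monitor_weight * partner_x
        return aim


# ---------------------------------------------------------------------------
# Q-learning agent
# ---------------------------------------------------------------------------

_ACTIONS = (0, -1, 1)  # index order: none, left, right (argmax tie -> none)


@dataclass
class QTable:
    """Tabular Q over (paddle->ball offset bin, time-to-floor bin) x action."""

    q: np.ndarray
    offset_edges: np.ndarray
    tf_edges: np.ndarray

    @classmethod
    def zeros(cls, config: GameConfig, offset_bin_px=40.0, tf_bin_s=0.25,
              tf_max_s=5.0):
        span = config.playable_span
        offset_edges = np.arange(-span, span + offset_bin_px, offset_bin_px)
        tf_edges = np.arange(0.0, tf_max_s + tf_bin_s, tf_bin_s)
        q = np.zeros((len(offset_edges) - 1, len(tf_edges) - 1, len(_ACTIONS)))
        return cls(q, offset_edges, tf_edges)

    def state_index(self, offset, tf):
        i = int(np.searchsorted(self.offset_edges, offset, side="right")) - 1
        j = int(np.searchsorted(self.tf_edges, tf, side="right")) - 1
        i = min(max(i, 0), self.q.shape[0] - 1)
        j = min(max(j, 0), self.q.shape[1] - 1)
        return i, j

    def save(self, path_prefix):
        """Store as <prefix>.npy plus a JSON sidecar of bin edges."""
        import json
        np.save(f"{path_prefix}.npy", self.q)
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump({"offset_edges": self.offset_edges.tolist(),
                       "tf_edges": self.tf_edges.tolist()}, fh)

    @classmethod
    def load(cls, path_prefix):
        import json
        q = np.load(f"{path_prefix}.npy")
        with open(f"{path_prefix}.json") as fh:
            side = json.load(fh)
        return cls(q, np.asarray(side["offset_edges"]),
                   np.asarray(side["tf_edges"]))


class QLearningPolicy:
    """Greedy policy over a learned tabular Q (see :func:`q_agent_train`).

    The state is the signed horizontal offset from the paddle to the
    soonest-landing eligible ball (binned) crossed with that ball's
    time-to-floor (binned); with no descending ball the policy holds
    still.  Ties in Q favour "none".
    """

    kind = "q_learning"

    def __init__(self, table: QTable, decision_epoch=DECISION_EPOCH):
        self.table = table
        self.decision_epoch = decision_epoch

    def params(self) -> dict:
        return {"q_shape": list(self.table.q.shape)}

    def reset(self, player_id, condition, config, seed):
        self.condition = condition
        self.config = config
        self._own_color = "red" if player_id == "A" else "blue"

    def _observe(self, state: GameState, player_id):
        """(offset, tf) of the soonest-landing eligible descending ball."""
        own_x = state.paddle_x[player_id]
        separate = state.condition == "separate"
        best = None
        for b in state.balls:
            if not b.alive or b.vy <= 0.0:
                continue
            if separate and b.color != self._own_color:
                continue
            tf = (state.config.paddle_y - b.y) / b.vy
            if best is None or tf < best[0]:
                best = (tf, b.x - own_x)
        return best

    def act(self, state: GameState, player_id) -> int:
        obs = self._observe(state, player_id)
        if obs is None:
            return 0
        tf, offset = obs
        i, j = self.table.state_index(offset, tf)
        return _ACTIONS[int(np.argmax(self.table.q[i, j]))]


def q_update(q: np.ndarray, state_idx: tuple, action_idx: int, reward: float,
             next_state_idx: tuple | None, alpha: float, gamma: float) -> None:
    """One tabular Q-learning backup; ``next_state_idx=None`` is terminal."""
    future = 0.0 if next_state_idx is None else float(np.max(q[next_state_idx]))
    cell = state_idx + (action_idx,)
    q[cell] += alpha * (reward + gamma * future - q[cell])


@dataclass
class QTrainingResult:
    policy: QLearningPolicy
    episode_hits: list
    episode_misses: list
    hyperparams: dict


def q_agent_train(config: GameConfig, episodes: int, hyperparams: dict | None = None,
                  seed: int = 0, workload=1) -> QTrainingResult:
    """Train a tabular Q-learning paddle agent with hits as reward.

    Episodes are solo separate-condition trials at ``workload``.  Each
    decision epoch the agent observes the binned (offset, time-to-floor)
    state of the soonest-landing ball, picks an epsilon-greedy action,
    holds it for ``decision_epoch`` frames, and receives +1 reward per
    hit credited in that span.  Epsilon decays linearly across episodes.
    With ``episodes=0`` the returned greedy policy is all-"none"
    (zero-initialised table).
    """
    if episodes < 0:
        raise ValueError("episodes must be >= 0")
    hp = {"alpha": 0.1, "gamma": 0.95, "epsilon_start": 1.0,
          "epsilon_end": 0.05, "offset_bin_px": 40.0, "tf_bin_s": 0.25}
    if hyperparams:
        hp.update(hyperparams)
    table = QTable.zeros(config, hp["offset_bin_px"], hp["tf_bin_s"])
    policy = QLearningPolicy(table)
    rng = random.Random(seed)
    alpha, gamma = hp["alpha"], hp["gamma"]
    epoch = policy.decision_epoch
    n_frames = config.n_frames
    episode_hits, episode_misses = [], []
    q = table.q
    for ep in range(episodes):
        frac = ep / max(episodes - 1, 1)
        eps = hp["epsilon_start"] + (hp["epsilon_end"] - hp["epsilon_start"]) * frac
        state = GameState(config, "separate", workload,
                          random.Random(rng.randrange(2 ** 31)), solo=True)
        policy.reset("A", "separate", config, 0)
        prev = None  # (i, j, action_idx)
        t = 0
        while t < n_frames:
            obs = policy._observe(state, "A")
            if obs is None:
                sidx = None
                a_idx = 0
            else:
                tf, offset = obs
                sidx = table.state_index(offset, tf)
                if rng.random() < eps:
                    a_idx = rng.randrange(len(_ACTIONS))
                else:
                    a_idx = int(np.argmax(q[sidx]))
            reward = 0.0
            action = _ACTIONS[a_idx]
            for _ in range(epoch):
                if t >= n_frames:
                    break
                for ev in state.step(action, 0):
                    if ev.kind == "hit":
                        reward += 1.0
                t += 1
            if prev is not None:
                pi, pj, pa = prev
                q_update(q, (pi, pj), pa, prev_reward, sidx, alpha, gamma)
            if sidx is not None:
                prev = (sidx[0], sidx[1], a_idx)
                prev_reward = reward
            else:
                prev = None
        if prev is not None:  # terminal: no bootstrap past the trial end
            pi, pj, pa = prev
            q_update(q, (pi, pj), pa, prev_reward, None, alpha, gamma)
        episode_hits.append(state.hits["A"])
        episode_misses.append(state.misses["A"])
    return QTrainingResult(policy, episode_hits, episode_misses, hp)


# ---------------------------------------------------------------------------
# factory
# ---------------------------------------------------------------------------

def build_policy(spec: PolicySpec, config: GameConfig | None = None):
    """Instantiate a policy object from a :class:`PolicySpec`.

    ``q_learning`` specs accept either a ``table`` (a :class:`QTable`)
    or training parameters (``episodes`` etc.), in which case a fresh
    agent is trained with the spec's seed.
    """
    params = dict(spec.params)
    if spec.kind == "ideal_observer_simple":
        return IdealObserverPolicy(**params)
    if spec.kind == "ideal_observer_considerate":
        return ConsideratePolicy(**params)
    if spec.kind == "human_surrogate":
        return HumanSurrogatePolicy(**params)
    if spec.kind == "q_learning":
        table = params.pop("table", None)
        if table is not None:
            return QLearningPolicy(table)
        if config is None:
            raise ValueError("training a q_learning policy needs a GameConfig")
        episodes = params.pop("episodes", 500)
        return q_agent_train(config, episodes, params or None, seed=spec.seed).policy
    raise ValueError(f"unknown policy kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# solo evaluation and calibration
# ---------------------------------------------------------------------------

def solo_miss_rate(policy, workload, config: GameConfig, n_trials: int,
                   seed: int):
    """Pooled solo miss rate over ``n_trials`` separate-condition trials.

    Returns ``(rate, mc_se, n_balls)`` where ``mc_se`` is the standard
    error of the mean of per-trial miss rates.
    """
    rng = random.Random(seed)
    hits = misses = 0.0
    per_trial = []
    for _ in range(n_trials):
        log = run_trial(policy, None, "separate", workload, config,
                        rng.randrange(2 ** 31), record="none")
        h, m = log.unit_counts("A")
        hits += h
        misses += m
        if h + m > 0:
            per_trial.append(m / (h + m))
    if hits + misses == 0:
        raise ValueError("no terminated balls across all trials")
    rate = misses / (hits + misses)
    se = (float(np.std(per_trial, ddof=1)) / math.sqrt(len(per_trial))
          if len(per_trial) > 1 else float("nan"))
    return rate, se, hits + misses


# base scales multiplied by the calibration noise scalar; the ratio sets
# how much of the induced error is aim scatter vs. attentional lapse.
# Lapses are episodic (~0.5 s): cheap to recover from with one slow ball,
# costly when balls land every few hundred ms, which is what lets a single
# scalar reach a low-workload rate near 0.05 and a very-high rate near 0.65.
_NOISE_SCALE_PX = 15.0
_LAPSE_SCALE = 0.065
_LAPSE_DURATION_S = 0.5


@dataclass
class CalibrationResult:
    params: dict
    noise_scalar: float
    achieved_low: float
    achieved_veryhigh: float
    se_low: float
    se_veryhigh: float
    converged: bool
    probes: list  # (scalar, miss_low, miss_veryhigh)

    def within(self, target: CalibrationTarget) -> bool:
        return (abs(self.achieved_low - target.workload_low_missrate)
                <= target.tolerance
                and abs(self.achieved_veryhigh - target.workload_veryhigh_missrate)
                <= target.tolerance)


class CalibrationError(RuntimeError):
    """Raised when the target band cannot be bracketed; carries probes."""

    def __init__(self, message, probes):
        super().__init__(message)
        self.probes = probes


def _policy_for_scalar(kind, scalar, extra=None):
    params = {"motor_noise_px": _NOISE_SCALE_PX * scalar,
              "lapse_prob": min(1.0, _LAPSE_SCALE * scalar),
              "lapse_duration_s": _LAPSE_DURATION_S}
    if extra:
        params.update(extra)
    spec = PolicySpec(kind, params)
    return build_policy(spec)


def calibrate_policy(kind: str, target: CalibrationTarget, config: GameConfig,
                     seed: int, scalar_hi: float = 4.0,
                     extra_params: dict | None = None) -> CalibrationResult:
    """Fit a single noise scalar so solo miss rates hit the target band.

    The scalar jointly scales the Gaussian aim noise (60 px per unit)
    and the per-decision lapse probability (0.06 per unit).  Solo miss
    rates are monotone in the scalar, so a bisection on the mean of the
    two target discrepancies converges; common random numbers (the same
    trial seeds at every probe) keep the probe curve smooth.  Raises
    :class:`CalibrationError` with the probe curve when the target is
    not bracketed between scalar 0 and ``scalar_hi``.
    """
    if kind == "q_learning":
        raise ValueError("calibration by noise scalar applies to "
                         "observer-based policies only")
    n = target.n_trials
    t_low, t_vh = target.workload_low_missrate, target.workload_veryhigh_missrate

    probes = []

    def discrepancy(scalar):
        pol = _policy_for_scalar(kind, scalar, extra_params)
        lo, se_lo, _ = solo_miss_rate(pol, "low", config, n, seed)
        vh, se_vh, _ = solo_miss_rate(pol, "very_high", config, n, seed + 1)
        probes.append((scalar, lo, vh))
        return 0.5 * ((lo - t_low) + (vh - t_vh)), (lo, vh, se_lo, se_vh)

    f_lo, _ = discrepancy(0.0)
    if f_lo > 0:
        raise CalibrationError(
            "targets unreachable: noiseless policy already misses more "
            "than the target band", probes)
    f_hi, _ = discrepancy(scalar_hi)
    if f_hi < 0:
        raise CalibrationError(
            f"targets unreachable: scalar {scalar_hi} still under-shoots "
            "the target band", probes)

    a, b = 0.0, scalar_hi
    fa = f_lo
    best = None
    for _ in range(12):
        mid = 0.5 * (a + b)
        fm, rates = discrepancy(mid)
        best = (mid, rates)
        if abs(fm) <= target.tolerance / 4:
            break
        if (fm < 0) == (fa < 0):
            a, fa = mid, fm
        else:
            b = mid
    scalar, (lo, vh, se_lo, se_vh) = best
    pol = _policy_for_scalar(kind, scalar, extra_params)
    result = CalibrationResult(
        params=pol.params(), noise_scalar=scalar, achieved_low=lo,
        achieved_veryhigh=vh, se_low=se_lo, se_veryhigh=se_vh,
        converged=True, probes=probes)
    result.converged = result.within(target)
    return result
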