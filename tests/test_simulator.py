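"""Game-engine behaviour: collisions, scoring, determinism, logging."""

import math
import random

import numpy as np
import pytest

from teamcap import (GameConfig, GameState, IdealObserverPolicy, DyadSpec,
                     credit_hit, step_game, run_trial, run_session,
                     write_trial_log, read_trial_log, TrialLogParseError,
                     HumanSurrogatePolicy)


def make_state(config, condition="separate", workload="low", seed=0, solo=True):
    return GameState(config, condition, workload, random.Random(seed), solo=solo)


# ---------------------------------------------------------------------------
# stepping and collisions
# ---------------------------------------------------------------------------

def test_paddle_clamped_at_playable_bounds(config):
    state = make_state(config)
    lo, hi = config.paddle_bounds()
    state.paddle_x["A"] = lo
    step_game(state, {"A": "left"})
    assert state.paddle_x["A"] == lo
    state.paddle_x["A"] = hi
    step_game(state, {"A": "right"})
    assert state.paddle_x["A"] == hi
    # interior movement covers one frame's distance
    state.paddle_x["A"] = 400.0
    step_game(state, {"A": "right"})
    assert state.paddle_x["A"] == pytest.approx(400.0 + config.paddle_speed
                                                / config.tick_rate)


def test_descending_ball_rebounds_off_overlapping_paddle(config):
    state = make_state(config)
    ball = state.balls[0]
    ball.x, ball.y = state.paddle_x["A"], config.paddle_y - 1.0
    ball.vx, ball.vy = 0.0, 300.0
    events = state.step(0)
    assert [ev.kind for ev in events] == ["hit"]
    assert events[0].players == ("A",)
    assert ball.vy == -300.0
    assert state.hits["A"] == 1.0
    assert state.scores["A"] == 1.0


def test_other_colored_ball_passes_through_paddle(config):
    """In the separate condition a teammate's ball is transparent."""
    state = make_state(config, solo=False)
    blue = next(b for b in state.balls if b.color == "blue")
    blue.x, blue.y = state.paddle_x["A"], config.paddle_y - 1.0
    blue.vx, blue.vy = 0.0, 300.0
    # park the blue paddle far away so only pass-through is possible
    state.paddle_x["B"] = config.paddle_bounds()[1]
    events = state.step(0, 0)
    assert not [ev for ev in events if ev.kind == "hit"]
    assert blue.alive and blue.y > config.paddle_y and blue.vy > 0


@pytest.mark.parametrize("condition,overlap,expected", [
    ("collaborative", ("A",), {"A": 0.0, "B": 0.0, "team": 1.0}),
    ("collaborative", ("A", "B"), {"A": 0.0, "B": 0.0, "team": 1.0}),
    ("competitive", ("A", "B"), {"A": 0.5, "B": 0.5, "team": 0.0}),
    ("separate", ("B",), {"A": 0.0, "B": 1.0, "team": 0.0}),
])
def test_hit_credit_rules(condition, overlap, expected):
    assert credit_hit(condition, overlap) == expected


def test_credit_hit_rejects_bad_input():
    with pytest.raises(ValueError):
        credit_hit("collaborative", ())
    with pytest.raises(ValueError):
        credit_hit("collaborative", ("C",))
    with pytest.raises(ValueError):
        credit_hit("solo", ("A",))


def test_step_game_rejects_malformed_action(config):
    state = make_state(config)
    with pytest.raises(ValueError, match="malformed action"):
        step_game(state, {"A": "up"})


def test_simultaneous_hit_split_in_competitive(config):
    state = make_state(config, condition="competitive", solo=False)
    ball = state.balls[0]
    state.paddle_x["A"] = 400.0
    state.paddle_x["B"] = 400.0
    ball.x, ball.y, ball.vx, ball.vy = 400.0, config.paddle_y - 1.0, 0.0, 300.0
    events = state.step(0, 0)
    hits = [ev for ev in events if ev.kind == "hit"]
    assert len(hits) == 1 and set(hits[0].players) == {"A", "B"}
    assert state.scores["A"] == state.scores["B"] == 0.5
    assert state.hits["team"] == 1.0


def test_stationary_player_misses_far_ball_on_schedule(config, stationary):
    """A ball dropped far from a motionless paddle produces exactly one
    miss, on the frame the hand calculation predicts."""
    state = make_state(config)
    ball = state.balls[0]
    ball.x, ball.y, ball.vx, ball.vy = 700.0, 0.0, 0.0, 300.0
    state.paddle_x["A"] = 100.0
    dt = 1.0 / config.tick_rate
    # bottom-edge crossing (y >= height) first holds on this frame
    expected_frame = math.ceil(config.frame_height / (300.0 * dt))
    misses = []
    for t in range(expected_frame + 10):
        misses += [ev for ev in state.step(0) if ev.kind == "miss"]
    assert len(misses) == 1
    assert misses[0].t == pytest.approx(expected_frame * dt)
    assert misses[0].players == ("A",)


# ---------------------------------------------------------------------------
# whole trials
# ---------------------------------------------------------------------------

def test_trial_is_deterministic_given_seed(config):
    logs = [run_trial(IdealObserverPolicy(motor_noise_px=20, lapse_prob=0.05,
                                          lapse_duration_s=0.5),
                      None, "separate", "medium", config, seed=99,
                      record="full")
            for _ in range(2)]
    assert logs[0] == logs[1]
    assert logs[0].n_frames == config.n_frames
    other = run_trial(IdealObserverPolicy(motor_noise_px=20, lapse_prob=0.05,
                                          lapse_duration_s=0.5),
                      None, "separate", "medium", config, seed=100,
                      record="full")
    assert other != logs[0]


def test_low_workload_keeps_single_concurrent_ball(config):
    log = run_trial(IdealObserverPolicy(), None, "separate", "low", config,
                    seed=5, record="full")
    assert max(len(frame) for frame in log.ball_frames) == 1
    assert log.workload_balls == 1


def test_every_spawned_ball_terminates_once(config):
    """Descent conservation: spawns = hits + misses + censored."""
    for seed, condition, solo in [(1, "separate", True),
                                  (2, "collaborative", False),
                                  (3, "competitive", False)]:
        pol_b = None if solo else IdealObserverPolicy(motor_noise_px=30)
        log = run_trial(IdealObserverPolicy(motor_noise_px=30), pol_b,
                        condition, "very_high", config, seed=seed)
        counts = log.event_counts()
        assert log.n_spawned == (counts["hit"] + counts["miss"]
                                 + log.n_censored)
        assert counts["miss"] == sum(log.misses.values())


def test_paddles_never_leave_playable_span(config):
    log = run_trial(HumanSurrogatePolicy(motor_noise_px=40, monitor_weight=0.5),
                    HumanSurrogatePolicy(motor_noise_px=40, share_bias=0.5),
                    "competitive", "very_high", config, seed=17)
    lo, hi = config.paddle_bounds()
    for trace in (log.xA, log.xB):
        assert trace.min() >= lo - 1e-9
        assert trace.max() <= hi + 1e-9


def test_separate_scores_unaffected_by_partner_policy(config):
    """With disjoint ball colors a player's outcomes are independent of
    who (or what) controls the other paddle."""
    me = dict(motor_noise_px=15.0, lapse_prob=0.05, lapse_duration_s=0.5)
    partners = [IdealObserverPolicy(),
                HumanSurrogatePolicy(motor_noise_px=80, lapse_prob=0.3,
                                     lapse_duration_s=1.0)]
    logs = [run_trial(IdealObserverPolicy(**me), partner, "separate",
                      "medium", config, seed=123) for partner in partners]
    assert logs[0].hits["A"] == logs[1].hits["A"]
    assert logs[0].misses["A"] == logs[1].misses["A"]
    assert logs[0].scores["A"] == logs[1].scores["A"]
    assert not np.array_equal(logs[0].xB, logs[1].xB)  # partners did differ


def test_scoreboard_equals_fold_over_hit_events(config):
    for condition, solo in [("separate", False), ("collaborative", False),
                            ("competitive", False)]:
        log = run_trial(IdealObserverPolicy(motor_noise_px=25),
                        IdealObserverPolicy(motor_noise_px=25),
                        condition, "high", config, seed=31)
        totals = {"A": 0.0, "B": 0.0, "team": 0.0}
        for ev in log.events:
            if ev.kind != "hit":
                continue
            for unit, delta in credit_hit(condition, ev.players).items():
                totals[unit] += delta
        assert totals == log.scores


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def test_session_block_structure_and_reproducibility(config):
    spec = DyadSpec(dyad_id="d0", team_type="HH",
                    policy_a=HumanSurrogatePolicy(motor_noise_px=15),
                    policy_b=HumanSurrogatePolicy(motor_noise_px=15),
                    block_order=("separate", "collaborative", "competitive"))
    rec = run_session(spec, config, seed=8, record="none")
    assert len(rec.trials) == 36
    for b in range(3):
        block = rec.trials[b * 12:(b + 1) * 12]
        assert {t.condition for t in block} == {rec.block_order[b]}
        workloads = sorted(t.workload for t in block)
        assert workloads == sorted(["low", "medium", "high", "very_high"] * 3)
    rec2 = run_session(spec, config, seed=8, record="none")
    assert [t.hits for t in rec.trials] == [t.hits for t in rec2.trials]
    assert [t.seed for t in rec.trials] == [t.seed for t in rec2.trials]


def test_dyad_spec_validates_block_order():
    with pytest.raises(ValueError):
        DyadSpec("d", "HH", None, None,
                 block_order=("separate", "separate", "collaborative"))
    with pytest.raises(ValueError):
        DyadSpec("d", "XX", None, None)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("record", ["full", "positions"])
def test_trial_log_roundtrip(config, tmp_path, record):
    log = run_trial(IdealObserverPolicy(motor_noise_px=10),
                    HumanSurrogatePolicy(), "collaborative", "low", config,
                    seed=4, record=record)
    path = tmp_path / "trial.jsonl"
    write_trial_log(log, path, tick_rate=config.tick_rate)
    assert read_trial_log(path) == log


def test_zero_ball_trial_roundtrips_with_empty_game_events(config, tmp_path,
                                                           stationary):
    log = run_trial(stationary, None, "separate", 0, config, seed=1,
                    record="positions")
    assert not [ev for ev in log.events if ev.kind in ("hit", "miss")]
    assert log.n_spawned == 0
    path = tmp_path / "empty.jsonl"
    write_trial_log(log, path)
    assert read_trial_log(path) == log


def test_truncated_or_malformed_log_raises_parse_error(config, tmp_path):
    log = run_trial(IdealObserverPolicy(), None, "separate", "low", config,
                    seed=2, record="positions")
    path = tmp_path / "trial.jsonl"
    write_trial_log(log, path)
    lines = path.read_text().splitlines()
    bad = tmp_path / "bad.jsonl"
    bad.write_text("\n".join(lines[:5])[:-7])  # truncate mid-record
    with pytest.raises(TrialLogParseError):
        read_trial_log(bad)
    empty = tmp_path / "empty.jsonl"
    empty.write_text("")
    with pytest.raises(TrialLogParseError, match="header"):
        read_trial_log(empty)
    noheader = tmp_path / "nohdr.jsonl"
    noheader.write_text('{"trial_id": "x"}\n')
    with pytest.raises(TrialLogParseError, match="missing field"):
        read_trial_log(noheader)


# ---------------------------------------------------------------------------
# configuration invariants
# ---------------------------------------------------------------------------

def test_playable_span_geometry(config):
    assert config.playable_span == 720.0
    assert config.left_bound == 40.0 and config.right_bound == 760.0


@pytest.mark.parametrize("kw", [
    {"workload_levels": {"low": 2, "medium": 3, "high": 5, "very_high": 7}},
    {"workload_levels": {"low": 1, "medium": 3, "high": 3, "very_high": 7}},
    {"paddle_speed": 0.0},
    {"paddle_y": 700.0},
])
def test_invalid_configs_rejected(kw):
    with pytest.raises(ValueError):
        GameConfig(**kw)
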