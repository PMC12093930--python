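"""Policies: intercept geometry, noise channels, Q-learning, calibration."""

import random

import numpy as np
import pytest

from teamcap import (GameConfig, GameState, IdealObserverPolicy,
                     ConsideratePolicy, HumanSurrogatePolicy, PolicySpec,
                     CalibrationTarget, CalibrationError, calibrate_policy,
                     build_policy, floor_intercept, run_trial, solo_miss_rate,
                     q_agent_train)
from teamcap.agents import q_update, QTable
from teamcap.metrics import momentary_distance


def make_state(config, condition="separate", workload="low", seed=0,
               solo=True):
    return GameState(config, condition, workload, random.Random(seed),
                     solo=solo)


# ---------------------------------------------------------------------------
# intercept geometry
# ---------------------------------------------------------------------------

def brute_force_intercept(x, y, vx, vy, config, dt=1.0 / 600.0):
    """Frame-step the ball (with wall reflections) until the paddle line."""
    while True:
        x_new, y_new = x + vx * dt, y + vy * dt
        if x_new < config.left_bound:
            x_new = 2 * config.left_bound - x_new
            vx = -vx
        elif x_new > config.right_bound:
            x_new = 2 * config.right_bound - x_new
            vx = -vx
        if y_new >= config.paddle_y:
            frac = (config.paddle_y - y) / (y_new - y)
            return x + (x_new - x) * frac, y_new
        x, y = x_new, y_new


def test_intercept_matches_brute_force_simulation(config):
    """Analytic wall-reflected extrapolation agrees with per-frame
    simulation to within a pixel over 1,000 random ball states."""
    rng = np.random.default_rng(12345)
    for _ in range(1000):
        x = rng.uniform(config.left_bound, config.right_bound)
        y = rng.uniform(0.0, config.paddle_y - 10.0)
        vx = rng.uniform(-300.0, 300.0)
        vy = rng.uniform(40.0, 400.0)
        ix, tf = floor_intercept(x, y, vx, vy, config)
        bx, _ = brute_force_intercept(x, y, vx, vy, config)
        assert abs(ix - bx) <= 1.0
        assert tf == pytest.approx((config.paddle_y - y) / vy)


def test_intercept_requires_descending_ball(config):
    with pytest.raises(ValueError):
        floor_intercept(400.0, 100.0, 0.0, -50.0, config)


# ---------------------------------------------------------------------------
# ideal observer
# ---------------------------------------------------------------------------

def test_observer_holds_under_ball_falling_onto_paddle(config):
    pol = IdealObserverPolicy(reaction_delay_s=0.0)
    pol.reset("A", "separate", config, seed=0)
    state = make_state(config)
    ball = state.balls[0]
    ball.x, ball.y, ball.vx, ball.vy = state.paddle_x["A"], 200.0, 0.0, 300.0
    assert pol.act(state, "A") == 0


def test_observer_moves_toward_intercept(config):
    pol = IdealObserverPolicy(reaction_delay_s=0.0)
    pol.reset("A", "separate", config, seed=0)
    state = make_state(config)
    ball = state.balls[0]
    ball.x, ball.y, ball.vx, ball.vy = 700.0, 100.0, 0.0, 300.0
    state.paddle_x["A"] = 200.0
    assert pol.act(state, "A") == 1


def test_full_lapse_never_acts(config):
    pol = IdealObserverPolicy(reaction_delay_s=0.0, lapse_prob=1.0)
    pol.reset("A", "separate", config, seed=0)
    state = make_state(config, workload="very_high")
    assert all(pol.act(state, "A") == 0 for _ in range(50))


def test_no_descending_ball_means_no_action(config):
    pol = IdealObserverPolicy(reaction_delay_s=0.0)
    pol.reset("A", "separate", config, seed=0)
    state = make_state(config)
    state.balls[0].vy = -200.0  # ascending after a rebound
    assert pol.act(state, "A") == 0


# ---------------------------------------------------------------------------
# considerate observer
# ---------------------------------------------------------------------------

def cands(*triples):
    return [(tf, ix, bid, True) for tf, ix, bid in triples]


def test_considerate_yields_ball_over_partner_in_collaboration(config):
    pol = ConsideratePolicy(avoid_radius_px=100.0)
    pol.reset("A", "collaborative", config, seed=0)
    # the sooner ball (id 1) lands on the partner; target the other one
    chosen = pol._select_target(cands((1.0, 300.0, 1), (1.5, 550.0, 2)),
                                own_x=400.0, partner_x=300.0)
    assert chosen[2] == 2
    # with no alternative the partner-covered ball is still taken
    chosen = pol._select_target(cands((1.0, 300.0, 1)), 400.0, 300.0)
    assert chosen[2] == 1


def test_considerate_ignores_partner_outside_collaboration(config):
    pol = ConsideratePolicy(avoid_radius_px=100.0)
    pol.reset("A", "competitive", config, seed=0)
    chosen = pol._select_target(cands((1.0, 300.0, 1), (1.5, 550.0, 2)),
                                400.0, 300.0)
    assert chosen[2] == 1


def test_considerate_identical_to_simple_outside_collaboration(config):
    """Outside the collaborative condition the two observers generate
    identical trials under shared seeds."""
    kw = dict(motor_noise_px=20.0, lapse_prob=0.05, lapse_duration_s=0.5)
    for condition in ("separate", "competitive"):
        partner = IdealObserverPolicy()
        logs = [run_trial(pol, partner, condition, "medium", config, seed=55)
                for pol in (IdealObserverPolicy(**kw), ConsideratePolicy(**kw))]
        assert np.array_equal(logs[0].xA, logs[1].xA)
        assert logs[0].hits == logs[1].hits
        assert logs[0].events == logs[1].events


# ---------------------------------------------------------------------------
# human surrogate
# ---------------------------------------------------------------------------

def test_share_bias_prefers_own_half(config):
    pol = HumanSurrogatePolicy(share_bias=1.0)
    pol.reset("A", "collaborative", config, seed=0)  # player A owns the left
    chosen = pol._select_target(cands((1.0, 600.0, 1), (2.0, 200.0, 2)),
                                400.0, 600.0)
    assert chosen[2] == 2
    # no own-half ball in the air: the constraint does not starve the player
    chosen = pol._select_target(cands((1.0, 600.0, 1)), 400.0, 600.0)
    assert chosen[2] == 1


def test_unbiased_surrogate_reduces_to_ideal_observer(config):
    kw = dict(motor_noise_px=20.0, lapse_prob=0.05, lapse_duration_s=0.5)
    partner_a, partner_b = IdealObserverPolicy(), IdealObserverPolicy()
    log_s = run_trial(HumanSurrogatePolicy(**kw), partner_a, "competitive",
                      "medium", config, seed=77)
    log_i = run_trial(IdealObserverPolicy(**kw), partner_b, "competitive",
                      "medium", config, seed=77)
    assert np.array_equal(log_s.xA, log_i.xA)
    assert log_s.hits == log_i.hits and log_s.misses == log_i.misses


def test_monitoring_reduces_paddle_separation(config):
    """Attraction toward the opponent shrinks mean momentary distance."""
    def mean_distance(monitor):
        dists = []
        for seed in range(100):
            log = run_trial(
                HumanSurrogatePolicy(motor_noise_px=15, monitor_weight=monitor),
                HumanSurrogatePolicy(motor_noise_px=15, monitor_weight=monitor),
                "competitive", "high", config, seed=9000 + seed)
            dists.append(momentary_distance(log.xA, log.xB))
        return float(np.mean(dists))

    assert mean_distance(0.5) < mean_distance(0.0)


# ---------------------------------------------------------------------------
# Q-learning
# ---------------------------------------------------------------------------

def test_q_update_rule_limits():
    table = QTable.zeros(GameConfig())
    q_update(table.q, (3, 4), 1, 1.0, None, alpha=1.0, gamma=0.0)
    assert table.q[3, 4, 1] == 1.0
    # bootstrap pulls toward reward + gamma * max future
    q_update(table.q, (0, 0), 2, 0.0, (3, 4), alpha=0.5, gamma=0.9)
    assert table.q[0, 0, 2] == pytest.approx(0.5 * 0.9 * 1.0)


def test_untrained_agent_holds_everywhere(config):
    res = q_agent_train(config, episodes=0, seed=1)
    pol = res.policy
    pol.reset("A", "separate", config, seed=0)
    for seed in range(5):
        state = make_state(config, workload="very_high", seed=seed)
        assert pol.act(state, "A") == 0
    assert not res.episode_hits


def test_training_beats_untrained_baseline(config, trained_q):
    untrained = q_agent_train(config, episodes=0, seed=1).policy
    r_untrained, _, _ = solo_miss_rate(untrained, "low", config, 60, seed=40)
    r_trained, _, _ = solo_miss_rate(trained_q.policy, "low", config, 60,
                                     seed=40)
    assert r_trained < r_untrained


def test_qtable_roundtrip(config, tmp_path, trained_q):
    prefix = str(tmp_path / "qtab")
    trained_q.policy.table.save(prefix)
    loaded = QTable.load(prefix)
    assert np.array_equal(loaded.q, trained_q.policy.table.q)
    assert np.array_equal(loaded.offset_edges,
                          trained_q.policy.table.offset_edges)


# ---------------------------------------------------------------------------
# specs and calibration
# ---------------------------------------------------------------------------

def test_policy_spec_validation():
    with pytest.raises(ValueError):
        PolicySpec("optimal_controller")
    with pytest.raises(ValueError):
        PolicySpec("human_surrogate", {"share_bias": 1.5})
    with pytest.raises(ValueError):
        PolicySpec("ideal_observer_simple", {"motor_noise_px": -1.0})
    pol = build_policy(PolicySpec("ideal_observer_considerate",
                                  {"avoid_radius_px": 80.0}))
    assert isinstance(pol, ConsideratePolicy)


def test_unreachable_target_reports_probe_curve(config):
    target = CalibrationTarget(workload_low_missrate=0.5,
                               workload_veryhigh_missrate=0.99,
                               tolerance=0.02, n_trials=4)
    with pytest.raises(CalibrationError) as exc:
        calibrate_policy("ideal_observer_simple", target, config, seed=1,
                         scalar_hi=0.1)
    assert len(exc.value.probes) >= 1


def test_degenerate_tolerance_accepts_anything(config):
    target = CalibrationTarget(tolerance=1.0, n_trials=4)
    res = calibrate_policy("ideal_observer_simple", target, config, seed=2)
    assert res.converged
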