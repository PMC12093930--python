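import pytest

from teamcap import (GameConfig, CalibrationTarget, calibrate_policy,
                     q_agent_train)


@pytest.fixture()
def config():
    return GameConfig()


@pytest.fixture(scope="session")
def session_config():
    return GameConfig()


@pytest.fixture(scope="session")
def calibration(session_config):
    """Calibrated ideal-observer noise (shared: calibration is the slow step)."""
    return calibrate_policy("ideal_observer_simple", CalibrationTarget(),
                            session_config, seed=20)


@pytest.fixture(scope="session")
def trained_q(session_config):
    """A briefly trained Q-learning agent (enough to beat the untrained one)."""
    return q_agent_train(session_config, episodes=150, seed=3)


class StationaryPolicy:
    """Never moves; useful as a degenerate baseline."""

    decision_epoch = 1

    def reset(self, player_id, condition, config, seed):
        pass

    def act(self, state, player_id):
        return 0


@pytest.fixture()
def stationary():
    return StationaryPolicy()
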