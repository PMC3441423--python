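import numpy as np
import pytest

from shpd.session import Session, SpikeTrain, TrialEvents, UnitWaveform
from shpd.simulate import GeneratorConfig, simulate_cohort


def make_trial(i, t0, condition="baseline", arm="left", correct=True,
               delay=10.0, run=2.0, branch=1.0, choice=1.0, reward=6.0):
    """Hand-built trial with simple round event times starting at t0."""
    t_gate = t0 + delay
    t_branch = t_gate + run
    t_choice = t_branch + branch
    if correct:
        t_reward = t_choice + choice
        t_pickup = t_reward + reward
    else:
        t_reward = None
        t_pickup = t_choice + choice
    return TrialEvents(
        trial_index=i, condition=condition, arm=arm, correct=correct,
        t_startbox=t0, t_gate=t_gate, t_branch=t_branch, t_choice=t_choice,
        t_pickup=t_pickup, t_reward=t_reward,
    )


@pytest.fixture
def tiny_session():
    """Three correct trials, one unit with a handful of spikes."""
    trials = [make_trial(1, 0.0), make_trial(2, 25.0, arm="right"),
              make_trial(3, 50.0)]
    spikes = SpikeTrain(unit_id="u0", times=np.array([0.1, 0.2, 0.6, 26.0, 51.5]),
                        session_id="s0")
    sess = Session(
        session_id="s0", condition="baseline", noise_db=60.0,
        delay_length_s=10.0, trials=trials, spikes=[spikes],
        waveforms={"u0": UnitWaveform(unit_id="u0", pp_duration_us=300.0)},
        pickup_tail_s=5.0,
    )
    sess.validate()
    return sess


@pytest.fixture(scope="session")
def small_cohort():
    """Two simulated units at modest size, shared across tests."""
    cfg = GeneratorConfig(
        n_trials=12, delay_length_s=5.0, n_units=2, seed=42,
        error_rate={"baseline": 0.0, "stress": 0.0},
    )
    return simulate_cohort(cfg)
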