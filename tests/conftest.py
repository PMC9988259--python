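import numpy as np
import pytest

import recalib as rc


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Compact paradigm: full structure, few repetitions."""
    return rc.ParadigmConfig(
        reps_pre=4,
        reps_per_ramp_increment=2,
        reps_max_delta=3,
        reps_post_single=4,
        reps_post_combined=1,
    )


@pytest.fixture(scope="session")
def demo_session(small_config):
    """One simulated session with two neurons, reused by read-only tests."""
    rng = np.random.default_rng(777)
    behavior = rc.sample_session_behavior("+", rng)
    neurons = rc.make_area_population("MSTd-like", 2, behavior, rng)
    return rc.simulate_session(
        small_config, behavior, neurons, rng=rng, monkey_id="D", session_id="s_demo"
    )


@pytest.fixture(scope="session")
def tuned_session():
    """Session with one steeply tuned default neuron, standard repetitions."""
    rng = np.random.default_rng(4242)
    behavior = rc.BehaviorProfile.from_shifts(
        shift={"vestibular": 1.5, "visual": -0.9}, lapse=0.0
    )
    neuron = rc.NeuronProfile(
        tuning_shift_deg={
            "vestibular": {"pre": 0.0, "post": 1.5},
            "visual": {"pre": 0.0, "post": -0.9},
        }
    )
    return rc.simulate_session(rc.ParadigmConfig(), behavior, [neuron], rng=rng)
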