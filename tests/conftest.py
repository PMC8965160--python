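import numpy as np
import pytest
from hypothesis import settings

import msmpath as mp

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def binding_system():
    return mp.build_ground_truth_chain("binding_landscape")


@pytest.fixture(scope="session")
def two_state_system():
    return mp.build_ground_truth_chain("two_state")


@pytest.fixture(scope="session")
def binding_trajs(binding_system):
    """Moderate ensemble from the binding preset for unit tests."""
    return [
        mp.sample_chain_trajectory(binding_system, 5000, start_state=0, seed=s)
        for s in range(10)
    ]


@pytest.fixture(scope="session")
def binding_msm(binding_trajs):
    """MSM on the (known) hidden states, with trajectories attached."""
    dtrajs = [t.hidden_states for t in binding_trajs]
    msm = mp.estimate_msm(mp.count_transitions(dtrajs, lag=1), frame_dt=1.0)
    return msm, dtrajs, binding_trajs


def exact_msm(T, lag=1, frame_dt=1.0):
    """Wrap a known transition matrix as a model (no estimation noise)."""
    T = np.asarray(T, dtype=float)
    return mp.MarkovStateModel(
        T=T,
        pi=mp.stationary_distribution(T),
        active_set=np.arange(T.shape[0]),
        lag=lag,
        frame_dt=frame_dt,
    )


def random_ergodic_chain(n, rng, metastable=False):
    """Dense random row-stochastic matrix; irreducible by construction."""
    A = rng.random((n, n)) + 0.05
    if metastable:
        A += np.eye(n) * rng.uniform(5, 20)
    return A / A.sum(axis=1, keepdims=True)
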