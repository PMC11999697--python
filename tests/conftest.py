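import numpy as np
import pytest

from fretscape.hmm import HmmModel
from fretscape.simulate import NoiseSpec, ScenarioSpec
from fretscape.traces import FretTrajectory


@pytest.fixture
def two_state_spec():
    """Well-separated two-state scenario (means 0.8/0.2, sticky chain)."""
    return ScenarioSpec(
        name="two-state",
        n_states=2,
        state_means=(0.8, 0.2),
        shared_sigma=0.05,
        transition_matrix=np.array([[0.95, 0.05], [0.05, 0.95]]),
        initial_dist=np.array([0.5, 0.5]),
    )


@pytest.fixture
def quiet_noise():
    """Noise-free, bleach-free detection chain (for exactness tests)."""
    return NoiseSpec(
        channel_noise_sigma=0.0,
        fret_jitter_sigma=0.0,
        bleedthrough_alpha=0.0,
        background_donor=0.0,
        background_acceptor=0.0,
        acceptor_bleach_hazard=0.0,
        simultaneous_bleach_hazard=0.0,
    )


def make_trajectories(means, sigma, transition, n_traces, n_frames, seed,
                      initial=None):
    """FRET trajectories drawn directly in E-space from a Markov chain.

    Bypasses the camera model; used wherever a test needs exact control of
    the Gaussian emission assumptions.
    """
    means = np.asarray(means, dtype=float)
    A = np.asarray(transition, dtype=float)
    K = len(means)
    pi = np.full(K, 1.0 / K) if initial is None else np.asarray(initial, float)
    rng = np.random.default_rng(seed)
    cum_pi = np.cumsum(pi)
    cum_A = np.cumsum(A, axis=1)
    out = []
    paths = []
    for i in range(n_traces):
        u = rng.random(n_frames)
        path = np.empty(n_frames, dtype=int)
        path[0] = np.searchsorted(cum_pi, u[0], side="right")
        for t in range(1, n_frames):
            path[t] = np.searchsorted(cum_A[path[t - 1]], u[t], side="right")
        e = means[path] + rng.normal(0.0, sigma, n_frames)
        out.append(FretTrajectory(trace_id=f"sim-{i:03d}", e_app=e))
        paths.append(path)
    return out, paths


@pytest.fixture
def tiny_model():
    """Small 2-state model used by the enumeration-oracle tests."""
    return HmmModel(
        n_states=2,
        means=np.array([0.8, 0.2]),
        shared_variance=0.01,
        transition_matrix=np.array([[0.9, 0.1], [0.2, 0.8]]),
        initial_dist=np.array([0.6, 0.4]),
    )
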