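"""Global shared-variance HMM: oracles, EM behavior, parameter recovery."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from conftest import make_trajectories
from fretscape.errors import DataError, ValidationError
from fretscape.hmm import (
    EmConfig,
    HmmModel,
    em_fit,
    forward_backward,
    init_model,
    load_model,
    model_loglik,
    save_model,
    viterbi,
)
from fretscape.traces import FretTrajectory


def _traj(values):
    return FretTrajectory(trace_id="t", e_app=np.asarray(values, float))


def brute_force_loglik(obs, model):
    """Exhaustive sum over all K^T hidden paths."""
    K, T = model.n_states, len(obs)
    sd = np.sqrt(model.shared_variance)
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = model.initial_dist[path[0]]
        for t in range(1, T):
            p *= model.transition_matrix[path[t - 1], path[t]]
        for t in range(T):
            p *= norm.pdf(obs[t], model.means[path[t]], sd)
        total += p
    return np.log(total)


def brute_force_viterbi(obs, model):
    """Exhaustive argmax over all paths; ties to the lexicographically
    smallest path, matching the lower-state-index rule."""
    K, T = model.n_states, len(obs)
    sd = np.sqrt(model.shared_variance)
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(model.initial_dist[path[0]])
        for t in range(1, T):
            lp += np.log(model.transition_matrix[path[t - 1], path[t]])
        for t in range(T):
            lp += norm.logpdf(obs[t], model.means[path[t]], sd)
        if lp > best_lp + 1e-12:
            best_lp, best_path = lp, path
    return np.array(best_path), best_lp


# ------------------------------------------------------------------- init


def test_init_is_deterministic_and_symmetric():
    rng = np.random.default_rng(0)
    half = 0.5 + rng.random(500) * 0.4
    vals = np.concatenate([half, 1.0 - half])  # exactly symmetric about 0.5
    trajs = [_traj(vals)]
    m1 = init_model(trajs, 2, seed=0)
    m2 = init_model(trajs, 2, seed=0)
    assert np.array_equal(m1.means, m2.means)
    assert m1.means[0] - 0.5 == pytest.approx(0.5 - m1.means[1], abs=1e-6)
    assert np.allclose(np.diag(m1.transition_matrix), 0.95)


def test_init_k1_uses_median():
    vals = np.array([0.1] * 30 + [0.9] * 10)
    model = init_model([_traj(vals)], 1)
    assert model.means[0] == np.median(vals)
    assert np.allclose(model.transition_matrix, [[1.0]])


def test_init_requires_enough_frames():
    with pytest.raises(DataError, match="pooled frames"):
        init_model([_traj([0.5] * 15)], 2)


# --------------------------------------------------- forward-backward oracle


def test_forward_backward_matches_path_enumeration(tiny_model):
    obs = np.array([0.75, 0.3, 0.55])
    gamma, xi, ll = forward_backward(_traj(obs), tiny_model)
    assert ll == pytest.approx(brute_force_loglik(obs, tiny_model), abs=1e-9)
    assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-12)
    assert np.allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-12)
    # posterior from enumeration
    K, T = 2, 3
    sd = np.sqrt(tiny_model.shared_variance)
    post = np.zeros((T, K))
    for path in itertools.product(range(K), repeat=T):
        p = tiny_model.initial_dist[path[0]]
        for t in range(1, T):
            p *= tiny_model.transition_matrix[path[t - 1], path[t]]
        for t in range(T):
            p *= norm.pdf(obs[t], tiny_model.means[path[t]], sd)
        for t in range(T):
            post[t, path[t]] += p
    post /= post.sum(axis=1, keepdims=True)
    assert np.allclose(gamma, post, atol=1e-9)


def test_model_loglik_additive_and_matches_oracle(tiny_model):
    t1, t2 = _traj([0.8, 0.7]), _traj([0.2, 0.25, 0.8])
    ll = model_loglik([t1, t2], tiny_model)
    assert ll == pytest.approx(
        brute_force_loglik(t1.e_app, tiny_model)
        + brute_force_loglik(t2.e_app, tiny_model),
        abs=1e-9,
    )
    assert ll == pytest.approx(
        model_loglik([t1], tiny_model) + model_loglik([t2], tiny_model), abs=1e-10
    )


def test_forward_backward_k1_closed_form():
    model = HmmModel(
        n_states=1,
        means=np.array([0.4]),
        shared_variance=0.01,
        transition_matrix=np.array([[1.0]]),
        initial_dist=np.array([1.0]),
    )
    obs = np.array([0.3, 0.5, 0.45])
    gamma, _, ll = forward_backward(_traj(obs), model)
    assert np.all(gamma == 1.0)
    assert ll == pytest.approx(norm.logpdf(obs, 0.4, 0.1).sum(), abs=1e-10)


def test_nan_observations_rejected():
    with pytest.raises(ValidationError):
        _traj([0.5, np.nan])


def test_loglik_matches_hmmlearn_reference(tiny_model):
    """Independent cross-check of the forward recursion against hmmlearn."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    rng = np.random.default_rng(3)
    trajs = [_traj(rng.normal(0.5, 0.2, n)) for n in (20, 35, 50)]
    ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag", init_params="")
    ref.startprob_ = tiny_model.initial_dist
    ref.transmat_ = tiny_model.transition_matrix
    ref.means_ = tiny_model.means[:, None]
    ref.covars_ = np.full((2, 1), tiny_model.shared_variance)
    X = np.concatenate([t.e_app for t in trajs])[:, None]
    lengths = [len(t) for t in trajs]
    assert model_loglik(trajs, tiny_model) == pytest.approx(
        ref.score(X, lengths), rel=1e-9
    )


# ---------------------------------------------------------------- Viterbi


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
@pytest.mark.parametrize("K,T", [(2, 8), (3, 6), (3, 10)])
def test_viterbi_matches_exhaustive_enumeration(seed, K, T):
    rng = np.random.default_rng(seed)
    A = rng.random((K, K)) + 0.2
    A /= A.sum(axis=1, keepdims=True)
    pi = rng.random(K) + 0.2
    pi /= pi.sum()
    model = HmmModel(
        n_states=K,
        means=np.sort(rng.random(K))[::-1].copy(),
        shared_variance=0.02,
        transition_matrix=A,
        initial_dist=pi,
    )
    obs = rng.random(T)
    vp = viterbi(_traj(obs), model)
    ref_path, ref_lp = brute_force_viterbi(obs, model)
    assert np.array_equal(vp.states, ref_path)
    assert vp.path_loglik == pytest.approx(ref_lp, abs=1e-9)


def test_viterbi_tie_breaks_to_lower_state_index():
    model = HmmModel(
        n_states=2,
        means=np.array([0.7, 0.3]),
        shared_variance=0.01,
        transition_matrix=np.full((2, 2), 0.5),
        initial_dist=np.array([0.5, 0.5]),
    )
    vp = viterbi(_traj([0.5, 0.5, 0.5]), model)  # exactly equidistant
    assert np.all(vp.states == 0)


def test_viterbi_constant_observations_decode_to_nearest_state():
    model = HmmModel(
        n_states=3,
        means=np.array([0.8, 0.5, 0.2]),
        shared_variance=0.001,
        transition_matrix=np.full((3, 3), 1 / 3),
        initial_dist=np.full(3, 1 / 3),
    )
    vp = viterbi(_traj([0.5] * 20), model)
    assert np.all(vp.states == 1)


# --------------------------------------------------------------------- EM


@pytest.fixture(scope="module")
def two_state_fit():
    A = np.array([[0.95, 0.05], [0.05, 0.95]])
    trajs, _ = make_trajectories([0.8, 0.2], 0.05, A, 100, 200, seed=1234)
    return em_fit(trajs, 2), trajs


def test_em_recovers_generating_parameters(two_state_fit):
    fit, _ = two_state_fit
    m = fit.model
    assert np.max(np.abs(m.means - [0.8, 0.2])) < 0.02
    assert abs(m.transition_matrix[0, 0] - 0.95) < 0.02
    assert abs(m.transition_matrix[1, 1] - 0.95) < 0.02
    assert abs(np.sqrt(m.shared_variance) - 0.05) < 0.01


def test_em_loglik_monotone_and_labels_descending(two_state_fit):
    fit, _ = two_state_fit
    diffs = np.diff(fit.loglik_trajectory)
    assert np.all(diffs >= -1e-8 * np.abs(fit.loglik_trajectory[:-1]))
    assert np.all(np.diff(fit.model.means) < 0)
    assert np.allclose(fit.model.transition_matrix.sum(axis=1), 1.0, atol=1e-9)
    assert fit.model.initial_dist.sum() == pytest.approx(1.0, abs=1e-9)


def test_em_is_deterministic(two_state_fit):
    fit, trajs = two_state_fit
    fit2 = em_fit(trajs, 2)
    assert np.array_equal(fit.model.means, fit2.model.means)
    assert np.array_equal(fit.model.transition_matrix, fit2.model.transition_matrix)


def test_em_parameter_recovery_over_replicates():
    """Median error over 20 seeded replicates of the 2-state fixture."""
    A = np.array([[0.95, 0.05], [0.05, 0.95]])
    mean_errs, diag_errs = [], []
    for rep in range(20):
        trajs, _ = make_trajectories([0.8, 0.2], 0.05, A, 25, 150, seed=5000 + rep)
        m = em_fit(trajs, 2).model
        mean_errs.append(np.max(np.abs(m.means - [0.8, 0.2])))
        diag_errs.append(
            max(
                abs(m.transition_matrix[0, 0] - 0.95),
                abs(m.transition_matrix[1, 1] - 0.95),
            )
        )
    assert np.median(mean_errs) <= 0.01
    assert np.median(diag_errs) <= 0.02


def test_em_constant_data_floors_variance():
    trajs = [_traj([0.5] * 60)]
    fit = em_fit(trajs, 2, config=EmConfig(max_iter=50))
    assert fit.variance_floored
    assert fit.model.shared_variance == pytest.approx(1e-6)
    assert np.allclose(fit.model.means, 0.5, atol=1e-9)


def test_em_empty_input_raises():
    with pytest.raises(DataError):
        em_fit([], 2)


def test_model_serialization_round_trip(tmp_path, two_state_fit):
    fit, _ = two_state_fit
    p = tmp_path / "model.json"
    save_model(fit.model, p)
    loaded = load_model(p)
    assert np.allclose(loaded.means, fit.model.means)
    assert np.allclose(loaded.transition_matrix, fit.model.transition_matrix)
    assert loaded.shared_variance == fit.model.shared_variance
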