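"""Global shared-variance Gaussian hidden Markov model for FRET trajectories.

One K-state HMM is fit jointly to *all* screened trajectories of an
experimental condition: a single transition matrix A, initial distribution
pi, state means mu_k, and one emission variance sigma^2 shared by every
state. Each trajectory contributes an independent chain started from pi;
Baum-Welch sufficient statistics are accumulated across trajectories.
Viterbi decoding then idealizes each trajectory into its most likely state
path.

All recursions run in scaled (per-frame normalized) space, so probabilities
cannot underflow regardless of trajectory length. Trajectories of unequal
length are handled by padding with unit emission likelihoods, which leaves
every per-frame normalizer and the total log-likelihood untouched.

States are always relabeled so that means are strictly descending
(state 0 = highest FRET) after a fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ValidationError
from .traces import FretTrajectory

__all__ = [
    "HmmModel",
    "FitResult",
    "ViterbiPath",
    "EmConfig",
    "init_model",
    "forward_backward",
    "em_fit",
    "viterbi",
    "viterbi_all",
    "model_loglik",
    "save_model",
    "load_model",
]

_ATOL = 1e-9
VARIANCE_FLOOR = 1e-6  # FRET^2


@dataclass(frozen=True)
class HmmModel:
    """K-state Gaussian-emission HMM with shared variance."""

    n_states: int
    means: np.ndarray
    shared_variance: float
    transition_matrix: np.ndarray
    initial_dist: np.ndarray

    def __post_init__(self):
        K = self.n_states
        mu = np.asarray(self.means, dtype=float)
        A = np.asarray(self.transition_matrix, dtype=float)
        pi = np.asarray(self.initial_dist, dtype=float)
        if mu.shape != (K,):
            raise ValidationError("means must have length n_states")
        if A.shape != (K, K) or np.any(A < 0):
            raise ValidationError("transition_matrix must be K x K, non-negative")
        if np.max(np.abs(A.sum(axis=1) - 1.0)) > _ATOL:
            raise ValidationError("transition_matrix rows must sum to 1 within 1e-9")
        if pi.shape != (K,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > _ATOL:
            raise ValidationError("initial_dist must be a simplex vector")
        if self.shared_variance < VARIANCE_FLOOR:
            raise ValidationError(
                f"shared_variance must be >= the floor {VARIANCE_FLOOR}"
            )
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "transition_matrix", A)
        object.__setattr__(self, "initial_dist", pi)

    def relabeled_descending(self) -> "HmmModel":
        """Permute states so means are strictly descending."""
        order = np.argsort(-self.means, kind="stable")
        return HmmModel(
            n_states=self.n_states,
            means=self.means[order],
            shared_variance=self.shared_variance,
            transition_matrix=self.transition_matrix[np.ix_(order, order)],
            initial_dist=self.initial_dist[order],
        )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a Baum-Welch fit."""

    model: HmmModel
    loglik_trajectory: np.ndarray
    n_iterations: int
    converged: bool
    n_trajectories: int
    n_frames: int
    variance_floored: bool = False

    @property
    def loglik(self) -> float:
        return float(self.loglik_trajectory[-1])


@dataclass(frozen=True)
class ViterbiPath:
    """Most likely hidden path for one trajectory."""

    trace_id: str
    states: np.ndarray
    path_loglik: float

    def __post_init__(self):
        object.__setattr__(self, "states", np.asarray(self.states, dtype=int))


@dataclass(frozen=True)
class EmConfig:
    """Baum-Welch stopping rules."""

    tol: float = 1e-6  # relative log-likelihood change
    max_iter: int = 1000


# ---------------------------------------------------------------------------
# internals: padded-batch representation
# ---------------------------------------------------------------------------


def _pack(trajectories) -> tuple[np.ndarray, np.ndarray, list]:
    """Stack ragged trajectories into (X, lengths, ids) with NaN padding."""
    trajectories = list(trajectories)
    if not trajectories:
        raise DataError("at least one trajectory is required")
    lengths = np.array([len(t) for t in trajectories], dtype=int)
    X = np.full((len(trajectories), int(lengths.max())), np.nan)
    for i, t in enumerate(trajectories):
        if not np.all(np.isfinite(t.e_app)):
            raise ValidationError(f"trajectory {t.trace_id!r} contains NaN")
        X[i, : lengths[i]] = t.e_app
    return X, lengths, [t.trace_id for t in trajectories]


def _emission_probs(X, lengths, model) -> np.ndarray:
    """Scaled per-frame Gaussian likelihoods, padded frames set to 1."""
    var = model.shared_variance
    z = (X[:, :, None] - model.means[None, None, :]) ** 2
    B = np.exp(-0.5 * z / var) / np.sqrt(2.0 * np.pi * var)
    mask = np.arange(X.shape[1])[None, :] < lengths[:, None]
    B[~mask] = 1.0
    # guard against total underflow at extreme outliers
    B = np.maximum(B, 1e-300)
    return B


def _forward_backward_batch(B, lengths, model):
    """Scaled forward-backward over a padded batch.

    Returns (gamma, xi_sum, log_c, loglik_per_traj) where gamma is the
    per-frame state posterior, xi_sum the per-trajectory summed transition
    posteriors (N, K, K), and log_c the per-frame log normalizers.
    """
    N, Tmax, K = B.shape
    A = model.transition_matrix
    pi = model.initial_dist
    mask = np.arange(Tmax)[None, :] < lengths[:, None]

    alpha = np.empty((N, Tmax, K))
    c = np.empty((N, Tmax))
    a = pi[None, :] * B[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / c[:, 0, None]
    for t in range(1, Tmax):
        a = (alpha[:, t - 1, :] @ A) * B[:, t, :]
        s = a.sum(axis=1)
        c[:, t] = s
        alpha[:, t, :] = a / s[:, None]

    beta = np.empty((N, Tmax, K))
    beta[:, Tmax - 1, :] = 1.0
    for t in range(Tmax - 2, -1, -1):
        b = (beta[:, t + 1, :] * B[:, t + 1, :]) @ A.T
        beta[:, t, :] = b / c[:, t + 1, None]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    gamma[~mask] = 0.0

    # xi summed over t: xi_t ∝ alpha_t A B_{t+1} beta_{t+1} / c_{t+1}
    xi_sum = np.zeros((N, K, K))
    valid = np.arange(1, Tmax)[None, :] < lengths[:, None]  # t+1 in range
    for t in range(Tmax - 1):
        w = (B[:, t + 1, :] * beta[:, t + 1, :]) / c[:, t + 1, None]
        x = alpha[:, t, :, None] * A[None, :, :] * w[:, None, :]
        x[~valid[:, t]] = 0.0
        xi_sum += x

    log_c = np.where(mask, np.log(c), 0.0)
    loglik = log_c.sum(axis=1)
    return gamma, xi_sum, log_c, loglik


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def init_model(trajectories, K: int, seed=0) -> HmmModel:
    """Deterministic range-based initialization.

    Means are evenly spaced between the 2.5th and 97.5th percentile of the
    pooled E_app (ordered descending; the pooled median for K = 1), the
    shared variance is the pooled variance divided by K (floored), the
    transition matrix has 0.95 on the diagonal with uniform off-diagonal
    mass, and pi is uniform. Spacing means over the observed *range* rather
    than over quantiles keeps sparsely populated states from collapsing
    onto the dominant peak when occupancies are strongly skewed. ``seed``
    is accepted for interface symmetry (used by restart variants).
    """
    trajectories = list(trajectories)
    pooled = np.concatenate([t.e_app for t in trajectories]) if trajectories else np.array([])
    if len(pooled) < 10 * K:
        raise DataError(
            f"need at least {10 * K} pooled frames to initialize K={K}, "
            f"got {len(pooled)}"
        )
    if K == 1:
        means = np.array([np.median(pooled)])
    else:
        lo, hi = np.quantile(pooled, [0.025, 0.975])
        means = np.linspace(hi, lo, K)  # descending
    var = max(float(np.var(pooled)) / K, VARIANCE_FLOOR)
    if K == 1:
        A = np.ones((1, 1))
    else:
        A = np.full((K, K), 0.05 / (K - 1))
        A[np.diag_indices(K)] = 0.95
    pi = np.full(K, 1.0 / K)
    return HmmModel(
        n_states=K,
        means=means,
        shared_variance=var,
        transition_matrix=A,
        initial_dist=pi,
    )


def forward_backward(trajectory: FretTrajectory, model: HmmModel):
    """Posterior state probabilities for one trajectory.

    Returns ``(gamma, xi, loglik)``: gamma has shape (T, K) with rows
    summing to 1; xi has shape (T-1, K, K), each slice summing to 1 over
    its K x K entries; loglik is the log of the total observation
    probability under the model.
    """
    X, lengths, _ = _pack([trajectory])
    B = _emission_probs(X, lengths, model)
    N, Tmax, K = B.shape
    A = model.transition_matrix

    alpha = np.empty((Tmax, K))
    c = np.empty(Tmax)
    a = model.initial_dist * B[0, 0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, Tmax):
        a = (alpha[t - 1] @ A) * B[0, t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((Tmax, K))
    beta[-1] = 1.0
    for t in range(Tmax - 2, -1, -1):
        beta[t] = ((beta[t + 1] * B[0, t + 1]) @ A.T) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = (
        alpha[:-1, :, None]
        * A[None, :, :]
        * (B[0, 1:, :] * beta[1:, :] / c[1:, None])[:, None, :]
    )
    xi /= xi.sum(axis=(1, 2), keepdims=True)
    return gamma, xi, float(np.log(c).sum())


def em_fit(
    trajectories,
    K: int,
    config: EmConfig | None = None,
    seed=0,
) -> FitResult:
    """Baum-Welch fit of the global shared-variance HMM.

    Sufficient statistics are pooled over all trajectories; sigma^2 is
    re-estimated as the single posterior-weighted variance pooled over all
    states and frames. Iterates until the relative log-likelihood change
    drops below ``config.tol`` or ``config.max_iter`` is reached. The
    returned model has states relabeled descending by mean. Deterministic
    given inputs and seed.
    """
    cfg = config or EmConfig()
    trajectories = list(trajectories)
    X, lengths, _ = _pack(trajectories)
    n_frames = int(lengths.sum())
    if n_frames < 10 * K:
        raise DataError(f"need at least {10 * K} pooled frames for K={K}")
    model = init_model(trajectories, K, seed=seed)
    mask = np.arange(X.shape[1])[None, :] < lengths[:, None]
    Xz = np.where(mask, X, 0.0)

    loglik_hist = []
    floored = False
    converged = False
    for it in range(cfg.max_iter):
        B = _emission_probs(X, lengths, model)
        gamma, xi_sum, _, loglik = _forward_backward_batch(B, lengths, model)
        total_ll = float(loglik.sum())
        loglik_hist.append(total_ll)

        # M-step
        pi_new = gamma[:, 0, :].sum(axis=0)
        pi_new /= pi_new.sum()
        trans = xi_sum.sum(axis=0)
        rows = trans.sum(axis=1, keepdims=True)
        # states never left keep their previous row
        A_new = np.where(rows > 0, trans / np.maximum(rows, 1e-300), model.transition_matrix)
        A_new /= A_new.sum(axis=1, keepdims=True)
        occ = gamma.sum(axis=(0, 1))  # (K,)
        mu_new = np.where(
            occ > 0,
            np.einsum("nt,ntk->k", Xz, gamma) / np.maximum(occ, 1e-300),
            model.means,
        )
        resid = (X[:, :, None] - mu_new[None, None, :]) ** 2
        resid = np.where(mask[:, :, None], resid, 0.0)
        var_new = float((gamma * resid).sum() / occ.sum())
        if var_new < VARIANCE_FLOOR:
            var_new = VARIANCE_FLOOR
            floored = True
        model = HmmModel(
            n_states=K,
            means=mu_new,
            shared_variance=var_new,
            transition_matrix=A_new,
            initial_dist=pi_new,
        )
        if it > 0:
            prev = loglik_hist[-2]
            if abs(total_ll - prev) <= cfg.tol * abs(prev):
                converged = True
                break

    # final likelihood under the last parameter update
    B = _emission_probs(X, lengths, model)
    _, _, _, loglik = _forward_backward_batch(B, lengths, model)
    loglik_hist.append(float(loglik.sum()))
    return FitResult(
        model=model.relabeled_descending(),
        loglik_trajectory=np.asarray(loglik_hist),
        n_iterations=len(loglik_hist) - 1,
        converged=converged,
        n_trajectories=len(trajectories),
        n_frames=n_frames,
        variance_floored=floored,
    )


def viterbi(trajectory: FretTrajectory, model: HmmModel) -> ViterbiPath:
    """Most likely state path (log-space); ties break to the lower index."""
    e = trajectory.e_app
    K = model.n_states
    var = model.shared_variance
    logB = -0.5 * (e[:, None] - model.means[None, :]) ** 2 / var - 0.5 * np.log(
        2.0 * np.pi * var
    )
    with np.errstate(divide="ignore"):
        logA = np.log(model.transition_matrix)
        logpi = np.log(model.initial_dist)
    T = len(e)
    delta = logpi + logB[0]
    back = np.empty((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logA  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # argmax -> lowest index on ties
        delta = cand[back[t], np.arange(K)] + logB[t]
    states = np.empty(T, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return ViterbiPath(
        trace_id=trajectory.trace_id,
        states=states,
        path_loglik=float(np.max(delta)),
    )


def viterbi_all(trajectories, model: HmmModel) -> list[ViterbiPath]:
    """Decode every trajectory."""
    return [viterbi(t, model) for t in trajectories]


def model_loglik(trajectories, model: HmmModel) -> float:
    """Total log-likelihood of a trajectory collection under a model.

    Additive over disjoint trajectory sets (independent chains).
    """
    X, lengths, _ = _pack(trajectories)
    B = _emission_probs(X, lengths, model)
    _, _, _, loglik = _forward_backward_batch(B, lengths, model)
    return float(loglik.sum())


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_MODEL_FORMAT_VERSION = "1.0"


def save_model(model: HmmModel, path) -> None:
    """Serialize a model to JSON with explicit field names."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "n_states": model.n_states,
        "means": list(model.means),
        "shared_variance": model.shared_variance,
        "transition_matrix": [list(r) for r in model.transition_matrix],
        "initial_dist": list(model.initial_dist),
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path) -> HmmModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return HmmModel(
        n_states=int(payload["n_states"]),
        means=np.asarray(payload["means"], dtype=float),
        shared_variance=float(payload["shared_variance"]),
        transition_matrix=np.asarray(payload["transition_matrix"], dtype=float),
        initial_dist=np.asarray(payload["initial_dist"], dtype=float),
    )
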