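"""State-count selection: composite densities, Gaussian mixtures, BIC.

For each candidate number of states K (default 2..5), a global HMM is fit
per condition, the pooled apparent-FRET samples of that condition are fit
with a Gaussian mixture initialized from the HMM, and the Bayesian
Information Criterion BIC = p ln(n) - 2 ln(L) with p = 3K - 1 free
parameters (K means, K variances, K-1 weights) is computed on the pooled
frames. One state count is chosen per receptor by minimizing the BIC summed
over its conditions (ties to the smaller K), and the consistency of the
fitted peak positions across conditions is reported as a sanity check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import KernelDensity

from .errors import DataError, ValidationError
from .hmm import EmConfig, FitResult, HmmModel, em_fit

__all__ = [
    "DensityCurve",
    "GmmFit",
    "SelectionResult",
    "FRET_GRID",
    "kde_density",
    "fit_gmm",
    "bic",
    "select_state_count",
    "save_selection",
]

#: Fixed FRET axis: 512 points spanning [-0.2, 1.2] so that unclamped
#: E_app values remain representable.
FRET_GRID = np.linspace(-0.2, 1.2, 512)

GMM_VARIANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class DensityCurve:
    """A 1-D density sampled on the fixed FRET grid (trapezoid-normalized)."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_points: int

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if g.shape != d.shape or g.ndim != 1:
            raise ValidationError("grid and density must be matching 1-D arrays")
        if np.any(d < 0):
            raise ValidationError("density values must be non-negative")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "density", d)

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class GmmFit:
    """A fitted K-component 1-D Gaussian mixture and its BIC."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    n_params: int
    bic: float
    n: int

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1 within 1e-9")
        if np.any(np.asarray(self.variances) < GMM_VARIANCE_FLOOR * (1 - 1e-12)):
            raise ValidationError("component variances below the floor")


@dataclass(frozen=True)
class SelectionResult:
    """Per-K fits and the selected state count for one receptor.

    ``per_condition`` maps K -> {condition -> (FitResult, GmmFit)}.
    ``bic_by_condition`` maps K -> {condition -> bic}; ``bic_total`` maps
    K -> summed bic. ``peak_consistency`` is, for the selected K, the
    maximum over states of the spread (max - min) of GMM component means
    across conditions after descending sort.
    """

    candidate_Ks: tuple
    selected_K: int
    bic_total: dict
    bic_by_condition: dict
    per_condition: dict
    peak_consistency: float
    notes: tuple = ()


def kde_density(values, bandwidth: float = 0.04) -> DensityCurve:
    """Gaussian-kernel density of E_app samples on the fixed FRET grid.

    Bandwidth default 0.04 FRET units. The curve is renormalized to unit
    trapezoidal integral over the grid.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise DataError("kde_density requires at least one finite value")
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be positive")
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth)
    kde.fit(x[:, None])
    dens = np.exp(kde.score_samples(FRET_GRID[:, None]))
    integral = np.trapezoid(dens, FRET_GRID)
    if integral > 0:
        dens = dens / integral
    return DensityCurve(
        grid=FRET_GRID.copy(), density=dens, bandwidth=float(bandwidth), n_points=len(x)
    )


def fit_gmm(values, K: int, init: HmmModel | None = None, seed=0) -> GmmFit:
    """Fit a K-component Gaussian mixture (per-component variances).

    When an HMM model is supplied, component means start at the HMM state
    means and weights at the HMM stationary occupancies; otherwise the
    deterministic quantile initialization is used. Components are reported
    in descending-mean order.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 10 * K:
        raise DataError(f"need at least {10 * K} points to fit a {K}-component GMM")
    if init is not None and init.n_states == K:
        means_init = np.asarray(init.means, dtype=float)[:, None]
        occ = init.initial_dist.copy()
        # stationary occupancy of the HMM chain as starting weights
        for _ in range(200):
            occ = occ @ init.transition_matrix
        occ = np.maximum(occ, 1e-6)
        weights_init = occ / occ.sum()
        precisions_init = np.full((K, 1, 1), 1.0 / init.shared_variance)
    else:
        levels = (np.arange(K) + 0.5) / K
        means_init = np.quantile(x, levels)[::-1].copy()[:, None]
        weights_init = np.full(K, 1.0 / K)
        precisions_init = np.full((K, 1, 1), 1.0 / max(np.var(x) / K, 1e-4))
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        reg_covar=GMM_VARIANCE_FLOOR,
        max_iter=500,
        tol=1e-6,
        n_init=1,
        weights_init=weights_init,
        means_init=means_init,
        precisions_init=precisions_init,
        random_state=int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)),
    )
    gm.fit(x[:, None])
    order = np.argsort(-gm.means_.ravel(), kind="stable")
    weights = gm.weights_.ravel()[order]
    means = gm.means_.ravel()[order]
    variances = gm.covariances_.reshape(K)[order]
    loglik = float(gm.score(x[:, None]) * n)
    p = 3 * K - 1
    return GmmFit(
        n_components=K,
        weights=weights,
        means=means,
        variances=np.maximum(variances, GMM_VARIANCE_FLOOR),
        loglik=loglik,
        n_params=p,
        bic=bic_value(loglik, p, n),
        n=n,
    )


def bic_value(loglik: float, n_params: int, n: int) -> float:
    """BIC = p ln(n) - 2 ln(L)."""
    if n < 1:
        raise DataError("BIC requires n >= 1")
    return float(n_params * np.log(n) - 2.0 * loglik)


def bic(fit: GmmFit, n: int) -> float:
    """BIC of a mixture fit evaluated at sample size ``n``."""
    return bic_value(fit.loglik, fit.n_params, n)


def select_state_count(
    trajectories_by_condition: dict,
    candidate_Ks=(2, 3, 4, 5),
    em_config: EmConfig | None = None,
    seed=0,
    peak_drift_flag: float = 0.05,
) -> SelectionResult:
    """Choose the number of conformational states for one receptor.

    For every candidate K and every condition: fit the global HMM, fit a
    GMM to the pooled E_app initialized from it, and compute the BIC on the
    pooled frames. The selected K minimizes the BIC summed across
    conditions (ties to the smaller K). For the selected K the spread of
    sorted GMM means across conditions is reported; a spread above
    ``peak_drift_flag`` FRET units raises a note.
    """
    candidate_Ks = tuple(sorted(candidate_Ks))
    if not trajectories_by_condition:
        raise DataError("at least one condition is required")
    for cond, trajs in trajectories_by_condition.items():
        if len(list(trajs)) == 0:
            raise DataError(f"condition {cond!r} has no accepted trajectories")

    per_condition: dict = {}
    bic_by_condition: dict = {}
    bic_total: dict = {}
    for K in candidate_Ks:
        per_condition[K] = {}
        bic_by_condition[K] = {}
        total = 0.0
        for cond, trajs in trajectories_by_condition.items():
            trajs = list(trajs)
            fit = em_fit(trajs, K, config=em_config, seed=seed)
            pooled = np.concatenate([t.e_app for t in trajs])
            gmm = fit_gmm(pooled, K, init=fit.model, seed=seed)
            per_condition[K][cond] = (fit, gmm)
            bic_by_condition[K][cond] = gmm.bic
            total += gmm.bic
        bic_total[K] = total

    selected_K = min(candidate_Ks, key=lambda K: (bic_total[K], K))

    # peak-position consistency across conditions at the selected K
    mean_sets = np.array(
        [per_condition[selected_K][c][1].means for c in trajectories_by_condition]
    )
    spread = float(np.max(mean_sets.max(axis=0) - mean_sets.min(axis=0)))
    notes = []
    if spread > peak_drift_flag:
        notes.append(
            f"peak positions drift by {spread:.3f} FRET units across conditions"
        )
    return SelectionResult(
        candidate_Ks=candidate_Ks,
        selected_K=int(selected_K),
        bic_total=bic_total,
        bic_by_condition=bic_by_condition,
        per_condition=per_condition,
        peak_consistency=spread,
        notes=tuple(notes),
    )


def save_selection(result: SelectionResult, path) -> None:
    """Serialize a SelectionResult (summary fields) to JSON."""
    payload = {
        "candidate_Ks": list(result.candidate_Ks),
        "selected_K": result.selected_K,
        "bic_total": {str(k): v for k, v in result.bic_total.items()},
        "bic_by_condition": {
            str(k): dict(v) for k, v in result.bic_by_condition.items()
        },
        "peak_consistency": result.peak_consistency,
        "gmm_means": {
            str(k): {c: list(fits[1].means) for c, fits in conds.items()}
            for k, conds in result.per_condition.items()
        },
        "notes": list(result.notes),
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
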