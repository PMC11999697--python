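"""Summary objects of the conformational landscape.

From fitted models and Viterbi-idealized paths this module derives the
quantities the analysis ultimately reports: fractional state populations,
per-state composite FRET histograms, transition density probability (TDP)
grids, dwell-time tables, and condition-to-condition population shifts.

TDP axes use the dwell-averaged *raw* apparent FRET before and after each
decoded transition rather than the fitted state means. This keeps distinct
underlying FRET levels distinguishable even when they share a model state,
which is what makes the classic mixed-labeling argument (four FRET levels
but only two TDP cross-peak pairs) testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter

from .errors import DataError, ValidationError
from .selection import DensityCurve, kde_density

__all__ = [
    "StatePopulations",
    "TransitionEvent",
    "TdpGrid",
    "DwellTable",
    "ConditionComparison",
    "TDP_GRID",
    "state_populations",
    "per_state_histograms",
    "extract_transitions",
    "build_tdp",
    "tdp_peaks",
    "count_cross_peak_pairs",
    "dwell_times",
    "compare_conditions",
]

#: Default TDP axis: 128 points per dimension spanning [-0.2, 1.2].
TDP_GRID = np.linspace(-0.2, 1.2, 128)


@dataclass(frozen=True)
class StatePopulations:
    """Frame-weighted fractional occupancy of each state for one condition."""

    condition: str
    fractions: np.ndarray
    n_frames: int
    n_traces: int

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f < 0) or np.any(f > 1) or abs(f.sum() - 1.0) > 1e-9:
            raise ValidationError("fractions must lie in [0,1] and sum to 1")
        object.__setattr__(self, "fractions", f)


@dataclass(frozen=True)
class TransitionEvent:
    """One decoded state-to-state switch.

    ``e_from``/``e_to`` are the mean raw E_app over the complete dwell
    before/after the switch; ``dwell_before`` is the duration of the
    preceding dwell in seconds.
    """

    trace_id: str
    from_state: int
    to_state: int
    e_from: float
    e_to: float
    dwell_before: float

    def __post_init__(self):
        if self.from_state == self.to_state:
            raise ValidationError("a transition must change state")
        if self.dwell_before <= 0:
            raise ValidationError("dwell_before must be positive")


@dataclass(frozen=True)
class TdpGrid:
    """2-D transition density over (initial FRET, final FRET)."""

    axes: np.ndarray
    density: np.ndarray
    n_transitions: int
    smoothing_sigma: float

    def __post_init__(self):
        ax = np.asarray(self.axes, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if d.shape != (len(ax), len(ax)):
            raise ValidationError("density must be square on the axis grid")
        if np.any(d < 0):
            raise ValidationError("density must be non-negative")
        object.__setattr__(self, "axes", ax)
        object.__setattr__(self, "density", d)

    @property
    def total_probability(self) -> float:
        step = self.axes[1] - self.axes[0]
        return float(self.density.sum() * step * step)


@dataclass(frozen=True)
class DwellTable:
    """Completed-dwell statistics per (state, condition)."""

    table: pd.DataFrame  # columns: state, condition, count, mean_s, rate_per_s
    samples: dict  # (state, condition) -> ndarray of dwell seconds
    flagged_empty: tuple = ()


@dataclass(frozen=True)
class ConditionComparison:
    """Per-state population deltas (b - a) in percentage points."""

    condition_a: str
    condition_b: str
    delta_fractions: np.ndarray
    group_deltas: dict

    def __post_init__(self):
        d = np.asarray(self.delta_fractions, dtype=float)
        if abs(d.sum()) > 1e-9:
            raise ValidationError("per-state deltas must sum to 0")
        object.__setattr__(self, "delta_fractions", d)


# ---------------------------------------------------------------------------


def state_populations(paths, K: int, condition: str = "") -> StatePopulations:
    """Fraction of frames Viterbi-assigned to each state."""
    paths = list(paths)
    if not paths:
        raise DataError("state_populations requires at least one path")
    counts = np.zeros(K, dtype=float)
    for p in paths:
        s = np.asarray(p.states, dtype=int)
        if s.max(initial=0) >= K:
            raise DataError(f"path {p.trace_id!r} contains labels >= K={K}")
        counts += np.bincount(s, minlength=K)
    total = counts.sum()
    if total == 0:
        raise DataError("no frames in the supplied paths")
    return StatePopulations(
        condition=condition,
        fractions=counts / total,
        n_frames=int(total),
        n_traces=len(paths),
    )


def per_state_histograms(trajectories, paths, bandwidth: float = 0.04):
    """Composite per-state KDE curves plus the overall envelope.

    Each state's curve is the KDE of the E_app values Viterbi-assigned to
    it, scaled by the state's occupancy fraction, so the state curves sum
    pointwise to the overall envelope (unit integral). States with zero
    assigned frames yield an empty (zero) curve and are flagged.

    Returns ``(state_curves, envelope, flagged_states)``.
    """
    trajectories = list(trajectories)
    paths = list(paths)
    if len(trajectories) != len(paths):
        raise DataError("trajectories and paths must be aligned")
    K = 0
    values_by_state: dict = {}
    all_values = []
    for traj, p in zip(trajectories, paths):
        s = np.asarray(p.states, dtype=int)
        if len(s) != len(traj.e_app):
            raise DataError(f"path/trajectory length mismatch for {traj.trace_id!r}")
        K = max(K, int(s.max()) + 1)
        for k in np.unique(s):
            values_by_state.setdefault(int(k), []).append(traj.e_app[s == k])
        all_values.append(traj.e_app)
    pooled = np.concatenate(all_values)
    n_total = len(pooled)

    from .selection import FRET_GRID

    state_curves = {}
    flagged = []
    for k in range(K):
        if k in values_by_state:
            vals = np.concatenate(values_by_state[k])
            curve = kde_density(vals, bandwidth)
            frac = len(vals) / n_total
            state_curves[k] = DensityCurve(
                grid=curve.grid,
                density=curve.density * frac,
                bandwidth=bandwidth,
                n_points=len(vals),
            )
        else:
            flagged.append(k)
            state_curves[k] = DensityCurve(
                grid=FRET_GRID.copy(),
                density=np.zeros_like(FRET_GRID),
                bandwidth=bandwidth,
                n_points=0,
            )
    env_density = np.sum([c.density for c in state_curves.values()], axis=0)
    envelope = DensityCurve(
        grid=FRET_GRID.copy(),
        density=env_density,
        bandwidth=bandwidth,
        n_points=n_total,
    )
    return state_curves, envelope, tuple(flagged)


def _runs(states: np.ndarray):
    """Decompose a label path into runs [(state, start, stop), ...]."""
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(states)]))
    return [(int(states[s]), int(s), int(e)) for s, e in zip(starts, stops)]


def extract_transitions(trajectories, paths, frame_interval: float = 0.1):
    """One TransitionEvent per consecutive label change in each path."""
    trajectories = list(trajectories)
    paths = list(paths)
    if len(trajectories) != len(paths):
        raise DataError("trajectories and paths must be aligned")
    events = []
    for traj, p in zip(trajectories, paths):
        runs = _runs(np.asarray(p.states, dtype=int))
        e = traj.e_app
        for (s1, a1, b1), (s2, a2, b2) in zip(runs[:-1], runs[1:]):
            events.append(
                TransitionEvent(
                    trace_id=p.trace_id,
                    from_state=s1,
                    to_state=s2,
                    e_from=float(np.mean(e[a1:b1])),
                    e_to=float(np.mean(e[a2:b2])),
                    dwell_before=(b1 - a1) * frame_interval,
                )
            )
    return events


def build_tdp(
    events,
    smoothing_sigma: float = 0.03,
    grid: np.ndarray | None = None,
) -> TdpGrid:
    """2-D Gaussian KDE of (e_from, e_to) pairs, normalized to total
    probability 1 over the grid. Zero events yield an empty (flagged by
    n_transitions == 0) grid, not an error."""
    if smoothing_sigma <= 0:
        raise ValidationError("smoothing_sigma must be positive")
    ax = TDP_GRID if grid is None else np.asarray(grid, dtype=float)
    events = list(events)
    n = len(events)
    density = np.zeros((len(ax), len(ax)))
    if n > 0:
        ef = np.array([ev.e_from for ev in events])
        et = np.array([ev.e_to for ev in events])
        # separable Gaussian kernels evaluated on the axis
        kx = np.exp(-0.5 * ((ax[:, None] - ef[None, :]) / smoothing_sigma) ** 2)
        ky = np.exp(-0.5 * ((ax[:, None] - et[None, :]) / smoothing_sigma) ** 2)
        density = kx @ ky.T  # (x=e_from, y=e_to) summed over events
        step = ax[1] - ax[0]
        density /= density.sum() * step * step
    return TdpGrid(
        axes=ax.copy(),
        density=density,
        n_transitions=n,
        smoothing_sigma=float(smoothing_sigma),
    )


def tdp_peaks(tdp: TdpGrid, threshold_frac: float = 0.1, min_offdiag: float = 0.0):
    """Local maxima of the TDP above ``threshold_frac`` of the global max.

    Returns a list of (e_from, e_to) peak coordinates; ``min_offdiag``
    optionally drops peaks closer than that to the diagonal.
    """
    d = tdp.density
    if tdp.n_transitions == 0 or d.max() <= 0:
        return []
    local_max = d == maximum_filter(d, size=3, mode="nearest")
    ok = local_max & (d >= threshold_frac * d.max())
    peaks = []
    for i, j in zip(*np.nonzero(ok)):
        x, y = float(tdp.axes[i]), float(tdp.axes[j])
        if abs(x - y) >= min_offdiag:
            peaks.append((x, y))
    return peaks


def count_cross_peak_pairs(peaks, tol: float = 0.06) -> int:
    """Number of unordered cross-peak pairs: peaks (a, b) and (b, a) that
    mirror each other across the diagonal within ``tol`` count once."""
    peaks = [p for p in peaks if abs(p[0] - p[1]) > tol]
    used = [False] * len(peaks)
    pairs = 0
    for i, (a, b) in enumerate(peaks):
        if used[i]:
            continue
        for j in range(i + 1, len(peaks)):
            if used[j]:
                continue
            c, d = peaks[j]
            if abs(a - d) <= tol and abs(b - c) <= tol:
                used[i] = used[j] = True
                pairs += 1
                break
    return pairs


def dwell_times(paths, frame_interval: float = 0.1, condition: str = "") -> DwellTable:
    """Completed-dwell table; the first and last dwell of every path are
    censored (their true extent is unobserved). Exponential rate = 1/mean."""
    samples: dict = {}
    max_state = -1
    for p in paths:
        runs = _runs(np.asarray(p.states, dtype=int))
        max_state = max(max_state, int(np.max(p.states)))
        for state, start, stop in runs[1:-1]:
            samples.setdefault((state, condition), []).append(
                (stop - start) * frame_interval
            )
    rows = []
    flagged = []
    sample_arrays = {}
    for state in range(max_state + 1):
        key = (state, condition)
        vals = np.asarray(samples.get(key, []), dtype=float)
        sample_arrays[key] = vals
        if len(vals) == 0:
            flagged.append(state)
            rows.append(
                {"state": state, "condition": condition, "count": 0,
                 "mean_s": np.nan, "rate_per_s": np.nan}
            )
        else:
            m = float(vals.mean())
            rows.append(
                {"state": state, "condition": condition, "count": len(vals),
                 "mean_s": m, "rate_per_s": 1.0 / m}
            )
    return DwellTable(
        table=pd.DataFrame(rows),
        samples=sample_arrays,
        flagged_empty=tuple(flagged),
    )


def compare_conditions(
    pop_a: StatePopulations, pop_b: StatePopulations, groups: dict | None = None
) -> ConditionComparison:
    """Per-state (and optional grouped) population shifts in percentage
    points, computed as (f_b - f_a) * 100."""
    if len(pop_a.fractions) != len(pop_b.fractions):
        raise DataError(
            "conditions have different state counts: "
            f"{len(pop_a.fractions)} vs {len(pop_b.fractions)}"
        )
    delta = (pop_b.fractions - pop_a.fractions) * 100.0
    group_deltas = {}
    if groups:
        for name, idx in groups.items():
            group_deltas[name] = float(np.sum(delta[list(idx)]))
    return ConditionComparison(
        condition_a=pop_a.condition,
        condition_b=pop_b.condition,
        delta_fractions=delta,
        group_deltas=group_deltas,
    )


# ---------------------------------------------------------------------------
# export helpers
# ---------------------------------------------------------------------------


def export_tdp_tsv(tdp: TdpGrid, path) -> None:
    """TDP grid as a TSV matrix with axis headers (rows = initial FRET)."""
    df = pd.DataFrame(
        tdp.density,
        index=[f"{v:.6f}" for v in tdp.axes],
        columns=[f"{v:.6f}" for v in tdp.axes],
    )
    df.index.name = "e_from\\e_to"
    df.to_csv(path, sep="\t", lineterminator="\n")


def export_populations_json(pops, path, extra: dict | None = None) -> None:
    payload = {
        p.condition: {
            "fractions": list(map(float, p.fractions)),
            "n_frames": p.n_frames,
            "n_traces": p.n_traces,
        }
        for p in pops
    }
    if extra:
        payload["_meta"] = extra
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
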