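"""Synthetic two-channel smFRET trace generator with known ground truth.

Emulates the statistical structure of prism-TIRF recordings of dye-labeled
membrane receptors: discrete Markov switching among a handful of
conformational states with seconds-scale dwells, state-dependent apparent
FRET, anti-correlated donor/acceptor intensities at roughly constant total
intensity, donor bleed-through, background offsets, and stochastic
single-step acceptor-only or simultaneous two-channel photobleaching.

The preset registry (:data:`PRESETS`) encodes named experimental conditions
for two chemokine receptors (CXCR4-like, three states R/R'/R*; ACKR3-like,
four states R/R'/R*'/R*) with ligand-induced stationary-population shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .traces import IntensityTrace

__all__ = [
    "ScenarioSpec",
    "NoiseSpec",
    "GroundTruth",
    "PRESETS",
    "DEFAULT_NOISE",
    "get_preset",
    "sequential_transition_matrix",
    "simulate_state_path",
    "simulate_trace",
    "simulate_experiment",
    "mixed_labeling_toy_events",
    "write_ground_truth",
    "read_ground_truth",
]

_ATOL = 1e-9


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative twin of the fitted hidden Markov model for one condition.

    Parameters
    ----------
    name : str
        Condition label (e.g. ``"apo-CXCR4"``).
    n_states : int
        Number of conformational states K, 1..6.
    state_means : tuple of float
        Apparent-FRET level of each state, strictly monotonic, in (0, 1).
        Presets order states descending (state 0 = highest FRET = R).
    shared_sigma : float
        Intended apparent-FRET emission standard deviation common to all
        states (the generator realizes it through ``NoiseSpec``).
    transition_matrix : ndarray, shape (K, K)
        Row-stochastic per-frame transition matrix.
    initial_dist : ndarray, shape (K,)
        Initial state distribution.
    frame_interval : float
        Seconds per frame (0.1 s = 100 ms camera integration).
    """

    name: str
    n_states: int
    state_means: tuple
    shared_sigma: float
    transition_matrix: np.ndarray
    initial_dist: np.ndarray
    frame_interval: float = 0.1

    def __post_init__(self):
        A = np.asarray(self.transition_matrix, dtype=float)
        pi = np.asarray(self.initial_dist, dtype=float)
        means = np.asarray(self.state_means, dtype=float)
        K = self.n_states
        if not (1 <= K <= 6):
            raise ValidationError(f"n_states must be in [1, 6], got {K}")
        if means.shape != (K,):
            raise ValidationError("state_means length must equal n_states")
        if np.any(means <= 0.0) or np.any(means >= 1.0):
            raise ValidationError("state_means must lie in the open interval (0, 1)")
        if K > 1:
            d = np.diff(means)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValidationError("state_means must be strictly monotonic")
            if np.min(np.abs(d)) <= 2 * np.finfo(float).eps:
                raise ValidationError("state_means must be pairwise distinct")
        if self.shared_sigma <= 0:
            raise ValidationError("shared_sigma must be positive")
        if A.shape != (K, K):
            raise ValidationError("transition_matrix must be K x K")
        if np.any(A < 0):
            raise ValidationError("transition_matrix entries must be non-negative")
        if np.max(np.abs(A.sum(axis=1) - 1.0)) > _ATOL:
            raise ValidationError("transition_matrix rows must sum to 1 within 1e-9")
        if pi.shape != (K,) or np.any(pi < 0):
            raise ValidationError("initial_dist must be a length-K non-negative vector")
        if abs(pi.sum() - 1.0) > _ATOL:
            raise ValidationError("initial_dist must sum to 1 within 1e-9")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be positive")
        object.__setattr__(self, "state_means", tuple(float(m) for m in means))
        object.__setattr__(self, "transition_matrix", A)
        object.__setattr__(self, "initial_dist", pi)

    @property
    def stationary_dist(self) -> np.ndarray:
        """Stationary distribution of the transition matrix (left Perron vector)."""
        w, v = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        p = np.real(v[:, i])
        p = np.abs(p)
        return p / p.sum()


@dataclass(frozen=True)
class NoiseSpec:
    """Detection-chain parameters for the synthetic camera traces.

    ``fret_jitter_sigma`` is a per-frame fluctuation of the emitted FRET
    efficiency around the state mean (intra-state donor-acceptor distance and
    dye-orientation noise); it produces the anti-correlated channel
    fluctuations seen within a single dwell of real traces.
    ``channel_noise_sigma`` is independent additive Gaussian read noise per
    channel. Hazards are per-frame bleaching probabilities.
    """

    total_intensity: float = 1000.0
    channel_noise_sigma: float = 30.0
    fret_jitter_sigma: float = 0.075
    bleedthrough_alpha: float = 0.0
    background_donor: float = 0.0
    background_acceptor: float = 0.0
    acceptor_bleach_hazard: float = 0.002
    simultaneous_bleach_hazard: float = 0.001
    post_bleach_frames_min: int = 30

    def __post_init__(self):
        for name in (
            "total_intensity",
            "channel_noise_sigma",
            "fret_jitter_sigma",
            "bleedthrough_alpha",
            "background_donor",
            "background_acceptor",
            "acceptor_bleach_hazard",
            "simultaneous_bleach_hazard",
            "post_bleach_frames_min",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not (0.0 <= self.bleedthrough_alpha <= 0.3):
            raise ValidationError("bleedthrough_alpha must be in [0, 0.3]")
        for name in ("acceptor_bleach_hazard", "simultaneous_bleach_hazard"):
            if getattr(self, name) >= 1.0:
                raise ValidationError(f"{name} must be < 1")


DEFAULT_NOISE = NoiseSpec()


@dataclass(frozen=True)
class GroundTruth:
    """Oracle record for one simulated trace."""

    state_path: np.ndarray
    bleach_frame: int | None
    bleach_class: str  # acceptor_only | simultaneous | none
    scenario: ScenarioSpec

    def __post_init__(self):
        path = np.asarray(self.state_path, dtype=int)
        K = self.scenario.n_states
        if path.ndim != 1 or len(path) < 1:
            raise ValidationError("state_path must be a non-empty 1-D sequence")
        if path.min() < 0 or path.max() >= K:
            raise ValidationError("state_path labels must lie in [0, K-1]")
        if self.bleach_class not in ("acceptor_only", "simultaneous", "none"):
            raise ValidationError(f"unknown bleach_class {self.bleach_class!r}")
        object.__setattr__(self, "state_path", path)


def sequential_transition_matrix(
    stationary, exchange_rates, *, atol: float = 1e-12
) -> np.ndarray:
    """Build a birth-death (adjacent-states-only) transition matrix.

    Detailed-balance construction: for the adjacent pair (i, i+1) with
    symmetric exchange rate ``s``, the per-frame rates are
    ``A[i, i+1] = s * min(1, pi[i+1]/pi[i])`` and
    ``A[i+1, i] = s * min(1, pi[i]/pi[i+1])``, which leaves ``stationary``
    invariant. Diagonals absorb the remainder.

    Parameters
    ----------
    stationary : array-like, shape (K,)
        Target stationary distribution (positive, sums to 1).
    exchange_rates : array-like, shape (K-1,)
        Per-frame symmetric exchange rate for each adjacent pair.
    """
    pi = np.asarray(stationary, dtype=float)
    s = np.atleast_1d(np.asarray(exchange_rates, dtype=float))
    K = len(pi)
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValidationError("stationary must be positive and sum to 1")
    if s.shape != (max(K - 1, 0),) and K > 1:
        raise ValidationError("exchange_rates must have length K-1")
    A = np.zeros((K, K))
    for i in range(K - 1):
        A[i, i + 1] = s[i] * min(1.0, pi[i + 1] / pi[i])
        A[i + 1, i] = s[i] * min(1.0, pi[i] / pi[i + 1])
    off = A.sum(axis=1)
    if np.any(off >= 1.0):
        raise ValidationError("exchange rates too large: diagonal would be negative")
    A[np.diag_indices(K)] = 1.0 - off
    assert np.max(np.abs(pi @ A - pi)) < 1e-9 + atol
    return A


def _preset(name, means, stationary, rates, sigma=0.08):
    pi = np.asarray(stationary, dtype=float)
    return ScenarioSpec(
        name=name,
        n_states=len(means),
        state_means=tuple(means),
        shared_sigma=sigma,
        transition_matrix=sequential_transition_matrix(pi, rates),
        initial_dist=pi,
        frame_interval=0.1,
    )


#: Named experimental-condition presets. State order is descending FRET:
#: CXCR4 (R, R', R*) and ACKR3 (R, R', R*', R*). Absolute stationary
#: fractions are documented modeling assumptions; the ligand presets encode
#: the headline population shifts (CXCL12 on CXCR4: R* +28 percentage
#: points; CXCL12 on ACKR3: R*+R*' +24 points) by construction.
PRESETS: dict[str, ScenarioSpec] = {
    "apo-CXCR4": _preset(
        "apo-CXCR4", (0.85, 0.59, 0.19), (0.75, 0.20, 0.05), (0.04, 0.05)
    ),
    "CXCL12-CXCR4": _preset(
        "CXCL12-CXCR4", (0.85, 0.59, 0.19), (0.47, 0.20, 0.33), (0.04, 0.05)
    ),
    "apo-ACKR3": _preset(
        "apo-ACKR3",
        (0.85, 0.66, 0.39, 0.11),
        (0.25, 0.25, 0.25, 0.25),
        (0.03, 0.03, 0.03),
    ),
    "CXCL12-ACKR3": _preset(
        "CXCL12-ACKR3",
        (0.85, 0.66, 0.39, 0.11),
        (0.14, 0.12, 0.32, 0.42),
        (0.03, 0.04, 0.04),
    ),
    "VUF16840-ACKR3": _preset(
        "VUF16840-ACKR3",
        (0.85, 0.66, 0.39, 0.11),
        (0.55, 0.25, 0.12, 0.08),
        (0.04, 0.04, 0.04),
    ),
    "Y257L-ACKR3": _preset(
        "Y257L-ACKR3",
        (0.85, 0.66, 0.39, 0.11),
        (0.60, 0.16, 0.12, 0.12),
        (0.02, 0.02, 0.02),
    ),
}


def get_preset(name: str) -> ScenarioSpec:
    """Look up a scenario preset by name; unknown names list the registry."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available presets: "
            + ", ".join(sorted(PRESETS))
        ) from None


def simulate_state_path(spec: ScenarioSpec, n_frames: int, seed) -> np.ndarray:
    """Draw a Markov state-label sequence of length ``n_frames``.

    The first label is drawn from ``spec.initial_dist``; each subsequent
    label from the transition-matrix row of its predecessor. Deterministic
    given ``seed``.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    cum_init = np.cumsum(spec.initial_dist)
    cum_rows = np.cumsum(spec.transition_matrix, axis=1)
    u = rng.random(n_frames)
    path = np.empty(n_frames, dtype=int)
    path[0] = np.searchsorted(cum_init, u[0], side="right")
    for t in range(1, n_frames):
        path[t] = np.searchsorted(cum_rows[path[t - 1]], u[t], side="right")
    np.clip(path, 0, spec.n_states - 1, out=path)
    return path


def _draw_bleach(n_frames: int, noise: NoiseSpec, rng) -> tuple[int | None, str]:
    """Sample (bleach_frame, bleach_class) from the per-frame hazards.

    The draw is truncated so that, whenever any hazard is positive, the
    bleach occurs no later than ``n_frames - post_bleach_frames_min``: the
    screen only retains molecules whose bleach step is observed, so a longer
    recording window is implied rather than simulated.
    """
    h_a, h_s = noise.acceptor_bleach_hazard, noise.simultaneous_bleach_hazard
    h = h_a + h_s
    if h <= 0:
        return None, "none"
    last = max(1, n_frames - int(noise.post_bleach_frames_min))
    # time of first event under combined hazard (geometric, support 1..)
    u = rng.random()
    t = int(np.ceil(np.log1p(-u) / np.log1p(-h))) if h < 1 else 1
    t = min(max(t, 1), last)
    cls = "acceptor_only" if rng.random() < h_a / h else "simultaneous"
    return t, cls


def simulate_trace(
    path,
    spec: ScenarioSpec,
    noise: NoiseSpec,
    seed,
    trace_id: str = "trace-0000",
) -> tuple[IntensityTrace, GroundTruth]:
    """Render a state path into a noisy two-channel intensity trace.

    Per frame, the emitted FRET is the state mean plus ``fret_jitter_sigma``
    fluctuation; ideal donor/acceptor split the total intensity accordingly.
    The recorded acceptor receives donor bleed-through and background; both
    channels receive independent Gaussian read noise. A bleach frame drawn
    from the hazards terminates the signal: acceptor-only bleaching zeroes
    the acceptor and returns the donor to the full total intensity (FRET
    stops), simultaneous bleaching zeroes both channels.
    """
    path = np.asarray(path, dtype=int)
    if path.ndim != 1 or len(path) < 2:
        raise ValidationError("path must be a 1-D sequence of length >= 2")
    if path.min() < 0 or path.max() >= spec.n_states:
        raise ValidationError("path labels must be valid state indices for spec")
    rng = np.random.default_rng(seed)
    n = len(path)
    T = noise.total_intensity

    e = np.asarray(spec.state_means)[path]
    if noise.fret_jitter_sigma > 0:
        e = e + rng.normal(0.0, noise.fret_jitter_sigma, size=n)
    ideal_d = T * (1.0 - e)
    ideal_a = T * e

    bleach_frame, bleach_class = _draw_bleach(n, noise, rng)
    if bleach_frame is not None:
        if bleach_class == "acceptor_only":
            ideal_a[bleach_frame:] = 0.0
            ideal_d[bleach_frame:] = T  # donor recovery: FRET stops
        else:
            ideal_a[bleach_frame:] = 0.0
            ideal_d[bleach_frame:] = 0.0

    donor = ideal_d + noise.background_donor
    acceptor = ideal_a + noise.bleedthrough_alpha * ideal_d + noise.background_acceptor
    if noise.channel_noise_sigma > 0:
        donor = donor + rng.normal(0.0, noise.channel_noise_sigma, size=n)
        acceptor = acceptor + rng.normal(0.0, noise.channel_noise_sigma, size=n)

    trace = IntensityTrace(
        trace_id=trace_id,
        donor=donor,
        acceptor=acceptor,
        frame_interval=spec.frame_interval,
        bleach_frame=bleach_frame,
        bleach_class=bleach_class,
    )
    truth = GroundTruth(
        state_path=path,
        bleach_frame=bleach_frame,
        bleach_class=bleach_class,
        scenario=spec,
    )
    return trace, truth


def _trace_seeds(master_seed, n_traces: int):
    """Stable per-trace integer seeds derived from the master seed.

    Uses ``numpy.random.SeedSequence(master_seed).spawn``, which is
    documented to be reproducible across platforms and numpy versions.
    """
    return np.random.SeedSequence(master_seed).spawn(n_traces)


def simulate_experiment(
    scenario_name: str,
    n_traces: int,
    n_frames: int,
    noise: NoiseSpec | None = None,
    seed=0,
) -> list[tuple[IntensityTrace, GroundTruth]]:
    """Simulate ``n_traces`` independent molecules from a named preset.

    Per-trace seeds are derived reproducibly from the master seed; the same
    (scenario, seed) pair yields bitwise-identical output.
    """
    spec = get_preset(scenario_name)
    noise = DEFAULT_NOISE if noise is None else noise
    out = []
    for i, child in enumerate(_trace_seeds(seed, n_traces)):
        path_rng, trace_rng = child.spawn(2)
        path = simulate_state_path(spec, n_frames, path_rng)
        trace, truth = simulate_trace(
            path, spec, noise, trace_rng, trace_id=f"{scenario_name}-{i:04d}"
        )
        out.append((trace, truth))
    return out


def mixed_labeling_toy_events(
    n_per_direction: int = 250,
    jitter_sigma: float = 0.02,
    seed=0,
    levels_a: tuple = (0.85, 0.55),
    levels_b: tuple = (0.70, 0.25),
):
    """Analytic two-orientation labeling toy for the TDP counterexample.

    Models a receptor with two conformations observed through two possible
    dye-labeling orientations. Each orientation contributes its own FRET
    level pair and transitions occur only *within* an orientation, so the
    model shows four distinct FRET levels but only two unordered cross-peak
    pairs in the transition density plot.

    Returns a list of ``landscape.TransitionEvent``.
    """
    from .landscape import TransitionEvent

    rng = np.random.default_rng(seed)
    events = []
    for pair in (levels_a, levels_b):
        for a, b in ((pair[0], pair[1]), (pair[1], pair[0])):
            for i in range(n_per_direction):
                events.append(
                    TransitionEvent(
                        trace_id=f"toy-{a:.2f}-{b:.2f}-{i}",
                        from_state=0,
                        to_state=1,
                        e_from=a + rng.normal(0.0, jitter_sigma),
                        e_to=b + rng.normal(0.0, jitter_sigma),
                        dwell_before=0.5,
                    )
                )
    return events


def _rle(path: np.ndarray) -> str:
    """Run-length encode an integer path as 'state:len,state:len,...'."""
    path = np.asarray(path, dtype=int)
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(path)]))
    return ",".join(f"{path[s]}:{e - s}" for s, e in zip(starts, ends))


def _unrle(text: str) -> np.ndarray:
    parts = [p.split(":") for p in text.split(",") if p]
    return np.concatenate([np.full(int(n), int(s), dtype=int) for s, n in parts])


def write_ground_truth(results, path) -> None:
    """Write a ground-truth sidecar: one TSV row per trace with trace_id,
    bleach_frame, bleach_class, and the run-length-encoded state path."""
    import io

    buf = io.StringIO()
    buf.write("trace_id\tbleach_frame\tbleach_class\tstate_path_rle\n")
    for trace, truth in results:
        bf = "" if truth.bleach_frame is None else str(truth.bleach_frame)
        buf.write(f"{trace.trace_id}\t{bf}\t{truth.bleach_class}\t{_rle(truth.state_path)}\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_ground_truth(path) -> dict:
    """Read a ground-truth sidecar into {trace_id: (state_path, bleach_frame,
    bleach_class)}."""
    out = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["trace_id", "bleach_frame", "bleach_class", "state_path_rle"]:
            raise ValueError(f"unexpected ground-truth header in {path}")
        for line in fh:
            tid, bf, cls, rle = line.rstrip("\n").split("\t")
            out[tid] = (_unrle(rle), None if bf == "" else int(bf), cls)
    return out
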