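"""Trace data model, file I/O, corrections, FRET computation and screening.

A molecule's recording is a pair of per-frame donor/acceptor intensities
(``IntensityTrace``). The processing chain mirrors standard smFRET practice:
subtract background and donor bleed-through, locate the photobleach step
that terminates the usable segment, compute the apparent FRET efficiency
E_app = I_A / (I_A + I_D) over the pre-bleach frames, and screen traces for
the single-molecule signature (exactly one bleach event, anti-correlated
channels, sufficient length).

File exchange format ("SMT-TSV"): a UTF-8 tab-separated file with header
``trace_id  frame_index  donor  acceptor`` sorted by (trace_id, frame_index),
frame_index contiguous from 0 per trace, plus a JSON manifest
(``<basename>.manifest.json``) carrying frame interval, units and
correction state.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    CorrectionStateError,
    DataError,
    ParseError,
    ValidationError,
)

__all__ = [
    "IntensityTrace",
    "CorrectionParams",
    "FretTrajectory",
    "ScreenReport",
    "StepDetectConfig",
    "ScreenConfig",
    "BleachDetection",
    "StepEvent",
    "read_traces",
    "write_traces",
    "correct_intensities",
    "compute_fret",
    "detect_photobleach",
    "screen_trace",
]

BLEACH_CLASSES = ("acceptor_only", "simultaneous", "none")


@dataclass(frozen=True)
class IntensityTrace:
    """Two-channel intensity time series for one molecule.

    ``bleach_frame`` is the first post-bleach frame (0-indexed); the
    pre-bleach segment is the half-open interval ``[0, bleach_frame)``.
    """

    trace_id: str
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float = 0.1
    bleach_frame: int | None = None
    bleach_class: str = "none"
    corrected: bool = False

    def __post_init__(self):
        d = np.asarray(self.donor, dtype=float)
        a = np.asarray(self.acceptor, dtype=float)
        if d.ndim != 1 or a.ndim != 1 or len(d) != len(a):
            raise ValidationError("donor and acceptor must be 1-D and equal length")
        if len(d) < 2:
            raise ValidationError("traces must have length >= 2")
        if not np.all(np.isfinite(d)) or not np.all(np.isfinite(a)):
            raise ValidationError("intensities must be finite")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be positive")
        if self.bleach_frame is not None and not (
            1 <= self.bleach_frame <= len(d) - 1
        ):
            raise ValidationError("bleach_frame must lie in [1, length-1]")
        if self.bleach_class not in BLEACH_CLASSES:
            raise ValidationError(f"unknown bleach_class {self.bleach_class!r}")
        object.__setattr__(self, "donor", d)
        object.__setattr__(self, "acceptor", a)

    def __len__(self) -> int:
        return len(self.donor)

    @property
    def prebleach_slice(self) -> slice:
        end = len(self) if self.bleach_frame is None else self.bleach_frame
        return slice(0, end)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


@dataclass(frozen=True)
class CorrectionParams:
    """Donor bleed-through fraction and per-channel background offsets."""

    bleedthrough_alpha: float = 0.0
    background_donor: float = 0.0
    background_acceptor: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.bleedthrough_alpha <= 0.3):
            raise ValidationError("bleedthrough_alpha must be in [0, 0.3]")
        if not np.isfinite(self.background_donor) or not np.isfinite(
            self.background_acceptor
        ):
            raise ValidationError("backgrounds must be finite")


@dataclass(frozen=True)
class FretTrajectory:
    """Per-frame apparent FRET efficiency, truncated at the first bleach.

    Values are not clamped to [0, 1]; channel noise legitimately pushes
    E_app outside the unit interval and the Gaussian emission model relies
    on that structure being preserved.
    """

    trace_id: str
    e_app: np.ndarray
    frame_interval: float = 0.1
    n_dropped: int = 0

    def __post_init__(self):
        e = np.asarray(self.e_app, dtype=float)
        if e.ndim != 1 or len(e) < 1:
            raise ValidationError("e_app must be a non-empty 1-D series")
        if not np.all(np.isfinite(e)):
            raise ValidationError("e_app values must be finite")
        object.__setattr__(self, "e_app", e)

    @property
    def n_frames(self) -> int:
        return len(self.e_app)

    def __len__(self) -> int:
        return len(self.e_app)


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of the automated single-molecule screen for one trace."""

    trace_id: str
    accepted: bool
    reasons: tuple
    anticorrelation: float
    n_detected_steps_acceptor: int
    n_detected_steps_total: int

    def __post_init__(self):
        if self.accepted != (len(self.reasons) == 0):
            raise ValidationError("accepted must be True iff reasons is empty")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["trace_id", "frame_index", "donor", "acceptor"]
_FORMAT_VERSION = "1.0"


def _manifest_path(path) -> str:
    base, _ = os.path.splitext(os.fspath(path))
    return base + ".manifest.json"


def write_traces(traces, path) -> None:
    """Write traces to SMT-TSV plus a JSON manifest, deterministically.

    Rows are sorted by (trace_id, frame_index); floats are rendered with
    repr-round-trip precision so writing the same traces twice yields
    byte-identical files.
    """
    traces = list(traces)
    lines = ["\t".join(_COLUMNS)]
    per_trace = {}
    for tr in sorted(traces, key=lambda t: t.trace_id):
        for i in range(len(tr)):
            lines.append(
                f"{tr.trace_id}\t{i}\t{float(tr.donor[i])!r}\t{float(tr.acceptor[i])!r}"
            )
        meta = {"n_frames": len(tr)}
        if tr.bleach_frame is not None:
            meta["bleach_frame"] = int(tr.bleach_frame)
            meta["bleach_class"] = tr.bleach_class
        per_trace[tr.trace_id] = meta
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    frame_interval = traces[0].frame_interval if traces else 0.1
    corrected = bool(traces[0].corrected) if traces else False
    manifest = {
        "format_version": _FORMAT_VERSION,
        "frame_interval_s": frame_interval,
        "channel_units": "au",
        "correction_state": "corrected" if corrected else "raw",
        "traces": per_trace,
    }
    with open(_manifest_path(path), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_traces(path) -> list[IntensityTrace]:
    """Read an SMT-TSV file (and its manifest) back into IntensityTrace objects.

    Raises :class:`ParseError` naming the file and rule for missing columns,
    duplicate or non-contiguous frame indices.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", dtype={"trace_id": str}, float_precision="round_trip"
        )
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: cannot parse SMT-TSV ({exc})") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if df[["trace_id", "frame_index"]].duplicated().any():
        dup = df[df[["trace_id", "frame_index"]].duplicated()].iloc[0]
        raise ParseError(
            f"{path}: duplicate (trace_id, frame_index) = "
            f"({dup['trace_id']}, {dup['frame_index']})"
        )
    manifest = {}
    mpath = _manifest_path(path)
    if os.path.exists(mpath):
        with open(mpath, encoding="utf-8") as fh:
            manifest = json.load(fh)
    frame_interval = float(manifest.get("frame_interval_s", 0.1))
    corrected = manifest.get("correction_state", "raw") == "corrected"
    per_trace = manifest.get("traces", {})

    out = []
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("frame_index")
        idx = grp["frame_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ParseError(
                f"{path}: frame_index for trace {tid!r} must be contiguous from 0"
            )
        meta = per_trace.get(str(tid), {})
        out.append(
            IntensityTrace(
                trace_id=str(tid),
                donor=grp["donor"].to_numpy(dtype=float),
                acceptor=grp["acceptor"].to_numpy(dtype=float),
                frame_interval=frame_interval,
                bleach_frame=meta.get("bleach_frame"),
                bleach_class=meta.get("bleach_class", "none"),
                corrected=corrected,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Corrections and FRET
# ---------------------------------------------------------------------------


def correct_intensities(trace: IntensityTrace, params: CorrectionParams) -> IntensityTrace:
    """Subtract backgrounds and donor bleed-through.

    donor' = donor - background_donor;
    acceptor' = acceptor - background_acceptor - alpha * donor'.
    Negative values are permitted (no flooring) so the additive noise
    structure survives for the Gaussian emission model. Applying the
    correction twice is a state error.
    """
    if trace.corrected:
        raise CorrectionStateError(
            f"trace {trace.trace_id!r} has already been corrected"
        )
    donor = trace.donor - params.background_donor
    acceptor = trace.acceptor - params.background_acceptor - params.bleedthrough_alpha * donor
    return replace(trace, donor=donor, acceptor=acceptor, corrected=True)


#: Frames whose summed intensity falls at or below this floor are dropped
#: from the FRET trajectory (the ratio is numerically meaningless there).
DENOMINATOR_FLOOR = 1e-9


def compute_fret(trace: IntensityTrace) -> FretTrajectory:
    """Apparent FRET efficiency E_app = I_A / (I_A + I_D) per pre-bleach frame.

    Frames with I_A + I_D <= the denominator floor are dropped and counted
    in ``n_dropped``. An all-degenerate trace raises :class:`DataError`.
    """
    sl = trace.prebleach_slice
    d = trace.donor[sl]
    a = trace.acceptor[sl]
    denom = d + a
    keep = denom > DENOMINATOR_FLOOR
    if not np.any(keep):
        raise DataError(
            f"trace {trace.trace_id!r}: all pre-bleach frames have degenerate "
            "total intensity"
        )
    e = a[keep] / denom[keep]
    return FretTrajectory(
        trace_id=trace.trace_id,
        e_app=e,
        frame_interval=trace.frame_interval,
        n_dropped=int(np.sum(~keep)),
    )


# ---------------------------------------------------------------------------
# Photobleach step detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepDetectConfig:
    """Settings for the change-point scan.

    ``z_threshold`` is the Welch-type standardized mean difference
    |m1 - m2| / (sigma * sqrt(1/n1 + 1/n2)) a split must reach, with sigma
    the robust per-channel noise scale from first differences. Bleach-like
    events must additionally land at the channel's background level: the
    post-event segment mean must lie within
    max(zero_tol_frac * signal span, zero_tol_z * sigma / sqrt(n_post)) of
    the lowest inter-event segment mean of the trace.
    """

    z_threshold: float = 5.0
    min_segment: int = 5
    max_depth: int = 4
    simultaneity_window: int = 1
    zero_tol_frac: float = 0.05
    zero_tol_z: float = 3.0


@dataclass(frozen=True)
class StepEvent:
    """A detected step in one channel."""

    frame: int
    channel: str  # "acceptor" | "total"
    mean_before: float
    mean_after: float
    score: float

    @property
    def downward(self) -> bool:
        return self.mean_after < self.mean_before


@dataclass(frozen=True)
class BleachDetection:
    """Result of :func:`detect_photobleach`."""

    bleach_frame: int | None
    bleach_class: str
    n_steps_acceptor: int
    n_steps_total: int
    events: tuple


def _robust_sigma(x: np.ndarray) -> float:
    """Noise scale from median absolute first difference (step-insensitive)."""
    d = np.abs(np.diff(x))
    if len(d) == 0:
        return 0.0
    return float(np.median(d)) * 1.4826 / np.sqrt(2.0)


def _best_split(x, lo, hi, min_seg, sigma):
    """Exhaustive scan of split frames in [lo+min_seg, hi-min_seg).

    Returns (frame, score, m1, m2) for the best split or None. The score is
    the standardized two-sample mean difference; with sigma == 0 any
    non-zero mean difference scores infinite.
    """
    n = hi - lo
    if n < 2 * min_seg:
        return None
    seg = x[lo:hi]
    csum = np.concatenate(([0.0], np.cumsum(seg)))
    splits = np.arange(min_seg, n - min_seg + 1)
    n1 = splits.astype(float)
    n2 = n - n1
    m1 = csum[splits] / n1
    m2 = (csum[n] - csum[splits]) / n2
    diff = np.abs(m1 - m2)
    se = np.sqrt(1.0 / n1 + 1.0 / n2)
    # a noiseless channel still ranks candidate splits by mean difference
    sigma_eff = sigma if sigma > 0 else 1e-12 * max(1.0, float(np.ptp(seg)))
    score = diff / (sigma_eff * se)
    i = int(np.argmax(score))
    return lo + int(splits[i]), float(score[i]), float(m1[i]), float(m2[i])


def _scan_channel(x, cfg: StepDetectConfig, channel: str) -> list[StepEvent]:
    """Depth-limited binary segmentation with the standardized-step statistic."""
    sigma = _robust_sigma(x)
    events: list[StepEvent] = []

    def recurse(lo, hi, depth):
        if depth > cfg.max_depth:
            return
        best = _best_split(x, lo, hi, cfg.min_segment, sigma)
        if best is None:
            return
        t, score, m1, m2 = best
        if score < cfg.z_threshold:
            return
        events.append(
            StepEvent(frame=t, channel=channel, mean_before=m1, mean_after=m2, score=score)
        )
        recurse(lo, t, depth + 1)
        recurse(t, hi, depth + 1)

    recurse(0, len(x), 1)
    events.sort(key=lambda ev: ev.frame)
    return events


def _segment_means(x, events):
    """Means of the segments delimited by the detected events."""
    bounds = [0] + [e.frame for e in events] + [len(x)]
    return [
        (lo, hi, float(np.mean(x[lo:hi])))
        for lo, hi in zip(bounds[:-1], bounds[1:])
        if hi > lo
    ]


def _bleach_like(x, events, ev_index, cfg: StepDetectConfig, sigma) -> bool:
    """True if the event's post segment sits at the channel's lowest level.

    The background of a bleached channel is the lowest inter-event segment
    mean of the trace (the post-bleach tail); a conformational transition
    lands at a FRET level that still sits above it.
    """
    segs = _segment_means(x, events)
    frame = events[ev_index].frame
    post = next((s for s in segs if s[0] == frame), None)
    if post is None:
        return False
    lo, hi, m_post = post
    m_min = min(m for _, _, m in segs)
    span = float(np.max(x) - np.min(x))
    tol = max(
        cfg.zero_tol_frac * span,
        cfg.zero_tol_z * sigma / np.sqrt(hi - lo),
    )
    return m_post - m_min <= tol


def detect_photobleach(
    trace: IntensityTrace, config: StepDetectConfig | None = None
) -> BleachDetection:
    """Locate and classify the photobleach step of a trace.

    Change points are found independently in the acceptor channel and in the
    total intensity by an exhaustive standardized-step scan (binary
    segmentation). Downward steps that land at the channel background are
    bleach-like; the *last* such event is the photobleach (the terminal loss
    of signal). Events present in the total channel mark simultaneous
    two-channel loss; acceptor-only events mark acceptor bleaching. Absence
    of any qualifying step returns ``bleach_frame=None`` and class
    ``"none"`` (handled downstream by screening).
    """
    cfg = config or StepDetectConfig()
    if len(trace) < 2 * cfg.min_segment:
        raise ValidationError(
            f"trace {trace.trace_id!r} shorter than 2 x min_segment"
        )
    acc = trace.acceptor
    tot = trace.total
    sig_a = _robust_sigma(acc)
    sig_t = _robust_sigma(tot)
    ev_a = _scan_channel(acc, cfg, "acceptor")
    ev_t = _scan_channel(tot, cfg, "total")

    frames_a = sorted(e.frame for e in ev_a)

    def _post_stop(frame):
        later = [f for f in frames_a if f > frame]
        return later[0] if later else len(acc)

    bleach_a = [
        e
        for i, e in enumerate(ev_a)
        if e.downward and _bleach_like(acc, ev_a, i, cfg, sig_a)
    ]
    bleach_t = [
        e
        for i, e in enumerate(ev_t)
        if e.downward and _bleach_like(tot, ev_t, i, cfg, sig_t)
    ]

    # Merge acceptor/total bleach-like events. A total-intensity event within
    # the simultaneity window is the same physical event; a total event that
    # falls *inside* an acceptor event's post segment supersedes it (the
    # acceptor scan could not resolve the final low-FRET sub-step before the
    # full two-channel loss). Each merged event is classified by whether the
    # donor itself drops there: simultaneous loss takes the donor down with
    # the acceptor, while acceptor-only bleaching leaves the donor level or
    # recovering upward.
    sig_d = _robust_sigma(trace.donor)

    def _classify(frame) -> str:
        w = 20
        lo = max(0, frame - w)
        hi = min(len(trace), frame + w)
        if frame - lo < 2 or hi - frame < 2:
            return "simultaneous"
        pre = trace.donor[lo:frame]
        post = trace.donor[frame:hi]
        drop = float(np.mean(pre) - np.mean(post))
        thresh = 3.0 * sig_d * np.sqrt(1.0 / len(pre) + 1.0 / len(post))
        return "simultaneous" if drop > thresh else "acceptor_only"

    merged: list[tuple[int, str]] = []
    used_t = set()
    for ea in bleach_a:
        stop = _post_stop(ea.frame)
        match = None
        for j, et in enumerate(bleach_t):
            if j in used_t:
                continue
            if (
                abs(et.frame - ea.frame) <= cfg.simultaneity_window
                or ea.frame < et.frame < stop
            ):
                match = j
                break
        if match is not None:
            used_t.add(match)
            merged.append((bleach_t[match].frame, _classify(bleach_t[match].frame)))
        else:
            merged.append((ea.frame, _classify(ea.frame)))
    for j, et in enumerate(bleach_t):
        if j not in used_t:
            merged.append((et.frame, _classify(et.frame)))
    merged.sort()

    if merged:
        frame, cls = merged[-1]
    else:
        frame, cls = None, "none"
    return BleachDetection(
        bleach_frame=frame,
        bleach_class=cls,
        n_steps_acceptor=len(bleach_a),
        n_steps_total=len(merged),
        events=tuple(ev_a + ev_t),
    )


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the automated single-molecule screen."""

    anticorrelation_max: float = -0.2
    min_prebleach_frames: int = 20
    step: StepDetectConfig = field(default_factory=StepDetectConfig)


def screen_trace(
    trace: IntensityTrace,
    config: ScreenConfig | None = None,
    detection: BleachDetection | None = None,
) -> ScreenReport:
    """Automated stand-in for the manual single-molecule screen.

    A trace is accepted iff (a) exactly one qualifying bleach event was
    detected, (b) the pre-bleach donor/acceptor Pearson correlation is at or
    below the anticorrelation threshold, and (c) the pre-bleach segment is
    long enough. ``reasons`` lists every failed rule:
    ``no_bleach_step``, ``multi_step``, ``too_short``, ``no_dynamics``,
    ``poor_anticorrelation``.
    """
    cfg = config or ScreenConfig()
    det = detection if detection is not None else detect_photobleach(trace, cfg.step)
    reasons = []
    if det.n_steps_total == 0:
        reasons.append("no_bleach_step")
    elif det.n_steps_total > 1:
        reasons.append("multi_step")

    end = det.bleach_frame if det.bleach_frame is not None else len(trace)
    d = trace.donor[:end]
    a = trace.acceptor[:end]
    if end < cfg.min_prebleach_frames:
        reasons.append("too_short")
    corr = np.nan
    if len(d) >= 2:
        sd_d, sd_a = float(np.std(d)), float(np.std(a))
        if sd_d == 0.0 or sd_a == 0.0:
            reasons.append("no_dynamics")
        else:
            corr = float(np.corrcoef(d, a)[0, 1])
            if not (corr <= cfg.anticorrelation_max):
                reasons.append("poor_anticorrelation")
    else:
        reasons.append("no_dynamics")
    return ScreenReport(
        trace_id=trace.trace_id,
        accepted=len(reasons) == 0,
        reasons=tuple(reasons),
        anticorrelation=corr,
        n_detected_steps_acceptor=det.n_steps_acceptor,
        n_detected_steps_total=det.n_steps_total,
    )
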