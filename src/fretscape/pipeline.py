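"""Convenience orchestration of the standard analysis chain.

simulate/load -> correct -> detect bleach -> screen -> E_app ->
global HMM -> Viterbi -> populations / transitions / TDP / dwells.

These helpers are what the CLI and the worked examples call; each stage
remains individually accessible through its own module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import hmm, landscape, traces as tr
from .errors import DataError
from .traces import CorrectionParams, ScreenConfig

__all__ = ["ScreenedCondition", "screen_condition", "ConditionAnalysis", "analyze_condition"]


@dataclass(frozen=True)
class ScreenedCondition:
    """Screened, corrected trajectories of one experimental condition."""

    condition: str
    trajectories: list
    reports: list
    n_input: int

    @property
    def n_accepted(self) -> int:
        return len(self.trajectories)

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_input if self.n_input else 0.0


def screen_condition(
    intensity_traces,
    condition: str = "",
    correction: CorrectionParams | None = None,
    screen: ScreenConfig | None = None,
) -> ScreenedCondition:
    """Correct, bleach-detect and screen raw traces; return accepted
    FRET trajectories (truncated at the detected bleach)."""
    correction = correction or CorrectionParams()
    screen = screen or ScreenConfig()
    trajs, reports = [], []
    n_input = 0
    for trace in intensity_traces:
        n_input += 1
        corrected = tr.correct_intensities(trace, correction) if not trace.corrected else trace
        det = tr.detect_photobleach(corrected, screen.step)
        corrected = tr.IntensityTrace(
            trace_id=corrected.trace_id,
            donor=corrected.donor,
            acceptor=corrected.acceptor,
            frame_interval=corrected.frame_interval,
            bleach_frame=det.bleach_frame,
            bleach_class=det.bleach_class,
            corrected=True,
        )
        report = tr.screen_trace(corrected, screen, detection=det)
        reports.append(report)
        if report.accepted:
            trajs.append(tr.compute_fret(corrected))
    return ScreenedCondition(
        condition=condition, trajectories=trajs, reports=reports, n_input=n_input
    )


@dataclass(frozen=True)
class ConditionAnalysis:
    """Fitted model, idealized paths and landscape summaries for one condition."""

    condition: str
    fit: hmm.FitResult
    paths: list
    populations: landscape.StatePopulations
    events: list
    tdp: landscape.TdpGrid
    dwells: landscape.DwellTable


def analyze_condition(
    screened: ScreenedCondition,
    K: int,
    em_config: hmm.EmConfig | None = None,
    seed=0,
    smoothing_sigma: float = 0.03,
) -> ConditionAnalysis:
    """Fit the K-state global HMM and derive all landscape summaries."""
    trajs = screened.trajectories
    if not trajs:
        raise DataError(f"condition {screened.condition!r} has no accepted trajectories")
    fit = hmm.em_fit(trajs, K, config=em_config, seed=seed)
    paths = hmm.viterbi_all(trajs, fit.model)
    pops = landscape.state_populations(paths, K, condition=screened.condition)
    frame_interval = trajs[0].frame_interval
    events = landscape.extract_transitions(trajs, paths, frame_interval)
    tdp = landscape.build_tdp(events, smoothing_sigma=smoothing_sigma)
    dwells = landscape.dwell_times(paths, frame_interval, condition=screened.condition)
    return ConditionAnalysis(
        condition=screened.condition,
        fit=fit,
        paths=paths,
        populations=pops,
        events=events,
        tdp=tdp,
        dwells=dwells,
    )
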