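"""Trace I/O, corrections, FRET computation, bleach detection, screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretscape import pipeline
from fretscape.errors import CorrectionStateError, DataError, ParseError
from fretscape.simulate import DEFAULT_NOISE, NoiseSpec, simulate_experiment, simulate_state_path, simulate_trace
from fretscape.traces import (
    CorrectionParams,
    IntensityTrace,
    compute_fret,
    correct_intensities,
    detect_photobleach,
    read_traces,
    screen_trace,
    write_traces,
)


def _trace(donor, acceptor, **kw):
    return IntensityTrace("t0", np.asarray(donor, float), np.asarray(acceptor, float), **kw)


# --------------------------------------------------------------------- I/O


def test_round_trip_is_value_identical(tmp_path):
    traces = [t for t, _ in simulate_experiment("apo-CXCR4", 3, 50, seed=2)]
    p = tmp_path / "traces.tsv"
    write_traces(traces, p)
    loaded = read_traces(p)
    assert [t.trace_id for t in loaded] == [t.trace_id for t in traces]
    for a, b in zip(traces, loaded):
        assert np.array_equal(a.donor, b.donor)
        assert np.array_equal(a.acceptor, b.acceptor)
        assert a.frame_interval == b.frame_interval
        assert a.bleach_frame == b.bleach_frame


def test_writing_twice_is_byte_identical(tmp_path):
    traces = [t for t, _ in simulate_experiment("apo-ACKR3", 2, 40, seed=3)]
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_traces(traces, p1)
    write_traces(traces, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert (tmp_path / "a.manifest.json").read_text() == (
        tmp_path / "b.manifest.json"
    ).read_text()


def test_empty_collection_writes_valid_header_only_file(tmp_path):
    p = tmp_path / "empty.tsv"
    write_traces([], p)
    assert p.read_text().startswith("trace_id\tframe_index")
    assert read_traces(p) == []


def test_ragged_lengths_load_independently(tmp_path):
    t1 = _trace(np.arange(10.0) + 100, np.arange(10.0) + 50)
    t2 = IntensityTrace("t1", np.full(25, 5.0), np.full(25, 7.0))
    p = tmp_path / "ragged.tsv"
    write_traces([t1, t2], p)
    loaded = {t.trace_id: t for t in read_traces(p)}
    assert len(loaded["t0"]) == 10 and len(loaded["t1"]) == 25


@pytest.mark.parametrize(
    "content,match",
    [
        ("trace_id\tframe_index\tacceptor\n a\t0\t1\n", "missing required column"),
        (
            "trace_id\tframe_index\tdonor\tacceptor\na\t0\t1\t1\na\t0\t2\t2\n",
            "duplicate",
        ),
        (
            "trace_id\tframe_index\tdonor\tacceptor\na\t0\t1\t1\na\t2\t2\t2\n",
            "contiguous",
        ),
    ],
)
def test_malformed_files_raise_parse_errors(tmp_path, content, match):
    p = tmp_path / "bad.tsv"
    p.write_text(content)
    with pytest.raises(ParseError, match=match):
        read_traces(p)


# ------------------------------------------------------------- corrections


def test_correction_formula_and_identity():
    t = _trace([100.0, 100.0], [60.0, 60.0])
    out = correct_intensities(
        t, CorrectionParams(bleedthrough_alpha=0.1, background_acceptor=10.0)
    )
    assert np.allclose(out.donor, 100.0)
    assert np.allclose(out.acceptor, 60.0 - 10.0 - 0.1 * 100.0)  # = 40
    ident = correct_intensities(t, CorrectionParams())
    assert np.array_equal(ident.donor, t.donor)
    assert np.array_equal(ident.acceptor, t.acceptor)


def test_correction_allows_negative_values_and_forbids_double_application():
    t = _trace([100.0, 100.0], [50.0, 50.0])
    out = correct_intensities(t, CorrectionParams(background_acceptor=100.0))
    assert np.all(out.acceptor < 0)
    with pytest.raises(CorrectionStateError):
        correct_intensities(out, CorrectionParams())


def test_correction_inverts_simulator_contamination(two_state_spec, quiet_noise):
    from dataclasses import replace

    noise = replace(
        quiet_noise,
        bleedthrough_alpha=0.1,
        background_donor=40.0,
        background_acceptor=60.0,
        acceptor_bleach_hazard=0.01,
    )
    path = simulate_state_path(two_state_spec, 200, seed=4)
    trace, truth = simulate_trace(path, two_state_spec, noise, seed=5)
    out = correct_intensities(
        trace,
        CorrectionParams(
            bleedthrough_alpha=0.1, background_donor=40.0, background_acceptor=60.0
        ),
    )
    end = truth.bleach_frame
    e = out.acceptor[:end] / (out.acceptor[:end] + out.donor[:end])
    assert np.max(np.abs(e - np.asarray(two_state_spec.state_means)[path[:end]])) < 1e-9


# ------------------------------------------------------------------- FRET


@pytest.mark.parametrize(
    "donor,acceptor,expected",
    [(100.0, 100.0, 0.5), (0.0, 50.0, 1.0), (150.0, 50.0, 0.25)],
)
def test_apparent_fret_formula(donor, acceptor, expected):
    t = _trace([donor, donor], [acceptor, acceptor])
    traj = compute_fret(t)
    assert traj.e_app == pytest.approx([expected, expected])


def test_fret_truncates_at_bleach_and_drops_degenerate_frames():
    donor = np.array([100.0, 0.0, 100.0, 5.0, 5.0])
    acceptor = np.array([100.0, 0.0, 100.0, 5.0, 5.0])
    t = _trace(donor, acceptor, bleach_frame=3)
    traj = compute_fret(t)
    assert len(traj) == 2 and traj.n_dropped == 1
    with pytest.raises(DataError, match="degenerate"):
        compute_fret(_trace([0.0, 0.0], [0.0, 0.0]))


# -------------------------------------------------------------- detection


def test_noiseless_acceptor_step_detected_exactly():
    donor = np.full(400, 300.0)
    acceptor = np.concatenate([np.full(200, 500.0), np.full(200, 20.0)])
    det = detect_photobleach(_trace(donor, acceptor))
    assert det.bleach_frame == 200
    assert det.bleach_class == "acceptor_only"
    assert det.n_steps_total == 1


def test_noisy_step_location_matches_exhaustive_oracle():
    rng = np.random.default_rng(5)
    donor = np.full(400, 300.0) + rng.normal(0, 10, 400)
    acceptor = (
        np.concatenate([np.full(200, 500.0), np.full(200, 20.0)])
        + rng.normal(0, 10, 400)
    )
    det = detect_photobleach(_trace(donor, acceptor))

    # independent oracle: scan every split of the acceptor channel for the
    # largest standardized mean difference
    best, best_score = None, -np.inf
    for t in range(5, 396):
        m1, m2 = acceptor[:t].mean(), acceptor[t:].mean()
        se = np.sqrt(1.0 / t + 1.0 / (400 - t))
        score = abs(m1 - m2) / se
        if score > best_score:
            best, best_score = t, score
    assert abs(det.bleach_frame - best) <= 1
    assert abs(det.bleach_frame - 200) <= 1


def test_constant_trace_has_no_bleach():
    det = detect_photobleach(_trace(np.full(100, 300.0), np.full(100, 200.0)))
    assert det.bleach_frame is None and det.bleach_class == "none"


def test_simultaneous_loss_classified_by_donor_drop():
    rng = np.random.default_rng(8)
    donor = np.concatenate([np.full(150, 300.0), np.full(150, 0.0)]) + rng.normal(0, 8, 300)
    acceptor = np.concatenate([np.full(150, 500.0), np.full(150, 0.0)]) + rng.normal(0, 8, 300)
    det = detect_photobleach(_trace(donor, acceptor))
    assert det.bleach_frame == 150 and det.bleach_class == "simultaneous"


def test_detector_agrees_with_single_split_oracle_on_short_fixtures():
    """For single-step traces of length <= 200 the detected bleach is the
    exhaustive single-split argmax."""
    rng = np.random.default_rng(17)
    for step_at, level, n in [(40, 400.0, 120), (100, 250.0, 200), (150, 600.0, 200)]:
        acceptor = np.concatenate([np.full(step_at, level), np.full(n - step_at, 0.0)])
        acceptor = acceptor + rng.normal(0, 12, n)
        donor = np.full(n, 300.0) + rng.normal(0, 12, n)
        det = detect_photobleach(_trace(donor, acceptor))
        best, best_score = None, -np.inf
        for t in range(5, n - 4):
            se = np.sqrt(1.0 / t + 1.0 / (n - t))
            score = abs(acceptor[:t].mean() - acceptor[t:].mean()) / se
            if score > best_score:
                best, best_score = t, score
        assert det.bleach_frame == best


# -------------------------------------------------------------- screening


def test_simulated_single_bleach_traces_accepted(two_state_spec):
    n_ok = 0
    for seed in range(10):
        path = simulate_state_path(two_state_spec, 300, seed=seed)
        trace, truth = simulate_trace(path, two_state_spec, DEFAULT_NOISE, seed=100 + seed)
        if truth.bleach_frame < 20:
            continue  # legitimately screened out as too short
        report = screen_trace(correct_intensities(trace, CorrectionParams()))
        assert report.accepted, (seed, report.reasons)
        n_ok += 1
    assert n_ok >= 8


def test_two_distinct_acceptor_steps_rejected_as_multi_step():
    rng = np.random.default_rng(1)
    acceptor = np.concatenate(
        [np.full(100, 600.0), np.full(50, 0.0), np.full(80, 600.0), np.full(70, 0.0)]
    ) + rng.normal(0, 20, 300)
    donor = np.concatenate(
        [np.full(100, 400.0), np.full(50, 1000.0), np.full(80, 400.0), np.full(70, 1000.0)]
    ) + rng.normal(0, 20, 300)
    report = screen_trace(_trace(donor, acceptor))
    assert not report.accepted
    assert "multi_step" in report.reasons
    assert report.n_detected_steps_acceptor == 2


def test_constant_channels_rejected_as_no_dynamics():
    report = screen_trace(_trace(np.full(100, 300.0), np.full(100, 200.0)))
    assert not report.accepted
    assert "no_dynamics" in report.reasons


def test_uncorrelated_channels_rejected():
    rng = np.random.default_rng(2)
    donor = 300.0 + rng.normal(0, 30, 300)
    acceptor = np.concatenate([np.full(250, 500.0), np.full(50, 0.0)]) + rng.normal(0, 30, 300)
    report = screen_trace(_trace(donor, acceptor))
    assert "poor_anticorrelation" in report.reasons


@pytest.mark.parametrize("scenario", ["apo-CXCR4", "apo-ACKR3"])
def test_screening_acceptance_rate_on_default_presets(scenario):
    res = simulate_experiment(scenario, 150, 300, seed=11)
    screened = pipeline.screen_condition([t for t, _ in res], scenario)
    assert screened.acceptance_rate >= 0.9


def test_double_bleach_traces_never_accepted():
    """Stitching two independently bleaching recordings produces two loss
    events; the screen must reject every such trace."""
    res = simulate_experiment("apo-CXCR4", 40, 150, seed=13)
    n_accepted = 0
    for (t1, g1), (t2, g2) in zip(res[:20], res[20:]):
        if g1.bleach_class != "acceptor_only" or g2.bleach_class != "acceptor_only":
            continue
        stitched = IntensityTrace(
            "stitch",
            np.concatenate([t1.donor, t2.donor]),
            np.concatenate([t1.acceptor, t2.acceptor]),
        )
        n_accepted += screen_trace(stitched).accepted
    assert n_accepted == 0


@settings(deadline=None, max_examples=20)
@given(
    n=st.integers(2, 40),
    offset=st.floats(-50, 50),
    scale=st.floats(1.0, 500.0),
)
def test_smt_tsv_round_trip_property(tmp_path_factory, n, offset, scale):
    rng = np.random.default_rng(abs(hash((n, round(offset, 3)))) % 2**31)
    t = IntensityTrace(
        "h", offset + scale * rng.random(n + 2), offset + scale * rng.random(n + 2)
    )
    p = tmp_path_factory.mktemp("rt") / "t.tsv"
    write_traces([t], p)
    (loaded,) = read_traces(p)
    assert np.array_equal(loaded.donor, t.donor)
    assert np.array_equal(loaded.acceptor, t.acceptor)
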