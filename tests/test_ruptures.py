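import numpy as np
import pytest

from rupturekit import (
    IntensityTrace,
    RuptureScriptEntry,
    circularity_cov,
    compute_ratio_derivative,
    detect_rupture_events,
    extract_events,
    initial_recovery_slope,
    rupture_frequency,
    simulate_trace,
    synchronize_events,
)
from rupturekit.pipeline import build_traces

LN2 = np.log(2.0)


def trace_from(rep, ref=None, interval=2.0, is_gap=None, area=None, **kw):
    rep = np.asarray(rep, dtype=float)
    n = len(rep)
    return IntensityTrace(
        track_id=0,
        time_min=np.arange(n) * interval,
        ref=np.full(n, 1000.0) if ref is None else np.asarray(ref, float),
        rep=rep,
        is_gap=is_gap,
        area=area,
        **kw,
    )


def exponential_trace(drop, tau, onset=10, n=200, interval=2.0, b=1000.0):
    entry = RuptureScriptEntry(
        nucleus_id=0, onset_frame=onset, drop_fraction=drop, recovery_tau=tau
    )
    df, _ = simulate_trace(
        entry, n_frames=n, frame_interval=interval, rep_baseline=b
    )
    return trace_from(df["rep"], interval=interval)


class TestRatioDerivative:
    def test_constant_channels_give_unity(self):
        dhn = compute_ratio_derivative(trace_from(np.full(10, 500.0)))
        assert np.isnan(dhn[0])
        assert np.allclose(dhn[1:], 1.0)

    def test_twenty_percent_nls_drop_gives_1_25(self):
        rep = np.full(10, 100.0)
        rep[5:] = 80.0
        dhn = compute_ratio_derivative(trace_from(rep))
        assert dhn[5] == pytest.approx(1.25)

    def test_focus_dip_cancels_exactly(self):
        """Both channels halved on one frame: dH/N stays exactly 1."""
        ref = np.full(10, 1000.0)
        rep = np.full(10, 800.0)
        ref[4] *= 0.5
        rep[4] *= 0.5
        dhn = compute_ratio_derivative(trace_from(rep, ref=ref))
        assert np.allclose(dhn[1:], 1.0)

    def test_nonpositive_reporter_rejected(self):
        with pytest.raises(ValueError, match="track 0"):
            trace_from([100.0, 0.0, 100.0])


class TestDetectEvents:
    def test_single_supra_threshold_frame(self):
        rep = np.array([100.0, 100, 80, 100, 100, 100])
        events = detect_rupture_events(trace_from(rep))
        assert [e.onset_frame for e in events] == [2]

    def test_sub_threshold_never_called(self):
        rep = np.array([100.0, 100, 85, 100, 100])  # dhn max ~1.18
        assert detect_rupture_events(trace_from(rep)) == []

    def test_consecutive_run_merges_to_one_event(self):
        # two successive >1.2 steps: 100 -> 76 -> 60
        rep = np.array([100.0, 100, 76, 60, 60, 60])
        events = detect_rupture_events(trace_from(rep))
        assert [e.onset_frame for e in events] == [2]

    def test_gap_anchored_onset_rejected(self):
        rep = np.array([100.0, 100, 80, 100, 100])
        is_gap = np.array([False, False, True, False, False])
        assert detect_rupture_events(trace_from(rep, is_gap=is_gap)) == []

    def test_area_jump_vetoes_artifact(self):
        rep = np.array([100.0, 100, 80, 100, 100])
        area = np.array([400.0, 400, 800, 400, 400])
        assert detect_rupture_events(trace_from(rep, area=area)) == []

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        rep = np.clip(100 + rng.normal(0, 12, 300), 40, None)
        counts = [
            len(detect_rupture_events(trace_from(rep), threshold=thr))
            for thr in (1.05, 1.1, 1.2, 1.4, 1.8)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_global_illumination_invariance_is_exact(self):
        rng = np.random.default_rng(7)
        rep = np.clip(100 + rng.normal(0, 10, 120), 30, None)
        ref = np.clip(500 + rng.normal(0, 10, 120), 30, None)
        gains = rng.uniform(0.4, 1.5, 120)
        base = compute_ratio_derivative(trace_from(rep, ref=ref))
        scaled = compute_ratio_derivative(
            trace_from(rep * gains, ref=ref * gains)
        )
        assert np.allclose(base[1:], scaled[1:], rtol=1e-12)


class TestCharacterizeEvent:
    def test_extent_and_halftime_closed_form(self):
        trace = exponential_trace(drop=0.5, tau=20.0)
        (event,) = extract_events(trace)
        assert event.extent == pytest.approx(0.50, abs=0.01)
        assert event.complete
        assert event.t_r == pytest.approx(20.0 * LN2, abs=2.0)

    def test_incomplete_recovery_has_no_halftime(self):
        trace = exponential_trace(drop=0.6, tau=200.0, n=60)
        (event,) = extract_events(trace)
        assert not event.complete
        assert event.t_r is None

    def test_two_identical_sequential_events_match(self):
        entry = RuptureScriptEntry(
            nucleus_id=0, onset_frame=10, drop_fraction=0.4, recovery_tau=10.0
        )
        df1, _ = simulate_trace(entry, n_frames=60)
        rep = np.concatenate([df1["rep"], df1["rep"]])
        events = extract_events(trace_from(rep))
        assert len(events) == 2
        assert events[0].extent == pytest.approx(events[1].extent, rel=1e-6)
        assert events[0].t_r == pytest.approx(events[1].t_r, abs=1e-6)

    def test_onset_too_close_to_start_keeps_event_without_extent(self):
        rep = np.array([100.0, 80, 82, 84, 86, 88])
        events = extract_events(trace_from(rep), min_extent=None)
        assert len(events) == 1
        assert events[0].extent is None
        assert events[0].t_r is None

    def test_halftime_oracle_over_tau_sweep(self):
        """|T_r - tau ln 2| <= one frame interval for tau in [5, 120] min."""
        for tau in np.linspace(5, 120, 24):
            trace = exponential_trace(drop=0.5, tau=float(tau), n=220)
            (event,) = extract_events(trace)
            assert event.t_r is not None, f"tau={tau}"
            assert abs(event.t_r - tau * LN2) <= 2.0, f"tau={tau}"
            assert abs(event.extent - 0.5) <= 0.01


class TestSynchronize:
    def test_identical_events_mean_equals_trace_and_sem_zero(self):
        traces = {}
        events = []
        for tid in (0, 1):
            trace = exponential_trace(drop=0.5, tau=20.0, n=120)
            trace.track_id = tid
            traces[tid] = trace
            evs = extract_events(trace)
            for e in evs:
                e.track_id = tid
            events += evs
        ens = synchronize_events(events, traces, pre_frames=4, post_frames=20)
        assert ens.matrix.shape[0] == 2
        assert np.allclose(np.nan_to_num(ens.sem), 0.0)
        expected = traces[0].rep[6:31] / events[0].baseline
        assert np.allclose(ens.mean, expected, rtol=1e-9)

    def test_pre_onset_rows_normalized_to_one(self):
        trace = exponential_trace(drop=0.4, tau=15.0, b=200.0)
        events = extract_events(trace)
        ens = synchronize_events(events, {0: trace}, pre_frames=3, post_frames=10)
        assert np.allclose(ens.matrix[0, :3], 1.0, atol=1e-9)
        assert ens.rel_time_min[3] == 0.0

    def test_fast_group_recovers_earlier_than_slow(self):
        traces, events = {}, []
        for tid, tau in enumerate([10.0] * 5 + [80.0] * 5):
            trace = exponential_trace(drop=0.5, tau=tau, n=300)
            trace.track_id = tid
            traces[tid] = trace
            evs = extract_events(trace)
            for e in evs:
                e.track_id = tid
            events += evs
        ens = synchronize_events(events, traces, pre_frames=2, post_frames=100)
        fast = ens.subset(np.array([g == "fast" for g in ens.group_labels]))
        slow = ens.subset(np.array([g == "slow" for g in ens.group_labels]))
        assert fast.matrix.shape[0] == 5 and slow.matrix.shape[0] == 5
        post = ens.rel_time_min > 0
        t_fast = ens.rel_time_min[post][np.argmax(fast.mean[post] >= 0.75)]
        t_slow = ens.rel_time_min[post][np.argmax(slow.mean[post] >= 0.75)]
        assert t_fast < t_slow

    def test_empty_event_list(self):
        ens = synchronize_events([], {}, 2, 5)
        assert ens.matrix.size == 0


class TestPopulationSummaries:
    def test_frequency_arithmetic(self):
        trace = exponential_trace(drop=0.5, tau=10.0, n=80)
        events = []
        for tid, n_ev in ((2, 1), (3, 3)):
            for k in range(n_ev):
                e = extract_events(trace)[0]
                e.track_id = tid
                events.append(e)
        out = rupture_frequency([0, 1, 2, 3], events)
        assert out["fraction_with_event"] == pytest.approx(0.5)
        assert out["mean_events_per_track"] == pytest.approx(1.0)
        assert out["max_events_per_track"] == 3

    def test_no_events(self):
        out = rupture_frequency([0, 1], [])
        assert out["fraction_with_event"] == 0.0
        assert out["mean_events_per_track"] == 0.0

    def test_circularity_cov_hand_computed(self):
        assert circularity_cov(np.full(10, 0.9)) == 0.0
        expected = np.std([0.8, 1.0], ddof=1) / 0.9
        assert circularity_cov(np.array([0.8, 1.0])) == pytest.approx(expected)
        assert expected == pytest.approx(0.1571, abs=2e-4)

    def test_initial_slope_linear_exact_and_ordering(self):
        n = 50
        t = np.arange(n) * 2.0
        rep = np.where(
            t < 20.0, 1000.0, np.clip(500.0 + 3.0 * (t - 20.0), None, 1000.0)
        )
        trace = trace_from(rep)
        events = extract_events(trace, min_extent=None)
        slope = initial_recovery_slope(trace, events[0], window=10.0)
        assert slope == pytest.approx(3.0 / events[0].baseline, rel=1e-6)
        # exponential comparison: slope(tau=10) > slope(tau=60)
        slopes = {}
        for tau in (10.0, 60.0):
            tr = exponential_trace(drop=0.5, tau=tau, n=200)
            (ev,) = extract_events(tr)
            slopes[tau] = initial_recovery_slope(tr, ev, window=10.0)
        assert slopes[10.0] > slopes[60.0]

    def test_flat_after_drop_zero_slope(self):
        rep = np.concatenate([np.full(10, 100.0), np.full(20, 70.0)])
        trace = trace_from(rep)
        (event,) = extract_events(trace)
        assert not event.complete
        slope = initial_recovery_slope(trace, event, window=10.0)
        assert slope == pytest.approx(0.0, abs=1e-12)


class TestBuildTracesQC:
    def test_area_outliers_interpolated(self):
        import pandas as pd

        n = 30
        df = pd.DataFrame(
            {
                "track_id": 0,
                "frame": np.arange(n),
                "time_min": np.arange(n) * 2.0,
                "mean_ref": 1000.0,
                "mean_rep": 900.0,
                "area": 400.0,
                "is_gap": False,
            }
        )
        df.loc[12, ["area", "mean_rep"]] = [820.0, 1700.0]  # merged mask
        traces = build_traces(df)
        trace = traces[0]
        assert trace.is_gap[12]
        assert trace.rep[12] == pytest.approx(900.0)
        assert extract_events(trace) == []
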