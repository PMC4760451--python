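"""Up-state detector: hand-traceable rule cases, oracle equivalence,
invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slicephys import (BaselineError, ParameterError, Trace,
                       UpStateDetectionConfig, UpStateEvent, detect_up_states,
                       estimate_baseline_sd, merge_intervals, preprocess_field,
                       upstate_charge_transfer, upstate_statistics)

DT = 1e-3  # 1 kHz test traces: 10 samples per 10-ms bin


def burst_trace(bursts, duration_s=20.0, base_sd=1.0, burst_sd=20.0, seed=0,
                dt=DT, mode="field"):
    """Gaussian noise with the given (start_s, end_s) high-SD intervals."""
    rng = np.random.default_rng(seed)
    n = int(duration_s / dt)
    x = rng.normal(0.0, base_sd, n)
    for a, b in bursts:
        i0, i1 = int(a / dt), int(b / dt)
        x[i0:i1] = rng.normal(0.0, burst_sd, i1 - i0)
    return Trace(x, dt=dt, mode=mode)


def brute_force_detect(x, dt, cfg, baseline_sd):
    """Exhaustive bin labeling + interval algebra; no streaming shortcuts."""
    bs = int(round(cfg.bin_ms * 1e-3 / dt))
    labels = []
    for i in range(len(x) // bs):
        labels.append(np.std(x[i * bs:(i + 1) * bs]) >
                      cfg.threshold_mult * baseline_sd)
    release = int(round(cfg.release_ms / cfg.bin_ms))
    min_bins = int(round(cfg.min_duration_ms / cfg.bin_ms))
    # candidates: supra runs, bridging sub runs <= release
    cands = []
    cur = None
    gap = 0
    for i, lab in enumerate(labels):
        if lab:
            if cur is None:
                cur = [i, i]
            elif gap <= release:
                cur[1] = i
            else:
                cands.append(cur)
                cur = [i, i]
            gap = 0
        else:
            gap += 1
    if cur is not None:
        cands.append(cur)
    cands = [c for c in cands if c[1] - c[0] + 1 >= min_bins]
    bin_s = bs * dt
    ivs = [(c[0] * bin_s, (c[1] + 1) * bin_s) for c in cands]
    merged = []
    counts = []
    for a, b in ivs:
        if merged and a - merged[-1][1] <= cfg.merge_window_s:
            merged[-1] = (merged[-1][0], b)
            counts[-1] += 1
        else:
            merged.append((a, b))
            counts.append(1)
    return merged, counts


class TestPreprocessField:
    def test_dc_offset_removed(self):
        tr = Trace(np.full(20000, 5.0) , dt=1e-4, mode="field")
        out = preprocess_field(tr)
        assert np.abs(out.samples[1000:-1000]).max() < 1e-6

    def test_passband_gain_near_unity_at_100hz(self):
        t = np.arange(0, 2, 1e-4)
        tr = Trace(np.sin(2 * np.pi * 100 * t), dt=1e-4, mode="field")
        out = preprocess_field(tr)
        assert out.samples[5000:15000].max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation_at_1khz(self):
        t = np.arange(0, 2, 1e-4)
        hi = preprocess_field(Trace(np.sin(2 * np.pi * 1000 * t), dt=1e-4,
                                    mode="field")).samples[5000:15000].max()
        lo = preprocess_field(Trace(np.sin(2 * np.pi * 100 * t), dt=1e-4,
                                    mode="field")).samples[5000:15000].max()
        assert lo / hi > 10

    def test_nyquist_violation_rejected(self):
        tr = Trace(np.zeros(1000), dt=2e-3, mode="field")  # 500 Hz sampling
        from slicephys import SamplingError
        with pytest.raises(SamplingError):
            preprocess_field(tr)


class TestBaseline:
    def test_iid_noise_sd_consistent(self, rng):
        tr = Trace(rng.normal(0, 1.0, 10000), dt=DT, mode="field")
        sd, _ = estimate_baseline_sd(tr)
        assert 0.8 <= sd <= 1.2

    def test_quiet_window_found_by_search(self, rng):
        x = np.concatenate([rng.normal(0, 1.0, 1500),
                            rng.normal(0, 10.0, 8500)])
        tr = Trace(x, dt=DT, mode="field")
        sd, (a, b) = estimate_baseline_sd(tr)
        assert b <= 1.6 and sd < 2.0
        # brute-force minimum over all candidate windows agrees
        w, step = 1000, 100
        starts = list(range(0, x.size - w + 1, step))
        if starts[-1] != x.size - w:
            starts.append(x.size - w)
        brute = min(np.std(x[s:s + w]) for s in starts)
        assert sd == pytest.approx(brute, rel=1e-9)

    def test_flat_trace_is_degenerate(self):
        tr = Trace(np.zeros(5000), dt=DT, mode="field")
        with pytest.raises(BaselineError):
            estimate_baseline_sd(tr)

    def test_explicit_window_override(self, rng):
        tr = Trace(rng.normal(0, 2.0, 5000), dt=DT, mode="field")
        cfg = UpStateDetectionConfig(baseline_span=(1.0, 2.0))
        sd, win = estimate_baseline_sd(tr, cfg)
        assert win == (1.0, 2.0)
        assert sd == pytest.approx(np.std(tr.samples[1000:2000]), rel=1e-9)


class TestDetectionRules:
    def test_pure_noise_yields_nothing(self, rng):
        tr = Trace(rng.normal(0, 1.0, 30000), dt=DT, mode="field")
        assert detect_up_states(tr, baseline_sd=1.0) == []

    def test_single_500ms_burst(self):
        tr = burst_trace([(5.0, 5.5)])
        events = detect_up_states(tr, baseline_sd=1.0)
        assert len(events) == 1
        assert 0.48 <= events[0].duration_s <= 0.52
        assert events[0].n_merged == 1

    def test_two_bursts_within_merge_window_become_one(self):
        tr = burst_trace([(5.0, 5.4), (6.2, 6.6)])  # 0.8 s gap < 1 s
        events = detect_up_states(tr, baseline_sd=1.0)
        assert len(events) == 1
        assert events[0].n_merged == 2
        assert events[0].duration_s == pytest.approx(1.6, abs=0.05)

    def test_two_bursts_beyond_merge_window_stay_separate(self):
        tr = burst_trace([(5.0, 5.4), (6.9, 7.3)])  # 1.5 s gap
        events = detect_up_states(tr, baseline_sd=1.0)
        assert len(events) == 2

    def test_short_burst_discarded(self):
        tr = burst_trace([(5.0, 5.2)])  # 200 ms < 300 ms minimum
        assert detect_up_states(tr, baseline_sd=1.0) == []

    def test_brief_dip_bridged_long_dip_terminates(self):
        # 100-ms dip inside a burst is bridged (release rule)...
        tr = burst_trace([(5.0, 5.4), (5.5, 5.9)], seed=1)
        events = detect_up_states(tr, baseline_sd=1.0)
        assert len(events) == 1 and events[0].n_merged == 1
        assert events[0].duration_s == pytest.approx(0.9, abs=0.05)

    def test_invalid_baseline_rejected(self):
        tr = burst_trace([(5.0, 5.5)])
        with pytest.raises(ParameterError):
            detect_up_states(tr, baseline_sd=0.0)

    def test_scale_equivariance(self):
        tr = burst_trace([(3.0, 3.6), (9.0, 9.5)], seed=4)
        ev1 = detect_up_states(tr, baseline_sd=1.0)
        tr2 = Trace(2.0 * tr.samples, dt=tr.dt, mode=tr.mode)
        ev2 = detect_up_states(tr2, baseline_sd=2.0)
        assert [(e.start_s, e.end_s, e.n_merged) for e in ev1] == \
               [(e.start_s, e.end_s, e.n_merged) for e in ev2]

    def test_matches_brute_force_oracle_on_random_traces(self):
        cfg = UpStateDetectionConfig()
        rng = np.random.default_rng(99)
        for _ in range(50):
            n_b = rng.integers(0, 4)
            bursts = []
            t = rng.uniform(1.0, 3.0)
            for _ in range(n_b):
                d = rng.uniform(0.1, 1.2)
                bursts.append((t, t + d))
                t += d + rng.uniform(0.05, 2.0)
            tr = burst_trace(bursts, duration_s=t + 2.0,
                             seed=int(rng.integers(1 << 30)))
            got = detect_up_states(tr, cfg, baseline_sd=1.0)
            exp, counts = brute_force_detect(tr.samples, tr.dt, cfg, 1.0)
            assert [(e.start_s, e.end_s) for e in got] == pytest.approx(exp)
            assert [e.n_merged for e in got] == counts

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_output_respects_min_duration_and_merge_gap(self, seed):
        rng = np.random.default_rng(seed)
        bursts = []
        t = 1.0
        for _ in range(rng.integers(0, 5)):
            d = rng.uniform(0.05, 1.0)
            bursts.append((t, t + d))
            t += d + rng.uniform(0.02, 2.5)
        tr = burst_trace(bursts, duration_s=t + 2.0, seed=int(seed % 1000))
        cfg = UpStateDetectionConfig()
        events = detect_up_states(tr, cfg, baseline_sd=1.0)
        for e in events:
            assert e.duration_s >= cfg.min_duration_ms / 1e3 - 1e-9
        for a, b in zip(events, events[1:]):
            assert b.start_s - a.end_s > cfg.merge_window_s


class TestStatisticsAndArea:
    def test_median_of_equal_durations(self):
        evs = [UpStateEvent(i * 10.0, i * 10.0 + 2.0) for i in range(3)]
        s = upstate_statistics(evs, 100.0)
        assert s.duration_median_s == 2.0
        assert s.rate_count_Hz == pytest.approx(0.03)

    def test_median_matches_sorted_middle(self):
        evs = [UpStateEvent(0.0, 1.0), UpStateEvent(10.0, 12.0),
               UpStateEvent(30.0, 34.0)]
        s = upstate_statistics(evs, 100.0)
        assert s.duration_median_s == 2.0
        assert s.rate_iei_median_Hz == pytest.approx(
            np.quantile([1 / 10.0, 1 / 20.0], 0.5))

    def test_empty_events_give_flagged_summary(self):
        s = upstate_statistics([], 100.0)
        assert s.n_events == 0 and s.duration_median_s is None

    def test_truncated_events_counted_but_not_measured(self):
        evs = [UpStateEvent(0.0, 1.0, truncated=True), UpStateEvent(5.0, 7.0)]
        s = upstate_statistics(evs, 50.0)
        assert s.n_events == 2 and s.durations_s == [2.0]

    @pytest.mark.parametrize("dev,dur,expect", [(0.0, 0.1, 0.0),
                                                (10.0, 0.1, 1.0),
                                                (10.0, 0.05, 0.5)])
    def test_charge_transfer_rectangles(self, dev, dur, expect):
        dt = 1e-4
        x = np.zeros(10000)
        x[1000:1000 + int(dur / dt)] = dev
        tr = Trace(x, dt=dt, mode="voltage_clamp")
        ev = UpStateEvent(0.1, 0.1 + dur)
        # trapezoid loses half a sample at each edge of a step
        assert upstate_charge_transfer(tr, ev, 0.0) == pytest.approx(
            expect, abs=dev * dt)

    def test_charge_transfer_bounds_checked(self):
        tr = Trace(np.zeros(100), dt=1e-4, mode="voltage_clamp")
        with pytest.raises(ParameterError):
            upstate_charge_transfer(tr, UpStateEvent(0.0, 1.0), 0.0)


def test_merge_intervals_counts():
    merged, counts = merge_intervals([(0, 1), (1.5, 2), (4, 5)], 1.0,
                                     with_counts=True)
    assert merged == [(0.0, 2.0), (4.0, 5.0)]
    assert counts == [2, 1]
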