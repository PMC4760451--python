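"""Spike-feature extraction, firing classification and passive-property fit."""

import numpy as np
import pytest

from slicephys import (FeatureError, FitError, Trace, ap_features,
                       ap_template, ap_threshold_phase_plane,
                       classify_firing_type, detect_spikes, firing_rate,
                       generate_current_steps, generate_membrane_test,
                       passive_properties, rheobase, sfa_ratio)

DT = 2e-5


def template_trace(ap, at_times_s, vrest=-70.0, dur_s=0.5):
    """Resting trace with the kinematics template injected after a slow
    (sub-criterion) depolarizing ramp to threshold."""
    v = np.full(int(dur_s / DT), vrest)
    tpl = ap_template(ap, DT)
    n_ramp = int(5e-3 / DT)                    # ~6 V/s approach, < 20 V/s
    n_hold = int(30e-3 / DT)                   # sit at the trough post-spike
    for t in at_times_s:
        i = int(round(t / DT))
        v[i - n_ramp:i] = np.linspace(vrest, ap.threshold_mV, n_ramp)
        v[i:i + tpl.size] = tpl[: v.size - i]
        j = i + tpl.size
        v[j:j + n_hold] = tpl[-1]
        k = j + n_hold
        n_back = int(50e-3 / DT)
        v[k:k + n_back] = np.linspace(tpl[-1], vrest, n_back)[: v.size - k]
    return Trace(v, dt=DT, mode="current_clamp")


class TestDetectSpikes:
    def test_flat_trace_empty(self):
        tr = Trace(np.full(5000, -70.0), dt=DT, mode="current_clamp")
        assert detect_spikes(tr) == []

    def test_injected_templates_found_at_truth(self, euploid):
        times = [0.1, 0.2, 0.3]
        tr = template_trace(euploid.ap, times)
        got = detect_spikes(tr)
        assert len(got) == 3
        # peak lags the threshold crossing by the template rise time
        for g, t in zip(got, times):
            assert 0 < g - t < 1.5e-3

    def test_refractory_merges_twin_peaks(self):
        v = np.full(5000, -70.0)
        v[1000:1010] = np.linspace(-70, 30, 10)   # fast rise to peak
        v[1010:1020] = 30.0
        v[1012] = 31.0                            # second "peak" 0.24 ms later
        v[1020:1060] = np.linspace(30, -70, 40)
        tr = Trace(v, dt=DT, mode="current_clamp")
        assert len(detect_spikes(tr)) == 1

    def test_subthreshold_ramp_ignored(self):
        v = -70 + 30 * np.linspace(0, 1, 50000)   # 0.6 V/s ramp
        tr = Trace(v, dt=DT, mode="current_clamp")
        assert detect_spikes(tr, min_peak_mV=-45.0) == []


class TestThresholdAndFeatures:
    def test_threshold_recovered_from_template(self, euploid):
        tr = template_trace(euploid.ap, [0.1])
        t_peak = detect_spikes(tr)[0]
        th = ap_threshold_phase_plane(tr, t_peak)
        assert th == pytest.approx(euploid.ap.threshold_mV, abs=0.5)

    def test_slow_ramp_never_meets_criterion(self):
        v = -70 + 5 * np.sin(np.linspace(0, np.pi, 10000))
        tr = Trace(v, dt=DT, mode="current_clamp")
        with pytest.raises(FeatureError):
            ap_threshold_phase_plane(tr, 10000 * DT / 2)

    def test_triangular_spike_geometry(self):
        # symmetric triangle: threshold 0, peak 100 mV, base width 2 ms
        n_half = int(1e-3 / DT)
        v = np.concatenate([np.zeros(1000),
                            np.linspace(0, 100, n_half),
                            np.linspace(100, 0, n_half),
                            np.zeros(1000) - 1.0])
        tr = Trace(v, dt=DT, mode="current_clamp")
        t_peak = (1000 + n_half) * DT
        f = ap_features(tr, t_peak, 0.0)
        assert f.amplitude_mV == pytest.approx(100.0, rel=1e-3)
        assert f.fwhm_ms == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("label", ["euploid", "trisomic"])
    def test_full_bundle_recovery_within_2pct(self, label, request):
        preset = request.getfixturevalue(label)
        tr = template_trace(preset.ap, [0.1])
        t_peak = detect_spikes(tr)[0]
        th = ap_threshold_phase_plane(tr, t_peak)
        f = ap_features(tr, t_peak, th)
        ap = preset.ap
        assert th == pytest.approx(ap.threshold_mV, abs=0.5)
        assert f.amplitude_mV == pytest.approx(ap.amplitude_mV, rel=0.02)
        assert f.fwhm_ms == pytest.approx(ap.fwhm_ms, abs=0.02)
        assert f.ahp_mV == pytest.approx(ap.ahp_mV, rel=0.02)
        assert f.max_rise_V_per_s == pytest.approx(ap.max_rise_V_per_s, rel=0.02)
        assert f.max_decay_V_per_s == pytest.approx(ap.max_decay_V_per_s, rel=0.02)

    def test_fwhm_interpolation_agrees_with_sample_scan(self, euploid):
        tr = template_trace(euploid.ap, [0.1])
        t_peak = detect_spikes(tr)[0]
        th = ap_threshold_phase_plane(tr, t_peak)
        f = ap_features(tr, t_peak, th)
        # brute force: count samples at or above the half level
        half = th + f.amplitude_mV / 2
        scan = np.sum(tr.samples >= half) * DT * 1e3
        assert abs(scan - f.fwhm_ms) <= DT * 2e3  # within one dt each flank

    def test_time_shift_invariance(self, euploid):
        f1 = _features_at(euploid.ap, 0.1)
        f2 = _features_at(euploid.ap, 0.23)
        assert f1.fwhm_ms == pytest.approx(f2.fwhm_ms, abs=1e-6)
        assert f1.ahp_mV == pytest.approx(f2.ahp_mV, abs=1e-6)

    def test_voltage_offset_shifts_threshold_not_fwhm(self, euploid):
        tr = template_trace(euploid.ap, [0.1])
        tr2 = Trace(tr.samples + 5.0, dt=DT, mode="current_clamp")
        t1, t2 = detect_spikes(tr)[0], detect_spikes(tr2)[0]
        th1 = ap_threshold_phase_plane(tr, t1)
        th2 = ap_threshold_phase_plane(tr2, t2)
        assert th2 - th1 == pytest.approx(5.0, abs=0.1)
        f1, f2 = ap_features(tr, t1, th1), ap_features(tr2, t2, th2)
        assert f1.fwhm_ms == pytest.approx(f2.fwhm_ms, abs=1e-6)
        assert f1.amplitude_mV == pytest.approx(f2.amplitude_mV, abs=0.1)


def _features_at(ap, t):
    tr = template_trace(ap, [t])
    t_peak = detect_spikes(tr)[0]
    return ap_features(tr, t_peak, ap_threshold_phase_plane(tr, t_peak))


class TestRheobaseAndAdaptation:
    def test_first_spiking_sweep_wins(self, euploid):
        sweeps = generate_current_steps(euploid, [35.0, 45.0, 55.0, 65.0])
        assert rheobase(sweeps) == 55.0

    def test_no_spiking_sweep_is_not_found(self, euploid):
        sweeps = generate_current_steps(euploid, [15.0, 25.0])
        assert rheobase(sweeps) is None

    def test_sfa_equal_intervals(self):
        assert sfa_ratio([0.0, 0.05, 0.10, 0.15, 0.20]) == pytest.approx(1.0)

    def test_sfa_hand_arithmetic(self):
        # ISIs 50, 50, 60, 70 ms -> (60+70)/(50+50) = 1.3
        spikes = np.cumsum([0.0, 0.05, 0.05, 0.06, 0.07])
        assert sfa_ratio(list(spikes)) == pytest.approx(1.3)

    def test_sfa_requires_five_spikes(self):
        assert sfa_ratio([0.0, 0.05, 0.1, 0.15]) is None

    def test_sfa_invariant_to_time_rescaling(self):
        spikes = list(np.cumsum([0.0, 0.04, 0.05, 0.07, 0.09]))
        a = sfa_ratio(spikes)
        b = sfa_ratio([3.0 * s for s in spikes])
        assert a == pytest.approx(b)

    def test_generated_sfa_matches_preset(self, euploid):
        sweeps = generate_current_steps(euploid, [euploid.ap.rheobase_pA])
        spikes = detect_spikes(sweeps[0])
        assert sfa_ratio(spikes) == pytest.approx(euploid.ap.sfa_ratio, rel=0.02)


class TestFiringClassification:
    @pytest.mark.parametrize("vrest,isi,rate,ahp,expect", [
        (-50.0, None, 20.0, -10.0, "excluded_depolarized"),
        (-65.0, 30.0, 80.0, -45.0, "FS"),
        (-65.0, 30.0, 80.0, -30.0, "RS"),     # both FS criteria required
        (-65.0, 30.0, 50.0, -45.0, "RS"),
        (-65.0, 5.0, 30.0, -10.0, "excluded_doublet"),
        (-65.0, None, 30.0, None, "RS"),
    ])
    def test_rules(self, vrest, isi, rate, ahp, expect):
        assert classify_firing_type(vrest, isi, rate, ahp) == expect

    def test_firing_rate_robust_to_onset(self):
        assert firing_rate([0.1, 0.2, 0.3]) == pytest.approx(10.0)
        assert firing_rate([0.5, 0.6, 0.7]) == pytest.approx(10.0)


class TestPassiveProperties:
    @pytest.mark.parametrize("ra,rm,cm", [(10.0, 200.0, 100.0),
                                          (10.0, 322.0, 70.0),
                                          (15.0, 244.4, 94.0)])
    def test_noiseless_inverse_is_exact(self, ra, rm, cm):
        tr, _ = generate_membrane_test(ra, rm, cm, step_mV=10.0)
        ra2, rm2, cm2, spec = passive_properties(tr, 10.0)
        assert ra2 == pytest.approx(ra, rel=5e-3)
        assert rm2 == pytest.approx(rm, rel=5e-3)
        assert cm2 == pytest.approx(cm, rel=5e-3)
        assert spec == pytest.approx(rm / cm, rel=1e-2)

    def test_bias_small_under_noise(self):
        cms = []
        for seed in range(100):
            tr, _ = generate_membrane_test(10.0, 322.0, 70.0, step_mV=10.0,
                                           noise_sd_pA=5.0, seed=seed)
            cms.append(passive_properties(tr, 10.0)[2])
        assert abs(np.mean(cms) - 70.0) / 70.0 < 0.02

    def test_zero_step_is_fit_error(self):
        tr, _ = generate_membrane_test(10.0, 200.0, 100.0, step_mV=10.0)
        with pytest.raises(FitError):
            passive_properties(tr, 0.0)
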