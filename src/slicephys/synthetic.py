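"""Calibrated synthetic recordings with ground-truth annotations.

Every generator is a pure function of its parameters and a seed and returns
(i) a :class:`~slicephys.trace_io.Trace` or :class:`~slicephys.trace_io.SweepSet`
and (ii) a :class:`GroundTruth` record listing every generated event, so each
analysis stage can be validated as a parameter-recovery loop without any
recorded data.

Conventions
-----------
* **Instantaneous frequency.** Spontaneous-event frequency is reported per
  event as 1/inter-event interval. For a homogeneous Poisson process the
  median of 1/interval is rate/ln 2, so a generator asked for a target
  *median* frequency uses rate = median * ln 2.
* **Up-state kinetics.** A semi-Markov two-state process: Up durations are
  log-normal (median-parameterized, sigma_log = 0.35 by default); Down
  durations are a 1.5-s-shifted exponential whose mean is tuned so the
  event rate (events per second of recording) matches the preset. The
  1.5-s floor guarantees the ground-truth intervals already satisfy the
  detector's 1-s merge rule by construction.
* **Action potentials.** A parameterized waveform template (sinusoidal-slope
  rise, power-of-sine-slope fall) whose threshold, amplitude, AHP, FWHM and
  maximal rise/decay slopes encode the preset's kinematics bundle exactly;
  it is stitched onto a leaky subthreshold trajectory at prescribed spike
  times. Feature recoverability, not conductance-based realism, is the
  contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, special

from .errors import ParameterError
from .presets import APKinematics, GenotypePreset
from .trace_io import SweepSet, Trace

LN2 = math.log(2.0)

#: default sampling intervals (s) per protocol; see docs/methods.md
DT_DEFAULT = 1e-4        # 10 kHz: spontaneous PSCs, evoked trials, membrane test
DT_STEPS = 2e-5          # 50 kHz: current steps (resolves max dV/dt to <1%)
DT_FIELD = 5e-4          # 2 kHz: Up-state traces (signal band <= 300 Hz)


@dataclass
class GroundTruth:
    """Per-trace generation record used as a test oracle."""

    upstate_intervals: list[tuple[float, float]] = field(default_factory=list)
    psc_times: list[float] = field(default_factory=list)
    psc_amplitudes: list[float] = field(default_factory=list)
    spike_times: list[float] = field(default_factory=list)
    true_latencies_ms: list[float] = field(default_factory=list)
    true_passive: tuple[float, float, float] | None = None  # (Ra, Rm, Cm)


def poisson_rate_from_median(median_inst_freq_Hz: float) -> float:
    """Poisson rate whose median instantaneous frequency equals the target."""
    return median_inst_freq_Hz * LN2


# ---------------------------------------------------------------------------
# PSC kernel and spontaneous trains
# ---------------------------------------------------------------------------

def generate_psc_kernel(amp_pA: float, tau_rise_ms: float, tau_decay_ms: float,
                        dt: float = DT_DEFAULT) -> np.ndarray:
    """Difference-of-exponentials PSC shape, peak-normalized to ``amp_pA``.

    The kernel is truncated at 8 * tau_decay, where its value is below
    3e-4 of the peak.
    """
    if not (0 < tau_rise_ms < tau_decay_ms):
        raise ParameterError(
            f"need 0 < tau_rise ({tau_rise_ms}) < tau_decay ({tau_decay_ms})")
    tr, td = tau_rise_ms * 1e-3, tau_decay_ms * 1e-3
    n = max(2, int(round(8 * td / dt)))
    t = np.arange(n) * dt
    k = np.exp(-t / td) - np.exp(-t / tr)
    peak = k.max()
    if peak <= 0:
        return np.zeros(n)
    return (amp_pA / peak) * k


def generate_psc_train(median_inst_freq_Hz: float, duration_s: float,
                       seed: int, *, amp_pA: float = 20.0,
                       tau_rise_ms: float = 0.5, tau_decay_ms: float = 5.0,
                       noise_sd_pA: float = 2.0, dt: float = DT_DEFAULT,
                       polarity: str = "inward",
                       amp_jitter_frac: float = 0.0) -> tuple[Trace, GroundTruth]:
    """Homogeneous Poisson PSC barrage in voltage clamp.

    Event times follow a Poisson process with rate
    ``median_inst_freq_Hz * ln 2``; each event injects the
    difference-of-exponentials kernel, optionally with multiplicative
    log-normal amplitude jitter; Gaussian noise is added on top.
    ``polarity='inward'`` produces negative-going events (EPSCs at a
    hyperpolarized holding), ``'outward'`` positive-going (IPSCs).
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be > 0")
    if median_inst_freq_Hz < 0:
        raise ParameterError("median_inst_freq_Hz must be >= 0")
    if polarity not in ("inward", "outward"):
        raise ParameterError(f"unknown polarity {polarity!r}")
    rng = np.random.default_rng(seed)
    rate = poisson_rate_from_median(median_inst_freq_Hz)
    n = int(round(duration_s / dt))
    x = np.zeros(n)
    times: list[float] = []
    amps: list[float] = []
    if rate > 0:
        t = rng.exponential(1.0 / rate)
        while t < duration_s:
            times.append(t)
            t += rng.exponential(1.0 / rate)
        idx = np.minimum((np.asarray(times) / dt).astype(int), n - 1)
        if amp_jitter_frac > 0:
            sigma = math.sqrt(math.log(1 + amp_jitter_frac ** 2))
            amps = list(amp_pA * rng.lognormal(-sigma ** 2 / 2, sigma, len(times)))
        else:
            amps = [amp_pA] * len(times)
        deltas = np.zeros(n)
        np.add.at(deltas, idx, np.asarray(amps))
        kernel = generate_psc_kernel(1.0, tau_rise_ms, tau_decay_ms, dt)
        x = signal.fftconvolve(deltas, kernel)[:n]
    if noise_sd_pA > 0:
        x = x + rng.normal(0.0, noise_sd_pA, n)
    sign = -1.0 if polarity == "inward" else 1.0
    trace = Trace(sign * x, dt=dt, mode="voltage_clamp",
                  meta={"polarity": polarity, "kind": "psc_train",
                        "amp_pA": amp_pA, "noise_sd_pA": noise_sd_pA})
    return trace, GroundTruth(psc_times=times, psc_amplitudes=amps)


# ---------------------------------------------------------------------------
# Up/Down-state traces
# ---------------------------------------------------------------------------

def _draw_state_intervals(preset: GenotypePreset, duration_s: float,
                          rng: np.random.Generator, sigma_log: float,
                          min_up_s: float = 0.35,
                          min_down_s: float = 1.5) -> list[tuple[float, float]]:
    rate = preset.upstate_rate_median_Hz
    if rate == 0:
        return []
    med = preset.upstate_duration_median_s
    mean_up = med * math.exp(sigma_log ** 2 / 2)
    mean_cycle = 1.0 / rate
    mean_down = mean_cycle - mean_up
    if mean_down <= min_down_s:
        raise ParameterError(
            f"Up-state rate {rate} Hz and duration median {med} s leave no room "
            f"for Down states longer than {min_down_s} s")
    intervals = []
    t = min_down_s + rng.exponential(mean_down - min_down_s)
    while t < duration_s:
        dur = rng.lognormal(math.log(med), sigma_log)
        while dur < min_up_s:
            dur = rng.lognormal(math.log(med), sigma_log)
        end = min(t + dur, duration_s)
        intervals.append((t, end))
        t = t + dur + min_down_s + rng.exponential(mean_down - min_down_s)
    return intervals


def generate_upstate_trace(preset: GenotypePreset, duration_s: float,
                           mode: str, seed: int, *,
                           dt: float = DT_FIELD, sigma_log: float = 0.35,
                           up_sd_mult: float = 10.0,
                           field_noise_sd: float = 1.0,
                           ic_noise_sd_mV: float = 0.25,
                           ic_depol_mV: float = 10.0,
                           ic_barrage_sd_mV: float = 2.0
                           ) -> tuple[Trace, GroundTruth]:
    """Semi-Markov Up/Down trace (field potential or intracellular).

    Field mode: zero-mean 3-300 Hz band-limited noise whose SD is
    ``up_sd_mult`` times the Down-state SD during Up states. Intracellular
    mode: resting potential plus, during Up states, a ~10 mV depolarization
    with a synaptic-barrage-like fluctuation. Ground-truth intervals are
    reported after the same 1-s merge rule the detector applies (the 1.5-s
    Down-state floor makes the merge a no-op by construction).
    """
    if mode not in ("field", "intracellular"):
        raise ParameterError(f"mode must be 'field' or 'intracellular', got {mode!r}")
    if duration_s <= 0:
        raise ParameterError("duration_s must be > 0")
    from .upstates import merge_intervals  # same rule as the detector

    rng = np.random.default_rng(seed)
    intervals = _draw_state_intervals(preset, duration_s, rng, sigma_log)
    n = int(round(duration_s / dt))
    up = np.zeros(n, dtype=bool)
    for a, b in intervals:
        up[int(a / dt): int(b / dt)] = True

    if mode == "field":
        sd = field_noise_sd * np.where(up, up_sd_mult, 1.0)
        x = rng.normal(0.0, 1.0, n) * sd
        sos = signal.butter(4, [3.0, 300.0], btype="bandpass", fs=1.0 / dt,
                            output="sos")
        x = signal.sosfiltfilt(sos, x)
        trace = Trace(x, dt=dt, mode="field",
                      meta={"genotype": preset.label, "kind": "upstate_field"})
    else:
        x = preset.vrest_mV + rng.normal(0.0, ic_noise_sd_mV, n)
        x = x + up * (ic_depol_mV + rng.normal(0.0, ic_barrage_sd_mV, n))
        trace = Trace(x, dt=dt, mode="current_clamp",
                      meta={"genotype": preset.label, "kind": "upstate_ic"})
    gt = GroundTruth(upstate_intervals=merge_intervals(intervals, 1.0))
    return trace, gt


# ---------------------------------------------------------------------------
# Action-potential template and current steps
# ---------------------------------------------------------------------------

def _sine_power_mean(p: float) -> float:
    """Mean of sin(u)^p over [0, pi]."""
    return special.gamma((p + 1) / 2) / (math.sqrt(math.pi) * special.gamma(p / 2 + 1))


#: depolarization rate at which the template leaves threshold (V/s). Kept
#: well above the 20 V/s phase-plane criterion so the first template sample
#: is the detected threshold; mimics the sharp sodium-activation knee.
AP_ONSET_SLOPE_V_PER_S = 60.0


def ap_template(ap: APKinematics, dt: float = DT_STEPS) -> np.ndarray:
    """Spike waveform from threshold crossing to AHP trough.

    Rise phase: dV/dt = max_rise * sin(u), with u advancing linearly from
    u0 = asin(onset_slope/max_rise) to pi, scaled so the excursion equals
    the amplitude. Fall phase: dV/dt = -|max_decay| * sin(pi s/t_f)^p, with
    (t_f, p) solved so the total drop equals amplitude - AHP and the
    half-amplitude level is re-crossed at FWHM after the rising
    half-crossing. Threshold, amplitude, AHP, FWHM and both slope extrema
    are therefore encoded exactly (up to sampling).
    """
    A = ap.amplitude_mV
    mr = ap.max_rise_V_per_s          # 1 V/s == 1 mV/ms; work in mV and ms
    md = abs(ap.max_decay_V_per_s)
    slope0 = min(AP_ONSET_SLOPE_V_PER_S, mr / 2)
    u0 = math.asin(slope0 / mr)
    dt_ms = dt * 1e3
    fine = min(dt_ms, 1e-3)

    # rise: integrate mr*sin(u) over u in [u0, pi] at unit angular rate,
    # then stretch time so the excursion is exactly A
    u = np.linspace(u0, math.pi, 4001)
    v_r = (np.cos(u0) - np.cos(u)) * mr               # per unit angular time
    stretch = A / v_r[-1]
    t_rise_grid = (u - u0) * stretch
    tr_grid = np.arange(0.0, t_rise_grid[-1], fine)
    v_rise = np.interp(tr_grid, t_rise_grid, v_r * (A / v_r[-1]))
    t_half_rise = float(np.interp(A / 2, v_rise, tr_grid))

    w2 = ap.fwhm_ms - (tr_grid[-1] - t_half_rise)     # peak -> half-level time
    drop = A - ap.ahp_mV                              # total repolarization, mV

    def time_to_half(p: float) -> float:
        t_f = drop / (md * _sine_power_mean(p))
        uu = np.linspace(0.0, math.pi, 4001)
        cum = np.concatenate(([0.0], np.cumsum(
            (np.sin(uu[:-1]) ** p + np.sin(uu[1:]) ** p) / 2 * np.diff(uu))))
        cum = cum * md * t_f / math.pi                # mV dropped vs s
        return float(np.interp(A / 2, cum, uu)) * t_f / math.pi

    lo, hi = 1.0, 12.0
    if time_to_half(lo) > w2:
        raise ParameterError(
            "AP bundle infeasible: FWHM shorter than the steepest admissible fall")
    while time_to_half(hi) < w2 and hi < 200:
        hi *= 2
    from scipy.optimize import brentq
    p = brentq(lambda q: time_to_half(q) - w2, lo, hi, xtol=1e-6)
    t_f = drop / (md * _sine_power_mean(p))

    tf_grid = np.arange(0.0, t_f + fine, fine)
    slope = md * np.clip(np.sin(math.pi * np.minimum(tf_grid, t_f) / t_f),
                         0.0, None) ** p
    v_fall_drop = np.concatenate(([0.0], np.cumsum((slope[:-1] + slope[1:]) / 2 * fine)))
    v_fall = A - v_fall_drop * (drop / v_fall_drop[-1])  # exact trough
    t_fine = np.concatenate((tr_grid, tr_grid[-1] + fine + tf_grid))
    v_fine = np.concatenate((v_rise, v_fall))
    t_out = np.arange(0.0, t_fine[-1], dt_ms)
    return ap.threshold_mV + np.interp(t_out, t_fine, v_fine)


def _warped_rise(v0: float, v1: float, n: int, tau_samples: float) -> np.ndarray:
    """Exponential-shaped segment reaching v1 exactly at the last sample."""
    if n <= 0:
        return np.empty(0)
    u = np.arange(1, n + 1, dtype=float)
    shape = (1 - np.exp(-u / tau_samples)) / (1 - np.exp(-n / tau_samples))
    return v0 + (v1 - v0) * shape


def _spike_schedule(ap: APKinematics, I_pA: float, step_dur_ms: float,
                    n_rheo: int, template_ms: float) -> list[float]:
    """Prescribed spike (threshold-crossing) times within a step, in ms."""
    ratio = I_pA / ap.rheobase_pA
    n_spk = max(2, int(round(n_rheo * ratio)))
    t_first = 15.0 / ratio
    span = step_dur_ms - t_first - template_ms - 5.0
    m = n_spk - 1
    while m >= 1 and span / m < 1.5 * template_ms:
        m -= 1                     # cap rate so spikes never overlap
        n_spk = m + 1
    if m < 1:
        return [t_first]
    g = ap.sfa_ratio ** (1.0 / (m - 2)) if m >= 3 else 1.0
    if abs(g - 1) < 1e-12:
        base = span / m
        isis = [base] * m
    else:
        base = span * (g - 1) / (g ** m - 1)
        isis = [base * g ** k for k in range(m)]
    times = [t_first]
    for isi in isis:
        times.append(times[-1] + isi)
    return times


def generate_current_steps(preset: GenotypePreset, step_amps_pA: list[float],
                           step_dur_ms: float = 250.0, seed: int = 0, *,
                           dt: float = DT_STEPS, pre_ms: float = 50.0,
                           post_ms: float = 50.0, holding_mV: float = -70.0,
                           n_spikes_at_rheobase: int = 6,
                           noise_sd_mV: float = 0.0) -> SweepSet:
    """Current-step family with template action potentials.

    Sweeps at or above the preset rheobase fire a prescribed train whose
    first spike latency shortens with drive, whose ISI progression is
    geometric so the adaptation ratio at rheobase equals the preset SFA,
    and whose waveform is the exact kinematics template. Sub-rheobase
    sweeps show only the leaky subthreshold charging curve
    (steady state = holding + I * R with R = (threshold - holding)/rheobase,
    the closed-form rheobase condition).
    """
    amps = [float(a) for a in step_amps_pA]
    if amps != sorted(amps):
        raise ParameterError("step amplitudes must be sorted ascending")
    ap = preset.ap
    rng = np.random.default_rng(seed)
    r_GOhm = (ap.threshold_mV - holding_mV) / ap.rheobase_pA  # mV/pA = GOhm
    tau_ms = r_GOhm * preset.cm_pF                            # GOhm*pF = ms
    template = ap_template(ap, dt)
    template_ms = template.size * dt * 1e3
    dt_ms = dt * 1e3
    n_pre = int(round(pre_ms / dt_ms))
    n_step = int(round(step_dur_ms / dt_ms))
    n_post = int(round(post_ms / dt_ms))
    tau_samples = tau_ms / dt_ms
    traces = []
    for amp in amps:
        v = np.full(n_pre + n_step + n_post, holding_mV)
        v_inf = holding_mV + amp * r_GOhm
        seg = np.arange(1, n_step + 1, dtype=float)
        if amp < ap.rheobase_pA or amp <= 0:
            v[n_pre:n_pre + n_step] = holding_mV + (v_inf - holding_mV) * (
                1 - np.exp(-seg / tau_samples))
        else:
            spikes_ms = _spike_schedule(ap, amp, step_dur_ms, n_spikes_at_rheobase,
                                        template_ms)
            step = np.full(n_step, ap.threshold_mV + ap.ahp_mV)
            cursor = 0
            v_prev = holding_mV
            for t_ms in spikes_ms:
                i_th = int(round(t_ms / dt_ms))
                step[cursor:i_th] = _warped_rise(v_prev, ap.threshold_mV,
                                                 i_th - cursor, tau_samples)
                i_end = min(i_th + template.size, n_step)
                step[i_th:i_end] = template[: i_end - i_th]
                cursor = i_end
                v_prev = ap.threshold_mV + ap.ahp_mV
            if cursor < n_step:
                tail = np.arange(1, n_step - cursor + 1, dtype=float)
                v_rest_to = min(v_inf, ap.threshold_mV - 2.0)
                step[cursor:] = v_prev + (v_rest_to - v_prev) * (
                    1 - np.exp(-tail / tau_samples))
            v[n_pre:n_pre + n_step] = step
        decay = np.arange(1, n_post + 1, dtype=float)
        v[n_pre + n_step:] = holding_mV + (v[n_pre + n_step - 1] - holding_mV) * np.exp(
            -decay / tau_samples)
        if noise_sd_mV > 0:
            v = v + rng.normal(0.0, noise_sd_mV, v.size)
        traces.append(Trace(v, dt=dt, mode="current_clamp", holding=holding_mV,
                            stim_times=[pre_ms * 1e-3],
                            meta={"genotype": preset.label, "step_pA": amp,
                                  "step_dur_ms": step_dur_ms}))
    return SweepSet(traces, protocol="current_steps", step_amplitudes=amps)


# ---------------------------------------------------------------------------
# Membrane test
# ---------------------------------------------------------------------------

def generate_membrane_test(Ra_MOhm: float, Rm_MOhm: float, Cm_pF: float,
                           step_mV: float = 10.0, noise_sd_pA: float = 0.0,
                           seed: int = 0, *, dt: float = DT_DEFAULT,
                           pre_ms: float = 20.0, dur_ms: float = 60.0
                           ) -> tuple[Trace, GroundTruth]:
    """Voltage-clamp current response of the standard Ra-(Rm||Cm) circuit.

    Instantaneous peak I0 = step/Ra, steady state Iss = step/(Ra+Rm),
    relaxation tau = Cm * Ra*Rm/(Ra+Rm). Currents in pA, step in mV
    (mV/MOhm = nA, hence the factor 1000).
    """
    if min(Ra_MOhm, Rm_MOhm, Cm_pF) <= 0:
        raise ParameterError("Ra, Rm and Cm must all be positive")
    rng = np.random.default_rng(seed)
    n_pre = int(round(pre_ms * 1e-3 / dt))
    n_on = int(round(dur_ms * 1e-3 / dt))
    i0 = 1000.0 * step_mV / Ra_MOhm
    iss = 1000.0 * step_mV / (Ra_MOhm + Rm_MOhm)
    tau_s = Cm_pF * (Ra_MOhm * Rm_MOhm) / (Ra_MOhm + Rm_MOhm) * 1e-6  # pF*MOhm = us
    t = np.arange(n_on) * dt
    x = np.concatenate((np.zeros(n_pre), iss + (i0 - iss) * np.exp(-t / tau_s)))
    if noise_sd_pA > 0:
        x = x + rng.normal(0.0, noise_sd_pA, x.size)
    trace = Trace(x, dt=dt, mode="voltage_clamp", holding=-70.0,
                  stim_times=[pre_ms * 1e-3],
                  meta={"step_mV": step_mV, "kind": "membrane_test"})
    return trace, GroundTruth(true_passive=(Ra_MOhm, Rm_MOhm, Cm_pF))


# ---------------------------------------------------------------------------
# Evoked trials
# ---------------------------------------------------------------------------

def generate_evoked_trials(latency_ms: tuple[float, float], n_trials: int,
                           seed: int, *, amp_pA: float = 50.0, snr: float = 10.0,
                           tau_rise_ms: float = 0.2, tau_decay_ms: float = 2.0,
                           artifact: bool = True, upstate_tail: bool = False,
                           tail_dur_s: float = 2.0, polarity: str = "inward",
                           n_pulses: int = 1, pulse_interval_ms: float = 25.0,
                           intensity_uA: float | None = None,
                           dt: float = DT_DEFAULT
                           ) -> tuple[SweepSet, GroundTruth]:
    """Stimulus-evoked PSC trials with Gaussian onset jitter.

    Each trial: optional 1-ms biphasic stimulation artifact at every pulse
    time, a PSC whose onset is stim + N(mean, sd) ms after the first pulse,
    Gaussian noise with SD = amp/snr, and optionally an Up-state-like
    high-variance tail. True per-trial latencies are recorded.
    """
    mean_ms, sd_ms = float(latency_ms[0]), float(latency_ms[1])
    if sd_ms < 0:
        raise ParameterError("latency sd must be >= 0")
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    stim_s = 0.02
    dur_s = 0.12 + (tail_dur_s + 0.4 if upstate_tail else 0.0)
    n = int(round(dur_s / dt))
    noise_sd = amp_pA / snr
    kernel = generate_psc_kernel(amp_pA, tau_rise_ms, tau_decay_ms, dt)
    pulse_times = [stim_s + k * pulse_interval_ms * 1e-3 for k in range(n_pulses)]
    sign = -1.0 if polarity == "inward" else 1.0
    traces, lat_true = [], []
    for _ in range(n_trials):
        lat = rng.normal(mean_ms, sd_ms) if sd_ms > 0 else mean_ms
        lat_true.append(lat)
        x = rng.normal(0.0, noise_sd, n)
        i_on = int(round((stim_s + lat * 1e-3) / dt))
        seg = min(kernel.size, n - i_on)
        if seg > 0:
            x[i_on:i_on + seg] += kernel[:seg]
        if artifact:
            for pt in pulse_times:
                i_a = int(round(pt / dt))
                n_a = max(2, int(round(0.5e-3 / dt)))
                x[i_a:i_a + n_a] += 20.0 * amp_pA
                x[i_a + n_a:i_a + 2 * n_a] -= 15.0 * amp_pA
        if upstate_tail:
            i_t = i_on + seg
            i_e = min(n, i_t + int(round(tail_dur_s / dt)))
            x[i_t:i_e] += rng.normal(0.0, 8.0 * noise_sd, i_e - i_t)
        meta = {"polarity": polarity, "kind": "evoked"}
        if intensity_uA is not None:
            meta["intensity_uA"] = intensity_uA
        traces.append(Trace(sign * x, dt=dt, mode="voltage_clamp",
                            stim_times=list(pulse_times), meta=meta))
    return (SweepSet(traces, protocol="evoked"),
            GroundTruth(true_latencies_ms=lat_true))
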