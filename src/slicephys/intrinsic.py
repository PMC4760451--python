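"""Passive and active membrane properties from patch-clamp sweeps.

Active features follow current-clamp conventions: spike threshold from the
voltage-versus-dV/dt relation (first sample whose depolarization rate
exceeds 20 V/s), amplitude from threshold to peak, FWHM at the half-way
level between threshold and peak, AHP from threshold to the first trough,
and maximal rise/decay as the extrema of dV/dt over the spike. Derivatives
use central differences on raw samples; an optional Savitzky-Golay
smoothing (off by default) is available for noisy recordings.

Passive properties come from the whole-cell membrane-test transient: the
current response to a small voltage step is fit with a single exponential
I(t) = Iss + (I0 - Iss) exp(-t/tau), from which access resistance
Ra = step/I0, input resistance Rm = step/Iss - Ra and capacitance
Cm = tau (Ra + Rm)/(Ra Rm) follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

from .errors import FeatureError, FitError, ParameterError
from .trace_io import SweepSet, Trace

DVDT_THRESHOLD_V_PER_S = 20.0   # phase-plane threshold criterion, configurable
DOUBLET_ISI_MS = 10.0           # first-ISI bound defining a doublet


@dataclass
class SpikeFeatures:
    t_peak_s: float
    v_threshold_mV: float
    amplitude_mV: float
    fwhm_ms: float
    ahp_mV: float | None               # None when no trough found in window
    max_rise_V_per_s: float
    max_decay_V_per_s: float


@dataclass
class CellIntrinsicProfile:
    vrest_mV: float
    rheobase_pA: float | None
    sfa_ratio: float | None
    cm_pF: float
    rm_MOhm: float
    firing_class: str                  # RS / FS / excluded_doublet / excluded_depolarized

    @property
    def rm_specific_MOhm_per_pF(self) -> float:
        return self.rm_MOhm / self.cm_pF


def _dvdt(v: np.ndarray, dt: float, smooth: bool = False) -> np.ndarray:
    """dV/dt in V/s via central differences (mV / s * 1e-3)."""
    if smooth:
        v = sps.savgol_filter(v, 3, 1)
    return np.gradient(v, dt) * 1e-3


def detect_spikes(trace: Trace, min_peak_mV: float = 0.0,
                  dvdt_crit_V_per_s: float = DVDT_THRESHOLD_V_PER_S,
                  refractory_ms: float = 1.0) -> list[float]:
    """Spike peak times: local maxima above ``min_peak_mV`` preceded (within
    3 ms) by a dV/dt crossing of the threshold criterion; peaks closer than
    the refractory period collapse to the earlier one."""
    v = trace.samples
    dv = _dvdt(v, trace.dt)
    distance = max(1, int(round(refractory_ms * 1e-3 / trace.dt)))
    peaks, _ = sps.find_peaks(v, height=min_peak_mV, distance=distance)
    back = int(round(3e-3 / trace.dt))
    out = []
    for p in peaks:
        if np.any(dv[max(0, p - back):p + 1] >= dvdt_crit_V_per_s):
            out.append(p * trace.dt)
    return out


def ap_threshold_phase_plane(trace: Trace, spike_time: float,
                             dvdt_crit_V_per_s: float = DVDT_THRESHOLD_V_PER_S,
                             window_ms: float = 3.0) -> float:
    """Spike threshold: V at the first sample of the pre-peak window where
    dV/dt reaches the criterion (default 20 V/s)."""
    i_peak = int(round(spike_time / trace.dt))
    i0 = max(0, i_peak - int(round(window_ms * 1e-3 / trace.dt)))
    dv = _dvdt(trace.samples, trace.dt)
    idx = np.nonzero(dv[i0:i_peak + 1] >= dvdt_crit_V_per_s)[0]
    if idx.size == 0:
        raise FeatureError(
            f"dV/dt never reached {dvdt_crit_V_per_s} V/s before the peak")
    return float(trace.samples[i0 + idx[0]])


def _interp_crossing(t: np.ndarray, v: np.ndarray, level: float) -> float:
    """First time v crosses `level` (linear interpolation between samples)."""
    above = v >= level
    idx = np.nonzero(above[1:] != above[:-1])[0]
    if idx.size == 0:
        raise FeatureError("no crossing at the half-amplitude level")
    i = idx[0]
    f = (level - v[i]) / (v[i + 1] - v[i])
    return float(t[i] + f * (t[i + 1] - t[i]))


def ap_features(trace: Trace, spike_time: float, v_threshold: float,
                ahp_window_ms: float = 20.0) -> SpikeFeatures:
    """Per-spike feature bundle; see module docstring for definitions."""
    dt = trace.dt
    v = trace.samples
    i_peak = int(round(spike_time / dt))
    v_peak = float(v[i_peak])
    amplitude = v_peak - v_threshold
    if amplitude <= 0:
        raise FeatureError("peak not above threshold")
    half = v_threshold + amplitude / 2

    i0 = max(0, i_peak - int(round(5e-3 / dt)))
    i_ahp_end = min(v.size, i_peak + int(round(ahp_window_ms * 1e-3 / dt)))
    t = np.arange(i0, i_ahp_end) * dt
    seg = v[i0:i_ahp_end]
    rel_peak = i_peak - i0

    t_up = _interp_crossing(t[: rel_peak + 1], seg[: rel_peak + 1], half)
    t_dn = _interp_crossing(t[rel_peak:], -seg[rel_peak:], -half) \
        if np.any(seg[rel_peak:] < half) else None
    if t_dn is None:
        raise FeatureError("repolarization never reached the half level")
    fwhm_ms = (t_dn - t_up) * 1e3

    post = seg[rel_peak:]
    below = np.nonzero(post < v_threshold)[0]
    if below.size:
        i_tr = rel_peak + below[0] + int(np.argmin(post[below[0]:]))
        ahp = float(seg[i_tr] - v_threshold)
        i_end_spike = i0 + i_tr
    else:
        ahp = None
        i_end_spike = i_ahp_end
    dv = _dvdt(v[i0:i_end_spike + 1], dt)
    return SpikeFeatures(t_peak_s=i_peak * dt, v_threshold_mV=v_threshold,
                         amplitude_mV=amplitude, fwhm_ms=fwhm_ms, ahp_mV=ahp,
                         max_rise_V_per_s=float(dv.max()),
                         max_decay_V_per_s=float(dv.min()))


def rheobase(sweeps: SweepSet, min_peak_mV: float = 0.0) -> float | None:
    """Amplitude of the first current-step sweep evoking >= 1 spike.

    Returns None (not an error) when no sweep spikes.
    """
    if sweeps.protocol != "current_steps":
        raise ParameterError("rheobase requires a current_steps SweepSet")
    for amp, tr in zip(sweeps.step_amplitudes, sweeps.traces):
        if detect_spikes(tr, min_peak_mV):
            return float(amp)
    return None


def sfa_ratio(spike_times: list[float]) -> float | None:
    """Adaptation ratio (ISI_{n-1}+ISI_n)/(ISI_1+ISI_2) at rheobase.

    Requires >= 5 spikes (>= 4 intervals); returns None otherwise.
    """
    if len(spike_times) < 5:
        return None
    isi = np.diff(sorted(spike_times))
    return float((isi[-2] + isi[-1]) / (isi[0] + isi[1]))


def firing_rate(spike_times: list[float]) -> float:
    """(count - 1) / (last - first), robust to onset latency."""
    if len(spike_times) < 2:
        return 0.0
    st = sorted(spike_times)
    return (len(st) - 1) / (st[-1] - st[0])


def classify_firing_type(vrest_mV: float, first_isi_ms: float | None,
                         rate_2x_Hz: float, ahp_2x_mV: float | None) -> str:
    """Inclusion/classification rules for layer-4 neurons.

    Depolarized cells (vrest >= -55 mV) are excluded; fast-spiking requires
    BOTH rate > 60 Hz and AHP < -40 mV at twice rheobase; an initial spike
    doublet (first ISI < 10 ms) excludes the cell; otherwise regular spiking.
    """
    if vrest_mV >= -55.0:
        return "excluded_depolarized"
    if rate_2x_Hz > 60.0 and ahp_2x_mV is not None and ahp_2x_mV < -40.0:
        return "FS"
    if first_isi_ms is not None and first_isi_ms < DOUBLET_ISI_MS:
        return "excluded_doublet"
    return "RS"


def passive_properties(mtest: Trace, step_mV: float
                       ) -> tuple[float, float, float, float]:
    """(Ra_MOhm, Rm_MOhm, Cm_pF, rm_specific) from a membrane-test transient.

    The step onset is taken from ``stim_times`` (or the sample of maximal
    |dI/dt|). The decay is fit with a single exponential by non-linear least
    squares seeded from the sampled peak, tail mean and log-linear slope.
    """
    if step_mV == 0:
        raise FitError("zero voltage step produces no transient")
    x = mtest.samples
    dt = mtest.dt
    if mtest.stim_times:
        i_on = int(round(mtest.stim_times[0] / dt))
    else:
        i_on = int(np.argmax(np.abs(np.diff(x)))) + 1
    y = x[i_on:]
    if y.size < 8:
        raise FitError("too few post-step samples")
    t = np.arange(y.size) * dt
    i0_guess = float(y[0])
    iss_guess = float(y[int(y.size * 0.8):].mean())
    if abs(i0_guess - iss_guess) < 1e-12:
        raise FitError("no transient above noise")
    tau_guess = max(dt, float(np.trapezoid(y - iss_guess, dx=dt) /
                              (i0_guess - iss_guess)))

    def model(tt, i0, iss, tau):
        return iss + (i0 - iss) * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(model, t, y, p0=(i0_guess, iss_guess, tau_guess),
                            maxfev=10000)
    except RuntimeError as e:
        resid = float(np.sqrt(np.mean((model(t, i0_guess, iss_guess,
                                             tau_guess) - y) ** 2)))
        raise FitError(f"membrane-test fit did not converge (rms {resid:.3g} pA)") from e
    i0, iss, tau = popt
    if i0 <= 0 or iss <= 0 or tau <= 0 or i0 <= iss:
        raise FitError(f"non-physical fit: I0={i0:.3g} pA, Iss={iss:.3g} pA, "
                       f"tau={tau:.3g} s")
    ra = 1000.0 * step_mV / i0                   # mV/pA -> GOhm; *1000 -> MOhm
    rm = 1000.0 * step_mV / iss - ra
    cm = tau * 1e6 * (ra + rm) / (ra * rm)       # s/MOhm -> pF (1e6)
    return ra, rm, cm, rm / cm
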