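"""Spontaneous postsynaptic-current (PSC) detection and frequency analysis.

The detector isolates individual synaptic events by shape criteria: a
candidate is a deviation from a local (preceding 5 ms) baseline exceeding
``threshold_mult`` times the noise SD in the configured polarity; it is
accepted only if its 10-90% rise time and single-exponential decay constant
fall within configured bounds. Candidates closer than a minimum separation
collapse to the larger event. For each accepted event the onset time,
amplitude (local baseline to peak, signed by polarity) and rise/decay
kinetics are recorded; per-event instantaneous frequency is the reciprocal
of the interval to the previous event.

Noise is estimated from event-free stretches as the minimum SD over short
sliding windows (100 ms default — long enough for a stable estimate, short
enough that some windows are event-free even at tens of Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from scipy.ndimage import uniform_filter1d

from ._util import ecdf, ecdf_median, sliding_sd_min
from .errors import BaselineError, ParameterError
from .trace_io import Trace


@dataclass
class EventDetectionConfig:
    polarity: str = "inward"
    threshold_mult: float = 3.0
    local_baseline_ms: float = 5.0
    rise_bounds_ms: tuple[float, float] = (0.1, 5.0)
    decay_bounds_ms: tuple[float, float] = (1.0, 50.0)
    min_separation_ms: float = 2.0
    smooth_ms: float = 0.5              # boxcar prior to peak/amplitude reads
    noise_window_s: float = 0.1
    peak_window_ms: float = 8.0
    fit_window_ms: float = 25.0

    def __post_init__(self):
        if self.polarity not in ("inward", "outward"):
            raise ParameterError(f"unknown polarity {self.polarity!r}")
        if self.threshold_mult <= 0:
            raise ParameterError("threshold_mult must be > 0")
        for name in ("rise_bounds_ms", "decay_bounds_ms"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ParameterError(f"{name} must be ordered positive bounds")


@dataclass
class PSCEvent:
    t_onset_s: float
    amplitude_pA: float                # signed: negative for inward events
    rise_10_90_ms: float
    decay_tau_ms: float
    inst_freq_Hz: float | None = None  # 1/interval to previous event
    in_upstate: bool = False


def estimate_noise_sd(trace: Trace, cfg: EventDetectionConfig | None = None) -> float:
    """Raw-signal noise SD from the quietest sliding window."""
    cfg = cfg or EventDetectionConfig()
    y = trace.samples.astype(float)
    w = int(round(cfg.noise_window_s / trace.dt))
    sd, _ = sliding_sd_min(y, min(w, y.size), max(1, w // 2))
    return sd


def _smooth(y: np.ndarray, dt: float, smooth_ms: float) -> np.ndarray:
    k = max(1, int(round(smooth_ms * 1e-3 / dt)))
    return uniform_filter1d(y, k) if k > 1 else y


def detect_psc_events(trace: Trace, cfg: EventDetectionConfig | None = None,
                      upstate_intervals: list[tuple[float, float]] | None = None
                      ) -> list[PSCEvent]:
    """Detect spontaneous PSCs on a voltage-clamp trace.

    Events falling inside ``upstate_intervals`` (if given) are flagged so
    that barrage periods can be excluded from "spontaneous" statistics.
    """
    cfg = cfg or EventDetectionConfig()
    dt = trace.dt
    sign0 = -1.0 if cfg.polarity == "inward" else 1.0
    y_raw = sign0 * trace.samples.astype(float)
    if np.ptp(y_raw) == 0:
        return []
    noise_sd = estimate_noise_sd(trace, cfg)
    if noise_sd <= 0:
        raise BaselineError("degenerate noise estimate (zero SD)")
    thr = cfg.threshold_mult * noise_sd
    y = _smooth(y_raw, dt, cfg.smooth_ms)        # for peak finding/kinetics
    y_amp = _smooth(y_raw, dt, 2 * cfg.smooth_ms)  # low-bias amplitude readout

    # local baseline: mean of the preceding 5 ms (for the event reference
    # level; the window minimum alone is biased low by peak noise)
    w = max(2, int(round(cfg.local_baseline_ms * 1e-3 / dt)))
    c = np.concatenate(([0.0], np.cumsum(y)))
    base = np.full(y.size, y[:w].mean())
    base[w:] = (c[w:-1] - c[:-w - 1]) / w

    # candidate peaks: prominence above the local baseline (valley within
    # the peak window, generalizing the preceding-5-ms mean to overlapping
    # events) must exceed the 3-SD rule; peaks closer than min_separation
    # collapse to the larger via `distance`
    from scipy.signal import find_peaks
    w_prom = 2 * int(round(cfg.peak_window_ms * 1e-3 / dt)) + 1
    min_sep = max(1, int(round(cfg.min_separation_ms * 1e-3 / dt)))
    peaks, props = find_peaks(y, prominence=thr, wlen=w_prom, distance=min_sep)
    fit_w = max(4, int(round(cfg.fit_window_ms * 1e-3 / dt)))

    sign = -1.0 if cfg.polarity == "inward" else 1.0
    events: list[PSCEvent] = []
    for k, pk in enumerate(peaks):
        lb = int(props["left_bases"][k])
        lmin = lb + int(np.argmin(y[lb:pk + 1]))
        # detection gate: valley-referenced prominence against the 3-SD rule;
        # reference level for measurements: preceding-5-ms mean when the
        # stretch is quiet, the pre-event valley when riding on a tail
        if y[pk] - y[lmin] <= thr:
            continue
        ref = float(max(y[lmin], base[lmin]))
        amp = float(y[pk] - ref)
        if amp <= 0:
            continue
        rise = _measure_rise(y, lmin, pk, ref, amp, dt)
        if rise is None:
            continue
        t10, rise_ms = rise
        if rise_ms > cfg.rise_bounds_ms[1]:
            # primary window may span a preceding event; re-measure from the
            # local minimum within 3 ms of the peak
            lmin2 = pk - int(round(3e-3 / dt))
            if lmin2 > lmin:
                lmin2 = lmin2 + int(np.argmin(y[lmin2:pk + 1]))
                ref2, amp2 = float(y[lmin2]), float(y[pk] - y[lmin2])
                rise2 = _measure_rise(y, lmin2, pk, ref2, amp2, dt) \
                    if amp2 > thr else None
                if rise2 is not None:
                    lmin, ref, amp = lmin2, ref2, amp2
                    t10, rise_ms = rise2
        if not (cfg.rise_bounds_ms[0] <= rise_ms <= cfg.rise_bounds_ms[1]):
            continue
        # single-exponential decay fit (log-linear) from the peak; when a
        # following event truncates the window the fitted tau is biased
        # upward and only the fast-blob lower bound can be enforced
        j2 = min(y.size, pk + fit_w)
        truncated = False
        if k + 1 < len(peaks):
            nxt = int(peaks[k + 1])
            if nxt < j2:        # stop at the valley before the next event
                j2 = pk + int(np.argmin(y[pk:nxt + 1])) + 1
                truncated = True
        dec = y[pk:j2] - ref
        ok = dec > max(0.05 * amp, 1e-12)
        tau_ms = math.nan
        if ok.sum() >= 4:
            tt = np.arange(dec.size)[ok] * dt * 1e3
            slope = np.polyfit(tt, np.log(dec[ok]), 1)[0]
            if slope < 0:
                tau_ms = -1.0 / slope
        if math.isnan(tau_ms) or tau_ms > cfg.decay_bounds_ms[1]:
            if not truncated:
                continue
        elif tau_ms < cfg.decay_bounds_ms[0]:
            continue
        t_on = (lmin + t10) * dt
        amp_read = float(y_amp[pk] - ref)
        in_up = any(a <= t_on <= bnd for a, bnd in (upstate_intervals or []))
        events.append(PSCEvent(t_onset_s=t_on, amplitude_pA=sign * amp_read,
                               rise_10_90_ms=rise_ms, decay_tau_ms=tau_ms,
                               in_upstate=in_up))
    for prev, ev in zip(events, events[1:]):
        ev.inst_freq_Hz = 1.0 / (ev.t_onset_s - prev.t_onset_s)
    return events


def _measure_rise(y: np.ndarray, lmin: int, pk: int, ref: float, amp: float,
                  dt: float) -> tuple[float, float] | None:
    """(fractional 10%-crossing index rel. lmin, 10-90% rise time in ms).

    Returns None when the level crossings cannot be located.
    """
    seg = y[lmin:pk + 1] - ref
    t10 = _last_below(seg, 0.1 * amp)
    t90 = _last_below(seg, 0.9 * amp)
    if t10 is None or t90 is None or t90 <= t10:
        return None
    return t10, (t90 - t10) * dt * 1e3


def _last_below(seg: np.ndarray, level: float) -> int | None:
    """Fractional index of the last upward crossing of `level` before the end."""
    below = np.nonzero(seg[:-1] <= level)[0]
    if below.size == 0:
        return None
    i = below[-1]
    if seg[i + 1] == seg[i]:
        return float(i)
    return float(i) + (level - seg[i]) / (seg[i + 1] - seg[i])


@dataclass
class FrequencyDistribution:
    n_events: int
    freqs_Hz: list[float]
    median_Hz: float | None
    ecdf: tuple[np.ndarray, np.ndarray] = field(repr=False,
                                                default=(None, None))


def event_frequency_distribution(events: list[PSCEvent],
                                 exclude_in_upstate: bool = True
                                 ) -> FrequencyDistribution:
    """Instantaneous-frequency distribution (1/inter-event interval).

    With fewer than two usable events the result carries an undefined
    median rather than raising.
    """
    sel = [e for e in events if not (exclude_in_upstate and e.in_upstate)]
    times = sorted(e.t_onset_s for e in sel)
    freqs = [1.0 / (b - a) for a, b in zip(times, times[1:]) if b > a]
    if not freqs:
        return FrequencyDistribution(len(sel), [], None)
    return FrequencyDistribution(len(sel), freqs, ecdf_median(freqs), ecdf(freqs))


def compare_frequency_distributions(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on instantaneous frequencies.

    Accepts raw samples (lists/arrays) or FrequencyDistribution objects;
    returns (D, p) with scipy's exact small-sample p where applicable.
    """
    xa = np.asarray(a.freqs_Hz if isinstance(a, FrequencyDistribution) else a, float)
    xb = np.asarray(b.freqs_Hz if isinstance(b, FrequencyDistribution) else b, float)
    if xa.size == 0 or xb.size == 0:
        raise ParameterError("both samples must be non-empty")
    res = sstats.ks_2samp(xa, xb)
    return float(res.statistic), float(res.pvalue)
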