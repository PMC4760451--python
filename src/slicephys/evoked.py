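"""Evoked-response onset latency, connection classification, intensity curve.

Onset rule: scanning away from the stimulus (after a short artifact
blanking window), the response onset is the first sample deviating from the
mean of the preceding 5 ms of data by more than three of that window's
standard deviations. The 5-ms window slides with the candidate sample.
With a 4-pulse 40-Hz stimulus train the latency is measured from the first
pulse only.

An excitatory connection is called monosynaptic when the coefficient of
variation (CV = 100 * SD/mean) of its onset latency across trials is below
10%; inhibitory responses in barrel cortex are taken to be polysynaptic, so
the CV gate is not applied to them (the CV is still reported). At least
five trials are required for any call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .trace_io import Trace


@dataclass
class EvokedTrial:
    trace: Trace
    stim_time_s: float
    intensity_uA: float | None = None
    blank_ms: float = 1.0
    latency_ms: float | None = None

    def __post_init__(self):
        if not (0 <= self.stim_time_s <= self.trace.duration_s):
            raise ParameterError("stim_time outside trace")


@dataclass
class ConnectionCall:
    latencies_ms: list[float]
    mean_ms: float | None
    cv_percent: float | None
    call: str                       # monosynaptic / polysynaptic / undetermined


def detect_onset(trial: EvokedTrial, *, sd_mult: float = 3.0,
                 pre_window_ms: float = 5.0, polarity: str | None = None,
                 scan_limit_ms: float | None = None) -> float | None:
    """Onset latency in ms after the stimulus, or None for no response.

    Samples inside the blanking window after each stimulus pulse are
    replaced by linear interpolation before scanning, so stimulation
    artifacts cannot trip the threshold. ``polarity`` restricts the
    deviation direction ('positive'/'negative'; default from the trace's
    recorded polarity metadata, else either direction). ``scan_limit_ms``
    bounds the scan (e.g. to stop before the next pulse of a train).
    """
    tr = trial.trace
    dt = tr.dt
    x = tr.samples.astype(float).copy()
    pulses = tr.stim_times if tr.stim_times else [trial.stim_time_s]
    n_bl = int(round(trial.blank_ms * 1e-3 / dt))
    for pt in pulses:
        i_a = int(round(pt / dt))
        i_b = min(x.size - 1, i_a + n_bl)
        if i_b > i_a:
            x[i_a:i_b + 1] = np.linspace(x[max(0, i_a - 1)], x[i_b], i_b - i_a + 1)

    if polarity is None:
        polarity = {"inward": "negative", "outward": "positive"}.get(
            tr.meta.get("polarity"), "either")
    w = int(round(pre_window_ms * 1e-3 / dt))
    i_stim = int(round(trial.stim_time_s / dt))
    i_start = i_stim + n_bl + 1
    if i_start - w < 0:
        raise ParameterError("not enough pre-onset data for the 5-ms window")
    i_end = x.size
    if scan_limit_ms is not None:
        i_end = min(i_end, i_stim + int(round(scan_limit_ms * 1e-3 / dt)))
    elif len(pulses) > 1:
        i_end = min(i_end, int(round(pulses[1] / dt)))

    if i_end <= i_start:
        return None
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    idx = np.arange(i_start, i_end)
    mu = (c1[idx] - c1[idx - w]) / w              # mean of preceding w samples
    var = np.maximum((c2[idx] - c2[idx - w]) / w - mu ** 2, 0.0)
    sd = np.sqrt(var)
    dev = x[idx] - mu
    if polarity == "positive":
        hit = dev > sd_mult * sd
    elif polarity == "negative":
        hit = -dev > sd_mult * sd
    else:
        hit = np.abs(dev) > sd_mult * sd
    hit &= sd > 0
    # noise guard: the crossing must hold for two consecutive samples (the
    # first is reported); a single-sample 3-SD excursion over a many-sample
    # scan is overwhelmingly likely to be noise
    sustained = hit.copy()
    sustained[:-1] &= hit[1:]
    sustained[-1] = False
    j = np.nonzero(sustained)[0]
    if j.size == 0:
        return None
    # sub-sample refinement: interpolate the crossing of the 3-SD level
    # between the hit sample and its predecessor
    k = j[0]
    i_hit = int(idx[k])
    sgn = 1.0 if dev[k] > 0 else -1.0
    level = mu[k] + sgn * sd_mult * sd[k]
    x0, x1 = x[i_hit - 1], x[i_hit]
    frac = 1.0
    if x1 != x0:
        frac = float(np.clip((level - x0) / (x1 - x0), 0.0, 1.0))
    return float((i_hit - 1 + frac - i_stim) * dt * 1e3)


def measure_latencies(trials: list[EvokedTrial], **kwargs) -> list[float]:
    """detect_onset over trials, filling ``latency_ms``; drops no-responses."""
    out = []
    for t in trials:
        lat = detect_onset(t, **kwargs)
        t.latency_ms = lat
        if lat is not None:
            out.append(lat)
    return out


def classify_connection(latencies_ms, component: str = "excitatory",
                        cv_limit_percent: float = 10.0,
                        min_trials: int = 5) -> ConnectionCall:
    """Monosynaptic/polysynaptic call from the latency CV across trials.

    CV uses the sample SD (ddof=1). Inhibitory responses bypass the CV gate
    and are reported polysynaptic with their CV.
    """
    if component not in ("excitatory", "inhibitory"):
        raise ParameterError(f"unknown component {component!r}")
    lats = [float(v) for v in latencies_ms]
    if len(lats) < min_trials:
        return ConnectionCall(lats, None, None, "undetermined")
    mean = float(np.mean(lats))
    sd = float(np.std(lats, ddof=1))
    cv = 100.0 * sd / mean
    if component == "inhibitory":
        call = "polysynaptic"
    else:
        call = "monosynaptic" if cv < cv_limit_percent else "polysynaptic"
    return ConnectionCall(lats, mean, cv, call)


@dataclass
class IntensityCurve:
    peak_intensity_uA: float
    intensities_uA: list[float]
    mean_durations_s: list[float]
    normalized: dict[int, float] = field(default_factory=dict)  # multiple -> ratio


def evoked_upstate_intensity_curve(durations_by_intensity: dict[float, list[float]],
                                   multiples: tuple[int, ...] = (1, 2, 3),
                                   rel_tol: float = 0.05) -> IntensityCurve:
    """Evoked Up-state duration versus stimulus intensity, peak-normalized.

    Per intensity, the mean evoked duration; the most effective intensity is
    the argmax of the mean (ties resolved to the lowest intensity). The
    curve is reported as duration/peak-duration at integer multiples of the
    most effective intensity (intensities matching within ``rel_tol``).
    """
    if len(durations_by_intensity) < 2:
        raise ParameterError("need at least two intensity levels")
    intensities = sorted(durations_by_intensity)
    means = [float(np.mean(durations_by_intensity[i])) for i in intensities]
    best = max(range(len(intensities)), key=lambda k: (means[k], -intensities[k]))
    peak_int, peak_dur = intensities[best], means[best]
    normalized = {}
    for m in multiples:
        target = m * peak_int
        for inten, mu in zip(intensities, means):
            if abs(inten - target) <= rel_tol * target:
                normalized[m] = mu / peak_dur
                break
    return IntensityCurve(peak_intensity_uA=peak_int, intensities_uA=intensities,
                          mean_durations_s=means, normalized=normalized)
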