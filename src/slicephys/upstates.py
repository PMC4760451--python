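"""Up-state detection in field and intracellular recordings.

The detection rule operates on non-overlapping 10-ms bins of a prepared
signal (field: 3-300 Hz band-passed and rectified; intracellular: raw
membrane potential minus its Down-state level):

1. a quiet-period baseline SD is estimated (automatically, as the minimum
   over 1-s sliding windows stepped by 100 ms, or from an explicit window);
2. bins whose sample SD exceeds ``threshold_mult`` (default 5) times the
   baseline SD are active;
3. a candidate Up state is a maximal run of active bins in which
   sub-threshold runs no longer than ``release_ms`` (default 100 ms) are
   bridged — a longer return below threshold terminates the event;
4. candidates shorter than ``min_duration_ms`` (default 300 ms) are
   discarded;
5. surviving events separated by no more than ``merge_window_s`` (default
   1 s) are merged into a single event (``n_merged`` counts the raw
   events).

Events touching the trace boundary are flagged truncated and excluded from
duration statistics by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ._util import ecdf, ecdf_median, sliding_sd_min
from .errors import BaselineError, ParameterError, SamplingError, ValidationError
from .trace_io import Trace


@dataclass
class UpStateDetectionConfig:
    bandpass_Hz: tuple[float, float] = (3.0, 300.0)
    bin_ms: float = 10.0
    threshold_mult: float = 5.0
    min_duration_ms: float = 300.0
    release_ms: float = 100.0
    merge_window_s: float = 1.0
    baseline_window_s: float = 1.0      # auto-baseline sliding window
    baseline_step_s: float = 0.1
    baseline_span: tuple[float, float] | None = None   # explicit override

    def __post_init__(self):
        if self.threshold_mult <= 0:
            raise ValidationError("threshold_mult must be > 0")
        for name in ("min_duration_ms", "release_ms"):
            v = getattr(self, name)
            if abs(v / self.bin_ms - round(v / self.bin_ms)) > 1e-9:
                raise ValidationError(f"{name} must be a multiple of bin_ms")


@dataclass
class UpStateEvent:
    start_s: float
    end_s: float
    area: float = 0.0
    n_merged: int = 1
    truncated: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def merge_intervals(intervals, merge_window_s: float,
                    with_counts: bool = False):
    """Merge sorted (start, end) intervals whose gap is <= the window."""
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    merged: list[list[float]] = []
    counts: list[int] = []
    for a, b in ivs:
        if merged and a - merged[-1][1] <= merge_window_s:
            merged[-1][1] = max(merged[-1][1], b)
            counts[-1] += 1
        else:
            merged.append([a, b])
            counts.append(1)
    out = [(a, b) for a, b in merged]
    return (out, counts) if with_counts else out


def preprocess_field(trace: Trace, cfg: UpStateDetectionConfig | None = None) -> Trace:
    """Zero-phase band-pass (4th-order Butterworth) then full-wave rectify."""
    cfg = cfg or UpStateDetectionConfig()
    fs = 1.0 / trace.dt
    lo, hi = cfg.bandpass_Hz
    if hi >= fs / 2:
        raise SamplingError(
            f"sampling rate {fs:.0f} Hz too low for a {hi:.0f} Hz band edge")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = np.abs(signal.sosfiltfilt(sos, trace.samples))
    return Trace(y, dt=trace.dt, mode=trace.mode, holding=trace.holding,
                 stim_times=trace.stim_times, meta=dict(trace.meta))


def preprocess_intracellular(trace: Trace, bin_mV: float = 0.5) -> Trace:
    """Subtract the Down-state level, estimated as the histogram mode.

    The mode of a 0.5-mV-bin histogram of the membrane potential is robust
    to the fraction of time spent in Up states (unlike the mean).
    """
    x = trace.samples
    edges = np.arange(x.min(), x.max() + 2 * bin_mV, bin_mV)
    hist, _ = np.histogram(x, bins=edges)
    i = int(np.argmax(hist))
    level = 0.5 * (edges[i] + edges[i + 1])
    return Trace(x - level, dt=trace.dt, mode=trace.mode, holding=trace.holding,
                 stim_times=trace.stim_times, meta=dict(trace.meta))


def estimate_baseline_sd(trace: Trace, cfg: UpStateDetectionConfig | None = None
                         ) -> tuple[float, tuple[float, float]]:
    """Baseline (quiet-period) SD and the window it came from.

    Auto mode slides a ``baseline_window_s`` window in ``baseline_step_s``
    steps and keeps the window of minimal SD — a reproducible stand-in for
    visually picking a stretch of network inactivity. An explicit
    ``baseline_span`` overrides the search.
    """
    cfg = cfg or UpStateDetectionConfig()
    x = trace.samples
    if cfg.baseline_span is not None:
        a, b = cfg.baseline_span
        i0, i1 = int(round(a / trace.dt)), int(round(b / trace.dt))
        if not (0 <= i0 < i1 <= x.size):
            raise ParameterError("explicit baseline span outside trace")
        sd = float(np.std(x[i0:i1]))
        window = (a, b)
    else:
        w = int(round(cfg.baseline_window_s / trace.dt))
        step = max(1, int(round(cfg.baseline_step_s / trace.dt)))
        if w > x.size:
            raise ParameterError("trace shorter than the baseline window")
        sd, start = sliding_sd_min(x, w, step)
        window = (start * trace.dt, (start + w) * trace.dt)
    if sd <= 0:
        raise BaselineError("degenerate baseline: zero SD (constant trace?)")
    return sd, window


def _bin_sd(x: np.ndarray, bin_samples: int) -> np.ndarray:
    nb = x.size // bin_samples          # partial trailing bin ignored
    return x[: nb * bin_samples].reshape(nb, bin_samples).std(axis=1)


def detect_up_states(trace: Trace, cfg: UpStateDetectionConfig | None = None,
                     baseline_sd: float | None = None) -> list[UpStateEvent]:
    """Apply the binned-SD threshold rules; see module docstring.

    ``trace`` must already be prepared (:func:`preprocess_field` for field /
    voltage-clamp recordings, :func:`preprocess_intracellular` for membrane
    potential). If ``baseline_sd`` is omitted it is estimated automatically.
    """
    cfg = cfg or UpStateDetectionConfig()
    if baseline_sd is None:
        baseline_sd, _ = estimate_baseline_sd(trace, cfg)
    if baseline_sd <= 0:
        raise ParameterError("baseline_sd must be > 0")
    bin_samples = int(round(cfg.bin_ms * 1e-3 / trace.dt))
    if bin_samples < 2:
        raise SamplingError("fewer than 2 samples per bin; dt too coarse")
    bin_s = bin_samples * trace.dt
    sds = _bin_sd(trace.samples, bin_samples)
    supra = sds > cfg.threshold_mult * baseline_sd
    release_bins = int(round(cfg.release_ms / cfg.bin_ms))
    min_bins = int(round(cfg.min_duration_ms / cfg.bin_ms))

    # maximal runs of supra bins, then bridge sub-threshold runs <= release
    runs = []
    i = 0
    nb = supra.size
    while i < nb:
        if supra[i]:
            j = i
            while j + 1 < nb and supra[j + 1]:
                j += 1
            runs.append([i, j])        # inclusive bin indices
            i = j + 1
        else:
            i += 1
    candidates: list[list[int]] = []
    for r in runs:
        if candidates and r[0] - candidates[-1][1] - 1 <= release_bins:
            candidates[-1][1] = r[1]
        else:
            candidates.append(list(r))

    events = [c for c in candidates if (c[1] - c[0] + 1) >= min_bins]
    intervals = [(c[0] * bin_s, (c[1] + 1) * bin_s) for c in events]
    merged, counts = merge_intervals(intervals, cfg.merge_window_s, with_counts=True)

    x = trace.samples
    out = []
    for (a, b), nm in zip(merged, counts):
        i0, i1 = int(round(a / trace.dt)), int(round(b / trace.dt))
        area = float(np.trapezoid(np.abs(x[i0:i1]), dx=trace.dt))
        truncated = (i0 == 0) or (i1 >= (x.size // bin_samples) * bin_samples)
        out.append(UpStateEvent(start_s=a, end_s=b, area=area, n_merged=nm,
                                truncated=truncated))
    return out


@dataclass
class UpStateSummary:
    n_events: int
    record_duration_s: float
    durations_s: list[float]                       # non-truncated events
    duration_median_s: float | None
    rate_count_Hz: float                           # events / recording time
    intervals_s: list[float]                       # onset-to-onset
    rate_iei_median_Hz: float | None               # median of 1/interval
    duration_ecdf: tuple[np.ndarray, np.ndarray] = field(repr=False,
                                                         default=(None, None))


def upstate_statistics(events: list[UpStateEvent], record_duration_s: float,
                       include_truncated: bool = False) -> UpStateSummary:
    """Duration/frequency summary for one recording.

    Truncated (boundary) events count toward the event rate but are
    excluded from duration statistics unless requested. An empty event list
    yields a zero-count summary with undefined medians rather than an error.
    """
    if record_duration_s <= 0:
        raise ParameterError("record_duration_s must be > 0")
    durs = [e.duration_s for e in events if include_truncated or not e.truncated]
    onsets = sorted(e.start_s for e in events)
    ieis = list(np.diff(onsets)) if len(onsets) >= 2 else []
    return UpStateSummary(
        n_events=len(events),
        record_duration_s=record_duration_s,
        durations_s=durs,
        duration_median_s=ecdf_median(durs) if durs else None,
        rate_count_Hz=len(events) / record_duration_s,
        intervals_s=ieis,
        rate_iei_median_Hz=ecdf_median([1.0 / i for i in ieis]) if ieis else None,
        duration_ecdf=ecdf(durs) if durs else (np.array([]), np.array([])),
    )


def upstate_charge_transfer(trace: Trace, event: UpStateEvent,
                            local_baseline: float) -> float:
    """Charge moved during one Up state, in pC.

    Trapezoidal integral of |I - baseline| over the event on the *raw*
    voltage-clamp current (pA * s = pC).
    """
    i0 = int(round(event.start_s / trace.dt))
    i1 = int(round(event.end_s / trace.dt))
    if not (0 <= i0 < i1 <= trace.n_samples):
        raise ParameterError("event outside trace extent")
    dev = np.abs(trace.samples[i0:i1] - local_baseline)
    return float(np.trapezoid(dev, dx=trace.dt))
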