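"""Small shared numeric helpers (ECDF, sliding-window SD)."""

from __future__ import annotations

import numpy as np


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted values and cumulative probabilities i/n."""
    x = np.sort(np.asarray(values, dtype=float))
    return x, np.arange(1, x.size + 1) / x.size


def ecdf_median(values) -> float:
    """50% probability read from the ECDF by linear interpolation.

    Equivalent to the linearly interpolated sample median.
    """
    return float(np.quantile(np.asarray(values, dtype=float), 0.5))


def sliding_sd_min(x: np.ndarray, window: int, step: int
                   ) -> tuple[float, int]:
    """(smallest SD, window start index) over sliding windows.

    Population SD per window, computed with cumulative sums; windows start
    at multiples of ``step`` and the final full window is always included.
    """
    n = x.size
    if window > n:
        raise ValueError("window longer than signal")
    starts = np.arange(0, n - window + 1, step)
    if starts[-1] != n - window:
        starts = np.append(starts, n - window)
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    s1 = c1[starts + window] - c1[starts]
    s2 = c2[starts + window] - c2[starts]
    var = np.maximum(s2 / window - (s1 / window) ** 2, 0.0)
    i = int(np.argmin(var))
    return float(np.sqrt(var[i])), int(starts[i])
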