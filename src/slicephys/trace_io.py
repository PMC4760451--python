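"""Recording containers and file round-trip.

The package's canonical in-memory objects are :class:`Trace` (one uniformly
sampled signal plus acquisition metadata) and :class:`SweepSet` (an ordered
group of sweeps sharing sampling interval and recording mode, e.g. a
current-step family). Canonical internal units are mV (current clamp /
field), pA (voltage clamp) and seconds; readers convert on ingest and keep
the original unit string in ``meta``.

Two self-describing on-disk formats are supported:

* **CSV** — a hand-editable fixture format: a header block of ``# key=value``
  lines (``dt`` and ``mode`` are mandatory) followed by one column per sweep.
  Samples are written with 17 significant digits, which round-trips IEEE-754
  doubles exactly.
* **HDF5** — ``/sweeps`` (n_sweeps x n_samples), root attributes ``dt``,
  ``mode``, ``units``, ``protocol``, optional ``/stim_times`` and
  ``/step_amplitudes`` datasets, free-form metadata as attributes of
  ``/meta``. Bit-exact round-trip.

ABF and NWB ingestion are optional adapters behind the same contract; they
require ``pyabf`` / ``pynwb`` and raise :class:`MissingDependencyError`
when the backend is absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    FormatError,
    MetadataError,
    MissingDependencyError,
    ValidationError,
)

MODES = ("current_clamp", "voltage_clamp", "field")
PROTOCOLS = ("spontaneous", "current_steps", "membrane_test", "evoked")

#: display units per recording mode (canonical internal units)
MODE_UNITS = {"current_clamp": "mV", "voltage_clamp": "pA", "field": "mV"}


@dataclass
class Trace:
    """One uniformly sampled recording channel.

    Parameters
    ----------
    samples
        Signal in canonical units (mV for current-clamp/field, pA for
        voltage-clamp).
    dt
        Sampling interval in seconds.
    mode
        One of ``current_clamp``, ``voltage_clamp``, ``field``.
    holding
        Holding potential (mV) or current (pA), if applicable.
    stim_times
        Stimulus onset times in seconds, strictly increasing, within the
        trace extent.
    meta
        Free-form key/value metadata (cell id, genotype, intensity_uA, ...).
    """

    samples: np.ndarray
    dt: float
    mode: str
    holding: float | None = None
    stim_times: list[float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D array")
        if not np.isfinite(self.samples).all():
            raise ValidationError("samples contain NaN/Inf")
        if not (self.dt > 0):
            raise ValidationError(f"dt must be > 0, got {self.dt}")
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.stim_times is not None:
            st = [float(t) for t in self.stim_times]
            if any(b <= a for a, b in zip(st, st[1:])):
                raise ValidationError("stim_times must be strictly increasing")
            if st and (st[0] < 0 or st[-1] > self.duration_s):
                raise ValidationError("stim_times outside trace extent")
            self.stim_times = st

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size * self.dt

    @property
    def units(self) -> str:
        return MODE_UNITS[self.mode]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (first sample at t = 0)."""
        return np.arange(self.samples.size) * self.dt


@dataclass
class SweepSet:
    """Ordered sweeps sharing dt, mode and length."""

    traces: list[Trace]
    protocol: str = "spontaneous"
    step_amplitudes: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValidationError("SweepSet requires at least one sweep")
        if self.protocol not in PROTOCOLS:
            raise ValidationError(
                f"unknown protocol {self.protocol!r}; expected one of {PROTOCOLS}"
            )
        t0 = self.traces[0]
        for i, tr in enumerate(self.traces):
            if tr.dt != t0.dt or tr.mode != t0.mode or tr.n_samples != t0.n_samples:
                raise ValidationError(f"sweep {i} differs in dt/mode/length")
        if self.protocol == "current_steps":
            if self.step_amplitudes is None or len(self.step_amplitudes) != len(self.traces):
                raise ValidationError(
                    "current_steps protocol requires one step amplitude per sweep"
                )
            self.step_amplitudes = [float(a) for a in self.step_amplitudes]

    @property
    def dt(self) -> float:
        return self.traces[0].dt

    @property
    def mode(self) -> str:
        return self.traces[0].mode

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def __getitem__(self, i: int) -> Trace:
        return self.traces[i]


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _format_float_list(values: Sequence[float]) -> str:
    return ",".join(repr(float(v)) for v in values)


def _parse_float_list(text: str) -> list[float]:
    text = text.strip()
    return [float(tok) for tok in text.split(",")] if text else []


def _write_csv(sweeps: SweepSet, path: Path) -> None:
    t0 = sweeps.traces[0]
    lines = [
        f"# dt={t0.dt!r}",
        f"# mode={t0.mode}",
        f"# units={t0.units}",
        f"# protocol={sweeps.protocol}",
    ]
    if t0.holding is not None:
        lines.append(f"# holding={t0.holding!r}")
    if t0.stim_times:
        lines.append(f"# stim_times={_format_float_list(t0.stim_times)}")
    if sweeps.step_amplitudes is not None:
        lines.append(f"# step_amplitudes={_format_float_list(sweeps.step_amplitudes)}")
    for k, v in sorted(t0.meta.items()):
        lines.append(f"# meta.{k}={v}")
    data = np.column_stack([tr.samples for tr in sweeps.traces])
    body = "\n".join(" ".join(repr(float(x)) for x in row) for row in data)
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def _read_csv(path: Path) -> SweepSet:
    header: dict[str, str] = {}
    data_lines: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" not in body:
                raise FormatError(f"malformed header line in {path}: {raw!r}")
            k, v = body.split("=", 1)
            header[k.strip()] = v.strip()
        else:
            data_lines.append(line)
    if "dt" not in header or "mode" not in header:
        raise MetadataError(f"{path}: CSV header must define dt and mode")
    dt = float(header["dt"])
    mode = header["mode"]
    if not data_lines:
        raise FormatError(f"{path}: no sample rows")
    data = np.array([[float(x) for x in ln.replace(",", " ").split()] for ln in data_lines])
    holding = float(header["holding"]) if "holding" in header else None
    stim = _parse_float_list(header["stim_times"]) if "stim_times" in header else None
    meta = {k[5:]: v for k, v in header.items() if k.startswith("meta.")}
    traces = []
    for j in range(data.shape[1]):
        col = data[:, j]
        if not np.isfinite(col).all():
            raise ValidationError(f"{path}: sweep {j} contains NaN/Inf samples")
        traces.append(Trace(col, dt=dt, mode=mode, holding=holding,
                            stim_times=list(stim) if stim else None, meta=dict(meta)))
    steps = _parse_float_list(header["step_amplitudes"]) if "step_amplitudes" in header else None
    return SweepSet(traces, protocol=header.get("protocol", "spontaneous"),
                    step_amplitudes=steps)


# ---------------------------------------------------------------------------
# HDF5 layout
# ---------------------------------------------------------------------------

def _write_hdf5(sweeps: SweepSet, path: Path) -> None:
    import h5py

    t0 = sweeps.traces[0]
    with h5py.File(path, "w") as f:
        f.create_dataset("sweeps", data=np.vstack([tr.samples for tr in sweeps.traces]))
        f.attrs["dt"] = t0.dt
        f.attrs["mode"] = t0.mode
        f.attrs["units"] = t0.units
        f.attrs["protocol"] = sweeps.protocol
        if t0.holding is not None:
            f.attrs["holding"] = t0.holding
        if t0.stim_times:
            f.create_dataset("stim_times", data=np.asarray(t0.stim_times))
        if sweeps.step_amplitudes is not None:
            f.create_dataset("step_amplitudes", data=np.asarray(sweeps.step_amplitudes))
        g = f.create_group("meta")
        for k, v in t0.meta.items():
            g.attrs[k] = v


def _read_hdf5(path: Path) -> SweepSet:
    import h5py

    with h5py.File(path, "r") as f:
        if "sweeps" not in f:
            raise FormatError(f"{path}: missing /sweeps dataset")
        if "dt" not in f.attrs or "mode" not in f.attrs:
            raise MetadataError(f"{path}: missing dt/mode attributes")
        data = f["sweeps"][()]
        dt = float(f.attrs["dt"])
        mode = str(f.attrs["mode"])
        protocol = str(f.attrs.get("protocol", "spontaneous"))
        holding = float(f.attrs["holding"]) if "holding" in f.attrs else None
        stim = list(map(float, f["stim_times"][()])) if "stim_times" in f else None
        steps = list(map(float, f["step_amplitudes"][()])) if "step_amplitudes" in f else None
        meta = {k: _h5_scalar(v) for k, v in f["meta"].attrs.items()} if "meta" in f else {}
    traces = []
    for j, row in enumerate(np.atleast_2d(data)):
        if not np.isfinite(row).all():
            raise ValidationError(f"{path}: sweep {j} contains NaN/Inf samples")
        traces.append(Trace(row, dt=dt, mode=mode, holding=holding,
                            stim_times=list(stim) if stim else None, meta=dict(meta)))
    return SweepSet(traces, protocol=protocol, step_amplitudes=steps)


def _h5_scalar(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# Optional acquisition-format adapters
# ---------------------------------------------------------------------------

def _read_abf(path: Path) -> SweepSet:  # pragma: no cover - optional backend
    try:
        import pyabf
    except ImportError as e:
        raise MissingDependencyError("reading ABF files requires the 'pyabf' package") from e
    abf = pyabf.ABF(str(path))
    dt = 1.0 / abf.dataRate
    mode = "voltage_clamp" if "pA" in (abf.sweepUnitsY or "") else "current_clamp"
    traces = []
    for i in abf.sweepList:
        abf.setSweep(i)
        traces.append(Trace(np.asarray(abf.sweepY, float), dt=dt, mode=mode,
                            meta={"source": str(path), "sweep": i}))
    return SweepSet(traces)


def _read_nwb(path: Path) -> SweepSet:  # pragma: no cover - optional backend
    try:
        import pynwb  # noqa: F401
    except ImportError as e:
        raise MissingDependencyError("reading NWB files requires the 'pynwb' package") from e
    raise NotImplementedError("NWB ingestion adapter")


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_traces(path: str | Path, format: str | None = None) -> SweepSet:
    """Read a sweep set from disk.

    ``format`` may be ``csv``, ``hdf5``, ``abf`` or ``nwb``; when omitted it
    is inferred from the file suffix. Non-uniform sampling (only possible in
    the optional backends) raises :class:`SamplingError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".txt": "csv", ".h5": "hdf5", ".hdf5": "hdf5",
                  ".abf": "abf", ".nwb": "nwb"}.get(path.suffix.lower())
        if format is None:
            raise FormatError(f"cannot infer format from suffix {path.suffix!r}")
    readers = {"csv": _read_csv, "hdf5": _read_hdf5, "abf": _read_abf, "nwb": _read_nwb}
    if format not in readers:
        raise FormatError(f"unknown format {format!r}")
    return readers[format](path)


def write_traces(sweeps: SweepSet, path: str | Path, format: str | None = None) -> Path:
    """Write a sweep set; the result is readable back by :func:`read_traces`."""
    if not isinstance(sweeps, SweepSet):
        raise ValidationError("write_traces expects a SweepSet")
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".txt": "csv", ".h5": "hdf5", ".hdf5": "hdf5"}.get(
            path.suffix.lower())
        if format is None:
            raise FormatError(f"cannot infer format from suffix {path.suffix!r}")
    if format == "csv":
        _write_csv(sweeps, path)
    elif format == "hdf5":
        _write_hdf5(sweeps, path)
    else:
        raise FormatError(f"unsupported output format {format!r}")
    return path
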