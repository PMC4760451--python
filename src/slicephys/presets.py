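"""Genotype parameter presets driving the synthetic generators.

A :class:`GenotypePreset` bundles every quantity the generators need to
emulate recordings from one genotype: the passive single-compartment
circuit, resting potential, Up/Down-state kinetics, spontaneous-PSC
frequencies, evoked-latency distributions and the action-potential
kinematics bundle. The two shipped presets (``euploid``, ``trisomic``)
are plain key/value text files under ``slicephys/presets/`` so they can be
inspected and edited without touching code; :func:`load_preset` also
accepts a path to a user-supplied file with the same keys.

Latency jitter convention: the per-trial SD is the published SEM scaled by
sqrt(n of cells), so that a 10-trial experiment reproduces the printed
mean +/- SEM.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ParameterError, ValidationError

BUNDLED = ("euploid", "trisomic")


@dataclass(frozen=True)
class APKinematics:
    """Action-potential feature bundle (current-clamp conventions)."""

    rheobase_pA: float
    amplitude_mV: float
    ahp_mV: float          # threshold -> first trough, signed (negative)
    fwhm_ms: float
    threshold_mV: float
    sfa_ratio: float
    max_rise_V_per_s: float
    max_decay_V_per_s: float

    def __post_init__(self):
        if self.rheobase_pA <= 0 or self.amplitude_mV <= 0 or self.fwhm_ms <= 0:
            raise ValidationError("rheobase, amplitude and FWHM must be positive")
        if not (self.max_decay_V_per_s < 0 < self.max_rise_V_per_s):
            raise ValidationError("expected max_decay < 0 < max_rise")


@dataclass(frozen=True)
class GenotypePreset:
    label: str
    cm_pF: float
    rm_specific_MOhm_per_pF: float
    ra_MOhm: float
    vrest_mV: float
    upstate_duration_median_s: float
    upstate_rate_median_Hz: float
    epsc_freq_median_Hz: float
    ipsc_freq_median_Hz: float
    epsc_latency_ms: tuple[float, float]   # (mean, per-trial SD)
    ipsc_latency_ms: tuple[float, float]
    ap: APKinematics
    reversal_exc_mV: float = 20.0
    reversal_inh_mV: float = -45.0

    def __post_init__(self):
        for name in ("cm_pF", "rm_specific_MOhm_per_pF", "ra_MOhm",
                     "upstate_duration_median_s", "epsc_freq_median_Hz",
                     "ipsc_freq_median_Hz"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.upstate_rate_median_Hz < 0:
            raise ValidationError("upstate_rate_median_Hz must be >= 0")

    @property
    def rm_MOhm(self) -> float:
        """Whole-cell input resistance implied by Cm and Rm/Cm."""
        return self.rm_specific_MOhm_per_pF * self.cm_pF


def _parse_kv(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParameterError(f"{path}: malformed preset line {raw!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def load_preset(name_or_path: str | Path) -> GenotypePreset:
    """Load a bundled preset by label or any preset file by path."""
    if str(name_or_path) in BUNDLED:
        ref = resources.files("slicephys") / "presets" / f"{name_or_path}.cfg"
        with resources.as_file(ref) as p:
            kv = _parse_kv(p)
    else:
        p = Path(name_or_path)
        if not p.exists():
            raise ParameterError(
                f"unknown preset {name_or_path!r}: not one of {BUNDLED} and not a file")
        kv = _parse_kv(p)
    try:
        ap = APKinematics(
            rheobase_pA=float(kv["ap.rheobase_pA"]),
            amplitude_mV=float(kv["ap.amplitude_mV"]),
            ahp_mV=float(kv["ap.ahp_mV"]),
            fwhm_ms=float(kv["ap.fwhm_ms"]),
            threshold_mV=float(kv["ap.threshold_mV"]),
            sfa_ratio=float(kv["ap.sfa_ratio"]),
            max_rise_V_per_s=float(kv["ap.max_rise_V_per_s"]),
            max_decay_V_per_s=float(kv["ap.max_decay_V_per_s"]),
        )
        return GenotypePreset(
            label=kv["label"],
            cm_pF=float(kv["cm_pF"]),
            rm_specific_MOhm_per_pF=float(kv["rm_specific_MOhm_per_pF"]),
            ra_MOhm=float(kv["ra_MOhm"]),
            vrest_mV=float(kv["vrest_mV"]),
            upstate_duration_median_s=float(kv["upstate_duration_median_s"]),
            upstate_rate_median_Hz=float(kv["upstate_rate_median_Hz"]),
            epsc_freq_median_Hz=float(kv["epsc_freq_median_Hz"]),
            ipsc_freq_median_Hz=float(kv["ipsc_freq_median_Hz"]),
            epsc_latency_ms=(float(kv["epsc_latency_mean_ms"]),
                             float(kv["epsc_latency_sd_ms"])),
            ipsc_latency_ms=(float(kv["ipsc_latency_mean_ms"]),
                             float(kv["ipsc_latency_sd_ms"])),
            ap=ap,
            reversal_exc_mV=float(kv.get("reversal_exc_mV", 20.0)),
            reversal_inh_mV=float(kv.get("reversal_inh_mV", -45.0)),
        )
    except KeyError as e:
        raise ParameterError(f"preset file missing key {e.args[0]!r}") from e
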