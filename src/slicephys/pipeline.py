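"""End-to-end euploid-versus-trisomic comparison on synthetic studies.

``run_pipeline`` composes the whole chain — synthetic generation, passive
and active intrinsic profiling, Up-state detection, spontaneous-PSC
analysis and evoked-latency measurement — for both genotype presets and
emits report tables (a per-cell profile table shaped like the published
intrinsic-property table, event tables, distribution summaries) plus
group-comparison records. Everything is deterministic given the run seed.

Group statistics: two-sided Student's t (pooled variance by default, Welch
by flag), Kruskal-Wallis by ranks, two-sample Kolmogorov-Smirnov, and a
two-way ANOVA with Holm-Sidak step-down post hoc comparisons for the
factorial charge/area design. Values are reported as mean +/- SEM; the
significance threshold is 0.05.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import evoked as ev
from . import intrinsic as intr
from . import synaptic as syn
from . import upstates as ups
from .errors import ParameterError, ValidationError
from .presets import GenotypePreset, load_preset
from .synthetic import (generate_current_steps, generate_evoked_trials,
                        generate_membrane_test, generate_psc_train,
                        generate_upstate_trace)

ALPHA = 0.05
TESTS = ("student_t", "kruskal_wallis", "ks")


@dataclass
class GroupComparison:
    measure: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    test: str
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _sem(x) -> float:
    x = np.asarray(x, float)
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def group_compare(a, b, test: str = "student_t", measure: str = "",
                  welch: bool = False) -> GroupComparison:
    """Two-group comparison with the named test.

    Degenerate zero-variance t-tests are defined as statistic 0 / p 1 when
    the means are equal, and +/-inf / p 0 when they differ.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2")
    if test == "student_t":
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            if np.mean(a) == np.mean(b):
                stat, p = 0.0, 1.0
            else:
                stat = float(np.sign(np.mean(a) - np.mean(b)) * np.inf)
                p = 0.0
        else:
            res = sstats.ttest_ind(a, b, equal_var=not welch)
            stat, p = float(res.statistic), float(res.pvalue)
    elif test == "kruskal_wallis":
        res = sstats.kruskal(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "ks":
        res = sstats.ks_2samp(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ParameterError(f"unknown test {test!r}; expected one of {TESTS}")
    return GroupComparison(measure=measure,
                           mean_a=float(np.mean(a)), sem_a=_sem(a), n_a=a.size,
                           mean_b=float(np.mean(b)), sem_b=_sem(b), n_b=b.size,
                           test=test, statistic=stat, p_value=p)


def holm_sidak_adjust(pvals) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values (original order).

    adj_(k) = 1 - (1 - p_(k))^(m - k + 1) on the ascending-sorted p-values,
    enforced monotone non-decreasing by a running maximum.
    """
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def anova2_holm_sidak(df: pd.DataFrame, value: str, factor_a: str, factor_b: str
                      ) -> dict:
    """Two-way ANOVA (type II) with Holm-Sidak post hoc a-contrasts.

    Post hoc: for each level of ``factor_b``, the two (or more, pairwise)
    levels of ``factor_a`` are compared by t-test and the resulting p-values
    adjusted together by the Holm-Sidak step-down.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    d = df.rename(columns={value: "value", factor_a: "fa", factor_b: "fb"})
    model = ols("value ~ C(fa) * C(fb)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)
    posthoc = []
    raw_p = []
    for lb in sorted(d["fb"].unique()):
        sub = d[d["fb"] == lb]
        levels = sorted(sub["fa"].unique())
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                xa = sub[sub["fa"] == levels[i]]["value"]
                xb = sub[sub["fa"] == levels[j]]["value"]
                res = sstats.ttest_ind(xa, xb)
                posthoc.append({"within": lb, "a": levels[i], "b": levels[j],
                                "t": float(res.statistic),
                                "p_raw": float(res.pvalue)})
                raw_p.append(float(res.pvalue))
    for rec, adj in zip(posthoc, holm_sidak_adjust(raw_p) if raw_p else []):
        rec["p_holm_sidak"] = float(adj)
    return {"anova": table, "posthoc": posthoc}


# ---------------------------------------------------------------------------
# Full synthetic study
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    genotypes: tuple[str, str] = ("euploid", "trisomic")
    seed: int = 0
    n_cells: int = 6
    upstate_traces: int = 3
    upstate_duration_s: float = 300.0
    psc_trains: int = 3
    psc_duration_s: float = 120.0
    evoked_trials: int = 10
    mtest_noise_sd_pA: float = 0.0
    outdir: str | Path | None = None

    def digest(self) -> str:
        payload = {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class ReportBundle:
    cells: pd.DataFrame
    upstate_events: pd.DataFrame
    upstate_summary: pd.DataFrame
    psc_summary: pd.DataFrame
    latencies: pd.DataFrame
    comparisons: list[GroupComparison]
    area_anova: dict
    run_log: dict


def _stage_seed(seed: int, stage: int, item: int = 0) -> int:
    return (seed * 100003 + stage * 1009 + item) % (2 ** 31 - 1)


def _profile_cells(preset: GenotypePreset, cfg: RunConfig, stage: int
                   ) -> pd.DataFrame:
    rows = []
    rheo = preset.ap.rheobase_pA
    grid = list(np.arange(5.0, 2 * rheo + 15.0, 10.0))
    for c in range(cfg.n_cells):
        s = _stage_seed(cfg.seed, stage, c)
        rng = np.random.default_rng(s)
        vrest = preset.vrest_mV + rng.normal(0.0, 1.0)
        steps = generate_current_steps(preset, grid, seed=s)
        rb = intr.rheobase(steps)
        row = {"genotype": preset.label, "cell": f"{preset.label}-{c:02d}",
               "vrest_mV": vrest, "rheobase_pA": rb}
        if rb is not None:
            i_rb = steps.step_amplitudes.index(rb)
            tr = steps[i_rb]
            spikes = intr.detect_spikes(tr)
            th = intr.ap_threshold_phase_plane(tr, spikes[0])
            feats = intr.ap_features(tr, spikes[0], th)
            row.update({"threshold_mV": th, "amplitude_mV": feats.amplitude_mV,
                        "ahp_mV": feats.ahp_mV, "fwhm_ms": feats.fwhm_ms,
                        "max_rise_V_per_s": feats.max_rise_V_per_s,
                        "max_decay_V_per_s": feats.max_decay_V_per_s,
                        "sfa_ratio": intr.sfa_ratio(spikes)})
            i_2x = int(np.argmin(np.abs(np.asarray(steps.step_amplitudes) - 2 * rb)))
            tr2 = steps[i_2x]
            spikes2 = intr.detect_spikes(tr2)
            rate2 = intr.firing_rate(spikes2)
            ahp2 = None
            if spikes2:
                th2 = intr.ap_threshold_phase_plane(tr2, spikes2[0])
                ahp2 = intr.ap_features(tr2, spikes2[0], th2).ahp_mV
            first_isi = ((spikes2[1] - spikes2[0]) * 1e3 if len(spikes2) > 1 else None)
            row["firing_class"] = intr.classify_firing_type(vrest, first_isi,
                                                            rate2, ahp2)
        mtest, _ = generate_membrane_test(preset.ra_MOhm, preset.rm_MOhm,
                                          preset.cm_pF,
                                          noise_sd_pA=cfg.mtest_noise_sd_pA, seed=s)
        ra, rm, cm, rm_spec = intr.passive_properties(mtest, 10.0)
        row.update({"ra_MOhm": ra, "rm_MOhm": rm, "cm_pF": cm,
                    "rm_specific_MOhm_per_pF": rm_spec})
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Run the full synthetic study; see module docstring."""
    if cfg.n_cells < 2 or cfg.upstate_traces < 1 or cfg.psc_trains < 1:
        raise ValidationError("run config requires n_cells >= 2 and at least one "
                              "trace per channel (upstate_traces, psc_trains)")
    presets = {g: load_preset(g) for g in cfg.genotypes}
    ga, gb = cfg.genotypes

    cells = pd.concat([_profile_cells(presets[g], cfg, stage=1 + i)
                       for i, g in enumerate(cfg.genotypes)], ignore_index=True)

    ev_rows, sum_rows, area_rows = [], [], []
    durations: dict[str, list[float]] = {g: [] for g in cfg.genotypes}
    rates: dict[str, list[float]] = {g: [] for g in cfg.genotypes}
    for gi, g in enumerate(cfg.genotypes):
        for k in range(cfg.upstate_traces):
            for mode in ("field", "intracellular"):
                s = _stage_seed(cfg.seed, 10 + gi, 2 * k + (mode == "field"))
                trace, _ = generate_upstate_trace(presets[g],
                                                  cfg.upstate_duration_s, mode, s)
                prep = (ups.preprocess_field(trace) if mode == "field"
                        else ups.preprocess_intracellular(trace))
                events = ups.detect_up_states(prep)
                summ = ups.upstate_statistics(events, trace.duration_s)
                sum_rows.append({"genotype": g, "trace": k, "mode": mode,
                                 "n_events": summ.n_events,
                                 "duration_median_s": summ.duration_median_s,
                                 "rate_count_Hz": summ.rate_count_Hz})
                for e in events:
                    ev_rows.append({"genotype": g, "trace": k, "mode": mode,
                                    "start_s": e.start_s, "end_s": e.end_s,
                                    "duration_s": e.duration_s, "area": e.area,
                                    "n_merged": e.n_merged,
                                    "truncated": e.truncated})
                    if not e.truncated:
                        area_rows.append({"genotype": g, "mode": mode,
                                          "area": e.area})
                if mode == "field":
                    durations[g].extend(summ.durations_s)
                    rates[g].append(summ.rate_count_Hz)

    psc_rows = []
    freqs: dict[tuple[str, str], list[float]] = {}
    for gi, g in enumerate(cfg.genotypes):
        for comp, med, pol in (("epsc", presets[g].epsc_freq_median_Hz, "inward"),
                               ("ipsc", presets[g].ipsc_freq_median_Hz, "outward")):
            pooled: list[float] = []
            for k in range(cfg.psc_trains):
                s = _stage_seed(cfg.seed, 20 + gi, 2 * k + (comp == "epsc"))
                tr, _ = generate_psc_train(med, cfg.psc_duration_s, s, polarity=pol)
                cfg_det = syn.EventDetectionConfig(polarity=pol)
                events = syn.detect_psc_events(tr, cfg_det)
                dist = syn.event_frequency_distribution(events)
                pooled.extend(dist.freqs_Hz)
            freqs[(g, comp)] = pooled
            psc_rows.append({"genotype": g, "component": comp,
                             "n_intervals": len(pooled),
                             "median_Hz": (float(np.quantile(pooled, 0.5))
                                           if pooled else None)})

    lat_rows = []
    lat: dict[tuple[str, str], list[float]] = {}
    for gi, g in enumerate(cfg.genotypes):
        for comp, pars, pol in (("epsc", presets[g].epsc_latency_ms, "inward"),
                                ("ipsc", presets[g].ipsc_latency_ms, "outward")):
            s = _stage_seed(cfg.seed, 30 + gi, comp == "epsc")
            trials, _ = generate_evoked_trials(pars, cfg.evoked_trials, s,
                                               polarity=pol)
            et = [ev.EvokedTrial(t, t.stim_times[0]) for t in trials]
            ls = ev.measure_latencies(et)
            lat[(g, comp)] = ls
            call = ev.classify_connection(
                ls, "excitatory" if comp == "epsc" else "inhibitory")
            lat_rows.append({"genotype": g, "component": comp, "n": len(ls),
                             "mean_ms": call.mean_ms, "cv_percent": call.cv_percent,
                             "call": call.call})

    comparisons = []
    for xa, xb, test, name in (
            (cells[cells.genotype == ga]["cm_pF"],
             cells[cells.genotype == gb]["cm_pF"], "student_t", "cm_pF"),
            (cells[cells.genotype == ga]["rm_specific_MOhm_per_pF"],
             cells[cells.genotype == gb]["rm_specific_MOhm_per_pF"],
             "student_t", "rm_specific_MOhm_per_pF"),
            (durations[ga], durations[gb], "ks", "upstate_duration_s"),
            (rates[ga], rates[gb], "kruskal_wallis", "upstate_rate_Hz"),
            (freqs[(ga, "epsc")], freqs[(gb, "epsc")], "ks", "epsc_inst_freq_Hz"),
            (freqs[(ga, "ipsc")], freqs[(gb, "ipsc")], "ks", "ipsc_inst_freq_Hz"),
            (lat[(ga, "epsc")], lat[(gb, "epsc")], "student_t", "epsc_latency_ms"),
            (lat[(ga, "ipsc")], lat[(gb, "ipsc")], "student_t", "ipsc_latency_ms")):
        if len(xa) >= 2 and len(xb) >= 2:
            comparisons.append(group_compare(xa, xb, test, name))

    area_df = pd.DataFrame(area_rows)
    area_anova = (anova2_holm_sidak(area_df, "area", "genotype", "mode")
                  if not area_df.empty and area_df["genotype"].nunique() > 1
                  else {"anova": None, "posthoc": []})

    bundle = ReportBundle(
        cells=cells,
        upstate_events=pd.DataFrame(ev_rows),
        upstate_summary=pd.DataFrame(sum_rows),
        psc_summary=pd.DataFrame(psc_rows),
        latencies=pd.DataFrame(lat_rows),
        comparisons=comparisons,
        area_anova=area_anova,
        run_log={"config": {k: (str(v) if isinstance(v, Path) else v)
                            for k, v in asdict(cfg).items()},
                 "config_sha256": cfg.digest()},
    )
    if cfg.outdir is not None:
        _write_report(bundle, Path(cfg.outdir))
    return bundle


def _write_report(bundle: ReportBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.cells.to_csv(outdir / "cells.csv", index=False)
    bundle.upstate_events.to_csv(outdir / "upstate_events.csv", index=False)
    bundle.upstate_summary.to_csv(outdir / "upstate_summary.csv", index=False)
    bundle.psc_summary.to_csv(outdir / "psc_summary.csv", index=False)
    bundle.latencies.to_csv(outdir / "latencies.csv", index=False)
    comp = pd.DataFrame([asdict(c) | {"significant": c.significant}
                         for c in bundle.comparisons])
    comp.to_csv(outdir / "comparisons.csv", index=False)
    (outdir / "run_log.json").write_text(json.dumps(bundle.run_log, indent=2))
    lines = ["synthetic euploid-vs-trisomic study", ""]
    for c in bundle.comparisons:
        star = " *" if c.significant else ""
        lines.append(f"{c.measure}: {c.mean_a:.4g}+/-{c.sem_a:.2g} (n={c.n_a}) vs "
                     f"{c.mean_b:.4g}+/-{c.sem_b:.2g} (n={c.n_b}), "
                     f"{c.test} p={c.p_value:.3g}{star}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
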