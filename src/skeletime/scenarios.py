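"""End-to-end scenario runner: one config + seed -> files + summary JSON.

Each scenario reproduces a figure-level experiment at desk scale:
simulate the recordings with the limit-cycle ensemble, run the relevant
analysis stages, write the intermediate CSV/TSV files and a
machine-readable ``summary.json``.  Every scenario is fully specified by
its config and seed; rerunning with the same config yields byte-identical
summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import yaml

from .cosinor import Cosinor
from .counts import simulate_count_timeseries
from .events import amplitude_percent_change, estimate_phase_shift, wrap_shift_h
from .oscillator import (
    PHASE_CATEGORIES_H,
    OscillatorEnsembleParams,
    StimulusEvent,
    StimulusSchedule,
    make_schedule,
    simulate_cell_population,
    simulate_ensemble,
)
from .resetting import (
    DoseExperiment,
    PhaseExperiment,
    build_dose_response,
    build_prc,
)
from .series import LuminescenceSeries, detrend_moving_average, write_series_csv
from .singlecell import calls_to_frame, classify_population, responder_fraction
from .transcriptome import (
    detect_rhythmic_genes,
    differential_response,
    filter_min_counts,
    normalize_counts,
)

__all__ = ["ScenarioConfig", "SCENARIOS", "validate_config", "run_scenario"]

log = logging.getLogger("skeletime")

SCENARIOS = (
    "loading_pulse",
    "phase_series",
    "dose_series_osmotic",
    "dose_series_loading",
    "antiphase_entrainment",
    "media_swap",
    "osmotic_cycles_young_aged",
    "single_cell_osmotic",
    "rnaseq_osmotic",
    "treadmill_in_vivo",
)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class ScenarioConfig:
    """Normalized scenario configuration (config + seed = full state)."""

    scenario: str
    seed: int = 0
    out_dir: str = "skeletime_out"
    params: dict = field(default_factory=dict)    # OscillatorEnsembleParams overrides
    options: dict = field(default_factory=dict)   # scenario-specific knobs

    def ensemble_params(self, seed_offset: int = 0, **extra) -> OscillatorEnsembleParams:
        kw = dict(self.params)
        kw.update(extra)
        kw["seed"] = self.seed + seed_offset
        return OscillatorEnsembleParams(**kw)


_KNOWN_KEYS = {"scenario", "seed", "out_dir", "params", "options"}
_PARAM_FIELDS = set(OscillatorEnsembleParams.__dataclass_fields__)


def validate_config(source) -> ScenarioConfig:
    """Parse and validate a config file/dict, collecting all errors.

    ``source`` is a path to a YAML/JSON file or an already-parsed mapping.
    Raises ``ValueError`` whose message aggregates every problem found.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        raw = yaml.safe_load(text)  # YAML is a JSON superset
    else:
        raw = source
    errors: list[str] = []
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a mapping, got {type(raw).__name__}")
    for key in raw:
        if key not in _KNOWN_KEYS:
            errors.append(f"unknown key {key!r}")
    scenario = raw.get("scenario")
    if scenario is None:
        errors.append("missing required key 'scenario'")
    elif scenario not in SCENARIOS:
        errors.append(
            f"unknown scenario {scenario!r}; one of: {', '.join(SCENARIOS)}"
        )
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append(f"seed must be a nonnegative integer, got {seed!r}")
    params = raw.get("params", {})
    if not isinstance(params, dict):
        errors.append("params must be a mapping")
        params = {}
    else:
        for key, value in params.items():
            if key not in _PARAM_FIELDS or key == "seed":
                errors.append(f"params: unknown oscillator field {key!r}")
            elif key == "n_cells" and (not isinstance(value, int) or value < 1):
                errors.append(f"params.n_cells must be a positive integer, got {value!r}")
    options = raw.get("options", {})
    if not isinstance(options, dict):
        errors.append("options must be a mapping")
        options = {}
    for key in ("dose", "doses"):
        if key in options:
            vals = options[key] if isinstance(options[key], (list, tuple)) else [options[key]]
            for v in vals:
                if not isinstance(v, (int, float)) or v < 0:
                    errors.append(f"options.{key}: dose must be >= 0, got {v!r}")
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    return ScenarioConfig(
        scenario=scenario,
        seed=seed,
        out_dir=str(raw.get("out_dir", "skeletime_out")),
        params=params,
        options=options,
    )


def _write_summary(out: Path, summary: dict) -> dict:
    summary = {"schema_version": SUMMARY_SCHEMA_VERSION, **summary}
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _detrended(rec):
    return detrend_moving_average(rec.to_series())


def _scn_loading_pulse(cfg: ScenarioConfig, out: Path) -> dict:
    opt = cfg.options
    event_t = float(opt.get("event_time_h", 48.0))
    dose = float(opt.get("dose", 0.5))
    sched = StimulusSchedule(
        events=[StimulusEvent(t_h=event_t, dose=dose, kind="compression_MPa",
                              duration_h=float(opt.get("duration_h", 1.0)))]
    )
    rec = simulate_ensemble(cfg.ensemble_params(), sched, t_end_h=event_t + 84.0)
    rec.write_csv(out / "recording.csv")
    det = _detrended(rec)
    amp = amplitude_percent_change(det, event_t)
    shift = estimate_phase_shift(rec.to_series(), event_t).shift_h
    return {"scenario": cfg.scenario, "seed": cfg.seed, "dose_MPa": dose,
            "amplitude_pct": amp, "shift_h": shift}


def _scn_phase_series(cfg: ScenarioConfig, out: Path) -> dict:
    opt = cfg.options
    kind = opt.get("kind", "compression_MPa")
    dose = float(opt.get("dose", 0.5 if kind == "compression_MPa" else 200.0))
    duration = float(opt.get("duration_h", 1.0 if kind == "compression_MPa" else 0.0))
    ref_peak = float(opt.get("ref_peak_h", 48.0))
    schedules = make_schedule("phase_series", ref_peak_h=ref_peak, dose=dose,
                              kind=kind, duration_h=duration)
    experiments = []
    for cat, sched in schedules.items():
        t_ev = sched.events[0].t_h
        rec = simulate_ensemble(cfg.ensemble_params(), sched, t_end_h=t_ev + 60.0)
        rec.write_csv(out / f"recording_{cat}.csv")
        experiments.append(PhaseExperiment(PHASE_CATEGORIES_H[cat], t_ev, rec.to_series()))
    prc = build_prc(experiments, stimulus={"kind": kind, "dose": dose})
    prc.to_frame().to_csv(out / "prc.tsv", sep="\t", index=False)
    return {"scenario": cfg.scenario, "seed": cfg.seed,
            "phases_h": prc.old_phase_h.tolist(),
            "shift_h": prc.shift_h.tolist(),
            "amplitude_pct": prc.amplitude_pct.tolist()}


def _dose_series(cfg: ScenarioConfig, out: Path, kind: str, doses, duration: float) -> dict:
    phase = PHASE_CATEGORIES_H[cfg.options.get("phase_category", "mid_descending")]
    event_t = 48.0 + phase
    experiments = []
    for dose in doses:
        sched = StimulusSchedule(
            events=[StimulusEvent(t_h=event_t, dose=float(dose), kind=kind,
                                  duration_h=duration)]
        )
        rec = simulate_ensemble(cfg.ensemble_params(), sched, t_end_h=event_t + 60.0)
        experiments.append(DoseExperiment(float(dose), event_t, rec.to_series()))
    table = build_dose_response(experiments)
    table.to_frame().to_csv(out / "dose_response.tsv", sep="\t", index=False)
    return {"scenario": cfg.scenario, "seed": cfg.seed,
            "dose": table.dose.tolist(), "shift_h": table.shift_h.tolist(),
            "amplitude_pct": table.amplitude_pct.tolist(),
            "concordance": table.concordance}


def _scn_dose_series_osmotic(cfg, out):
    doses = cfg.options.get("doses", [0, 50, 100, 200, 300, 400])
    return _dose_series(cfg, out, "osmotic_mOsm", doses, 0.0)


def _scn_dose_series_loading(cfg, out):
    doses = cfg.options.get("doses", [0, 0.1, 0.2, 0.5, 1.0])
    return _dose_series(cfg, out, "compression_MPa", doses, 1.0)


def _scn_antiphase_entrainment(cfg: ScenarioConfig, out: Path) -> dict:
    opt = cfg.options
    days = int(opt.get("days", 3))
    free_h = float(opt.get("free_run_h", 48.0))
    sa, sb = make_schedule("antiphase_12_12", days=days,
                           dose=float(opt.get("dose", 0.5)))
    t_end = 24.0 * days + free_h
    pa = cfg.ensemble_params(init_mode=opt.get("init_mode", "desynchronized"))
    pb = cfg.ensemble_params(seed_offset=1000,
                             init_mode=opt.get("init_mode", "desynchronized"))
    ra = simulate_ensemble(pa, sa, t_end_h=t_end)
    rb = simulate_ensemble(pb, sb, t_end_h=t_end)
    ra.write_csv(out / "recording_inphase.csv")
    rb.write_csv(out / "recording_antiphase.csv")
    acc_a = Cosinor.from_series(ra.to_series().window(24.0 * days, t_end)).fit().acrophase_h
    acc_b = Cosinor.from_series(rb.to_series().window(24.0 * days, t_end)).fit().acrophase_h
    diff_h = abs(wrap_shift_h(acc_a - acc_b))
    return {"scenario": cfg.scenario, "seed": cfg.seed,
            "acrophase_a_h": acc_a, "acrophase_b_h": acc_b,
            "phase_difference_h": diff_h, "phase_difference_deg": diff_h * 15.0}


def _scn_media_swap(cfg: ScenarioConfig, out: Path) -> dict:
    # explants desynchronize for days, then experience an osmotic step-up
    opt = cfg.options
    swap_t = float(opt.get("swap_time_h", 162.0))
    dose = float(opt.get("dose", 200.0))
    sched = StimulusSchedule(
        events=[StimulusEvent(t_h=swap_t, dose=dose, kind="osmotic_mOsm")]
    )
    treated = simulate_ensemble(cfg.ensemble_params(), sched, t_end_h=swap_t + 96.0)
    control = simulate_ensemble(cfg.ensemble_params(seed_offset=1000), None,
                                t_end_h=swap_t + 96.0)
    treated.write_csv(out / "recording_swap_up.csv")
    control.write_csv(out / "recording_control.csv")
    amp_treated = amplitude_percent_change(_detrended(treated), swap_t)
    amp_control = amplitude_percent_change(_detrended(control), swap_t)
    return {"scenario": cfg.scenario, "seed": cfg.seed,
            "amplitude_pct_osmotic_increase": amp_treated,
            "amplitude_pct_control": amp_control}


def _scn_osmotic_cycles_young_aged(cfg: ScenarioConfig, out: Path) -> dict:
    # daily 12 h hyperosmotic cycles re-synchronize a noisy ("aged") ensemble
    opt = cfg.options
    days = int(opt.get("days", 4))
    start = float(opt.get("start_h", 72.0))
    sched = make_schedule("osmotic_cycles", dose=float(opt.get("dose", 100.0)),
                          days=days, start_h=start)
    t_end = start + 24.0 * days + 48.0
    summary = {"scenario": cfg.scenario, "seed": cfg.seed}
    for label, extra in (
        ("young", {}),
        ("aged", {"tau_sd_h": 1.0, "phase_noise": 0.15}),
    ):
        cycled = simulate_ensemble(cfg.ensemble_params(**extra), sched, t_end_h=t_end)
        free = simulate_ensemble(cfg.ensemble_params(seed_offset=1000, **extra), None,
                                 t_end_h=t_end)
        cycled.write_csv(out / f"recording_{label}_cycles.csv")
        free.write_csv(out / f"recording_{label}_free.csv")
        summary[f"amplitude_pct_{label}_cycles"] = amplitude_percent_change(
            _detrended(cycled), start + 24.0 * days, reference="peak_24h_after_start")
        summary[f"amplitude_pct_{label}_free"] = amplitude_percent_change(
            _detrended(free), start + 24.0 * days, reference="peak_24h_after_start")
    return summary


def _scn_single_cell_osmotic(cfg: ScenarioConfig, out: Path) -> dict:
    opt = cfg.options
    n = int(opt.get("n_cells", 78))
    frac = float(opt.get("responder_fraction", 0.66))
    treat_t = float(opt.get("treat_time_h", 48.0))
    params = cfg.ensemble_params(n_cells=n, init_mode="desynchronized",
                                 relax_rate=0.03)
    cells = simulate_cell_population(params, treat_t, frac, t_end_h=96.0)
    cells.write_csv(out / "cell_trajectories.csv")
    calls = classify_population(cells.time_h, cells.signals, treat_t,
                                cell_ids=cells.cell_ids)
    calls_to_frame(calls).to_csv(out / "responder_calls.tsv", sep="\t", index=False)
    summary = responder_fraction(calls)
    defined = [c for c in calls if c.responder is not None]
    truth = {cells.cell_ids[i]: bool(cells.responder_truth[i]) for i in range(n)}
    agree = sum(c.responder == truth[c.cell_id] for c in defined)
    return {"scenario": cfg.scenario, "seed": cfg.seed,
            "responder_pct": summary.percent,
            "ci_low_pct": summary.ci_low_pct, "ci_high_pct": summary.ci_high_pct,
            "n_defined": summary.n_defined, "n_undefined": summary.n_undefined,
            "truth_responder_pct": 100.0 * sum(truth.values()) / n,
            "truth_agreement_pct": 100.0 * agree / max(len(defined), 1)}


def _scn_rnaseq_osmotic(cfg: ScenarioConfig, out: Path) -> dict:
    opt = cfg.options
    expt = simulate_count_timeseries(
        g_genes=int(opt.get("g_genes", 400)),
        frac_rhythmic=float(opt.get("frac_rhythmic", 0.2)),
        n_reps=int(opt.get("n_reps", 6)),
        nb_dispersion=float(opt.get("nb_dispersion", 0.1)),
        seed=cfg.seed,
    )
    expt.write_tsvs(out)
    counts = filter_min_counts(expt.counts, threshold=int(opt.get("min_counts", 50)))
    norm = normalize_counts(counts)
    stats = detect_rhythmic_genes(norm, expt.sample_time_h,
                                  n_perm=int(opt.get("n_perm", 0)), seed=cfg.seed)
    stats.to_csv(out / "rhythm_stats.tsv", sep="\t")
    sheet = expt.sample_sheet
    t0 = sheet.loc[sheet.time_h == 0.0, "sample_id"].tolist()
    t4 = sheet.loc[sheet.time_h == 4.0, "sample_id"].tolist()
    de = differential_response(norm, t4, t0, fc_cut=float(opt.get("fc_cut", 1.0)))
    de.to_csv(out / "differential_response.tsv", sep="\t")
    return {"scenario": cfg.scenario, "seed": cfg.seed,
            "n_genes_kept": int(counts.shape[0]),
            "tier1_count": int(stats["tier1"].sum()),
            "tier2_count": int(stats["tier2"].sum()),
            "de_up": int((de["direction"] == "up").sum()),
            "de_down": int((de["direction"] == "down").sum())}


def _scn_treadmill_in_vivo(cfg: ScenarioConfig, out: Path) -> dict:
    # per-group recordings are means over explants, mirroring the wet-lab
    # design (several explants per mouse group, traces averaged)
    n_explants = int(cfg.options.get("n_explants", 6))
    sched = make_schedule("treadmill_in_vivo")
    last = sched.events[-1]
    t_end = last.t_h + last.duration_h + 50.0
    arms = {}
    for label, schedule, offset in (("running", sched, 0),
                                    ("sedentary", None, 500)):
        signals = []
        for k in range(n_explants):
            rec = simulate_ensemble(cfg.ensemble_params(seed_offset=offset + k),
                                    schedule, t_end_h=t_end)
            signals.append(rec.ensemble_signal)
        arms[label] = LuminescenceSeries(rec.time_h.copy(),
                                         np.mean(signals, axis=0), label)
        write_series_csv(out / f"recording_{label}.csv", [arms[label]])
    est = estimate_phase_shift(arms["running"], last.t_h + last.duration_h,
                               control=arms["sedentary"],
                               method="control_referenced")
    return {"scenario": cfg.scenario, "seed": cfg.seed,
            "n_explants": n_explants,
            "shift_h": est.shift_h, "shift_se_h": est.se_h}


_RUNNERS: dict[str, Callable[[ScenarioConfig, Path], dict]] = {
    "loading_pulse": _scn_loading_pulse,
    "phase_series": _scn_phase_series,
    "dose_series_osmotic": _scn_dose_series_osmotic,
    "dose_series_loading": _scn_dose_series_loading,
    "antiphase_entrainment": _scn_antiphase_entrainment,
    "media_swap": _scn_media_swap,
    "osmotic_cycles_young_aged": _scn_osmotic_cycles_young_aged,
    "single_cell_osmotic": _scn_single_cell_osmotic,
    "rnaseq_osmotic": _scn_rnaseq_osmotic,
    "treadmill_in_vivo": _scn_treadmill_in_vivo,
}


def run_scenario(config: ScenarioConfig) -> dict:
    """Run one scenario end to end; returns the summary written to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("scenario=%s seed=%d stage=start", config.scenario, config.seed)
    runner = _RUNNERS[config.scenario]
    try:
        summary = runner(config, out)
    except Exception:
        log.error("scenario=%s seed=%d stage=failed", config.scenario, config.seed)
        raise
    summary = _write_summary(out, summary)
    log.info("scenario=%s seed=%d stage=done", config.scenario, config.seed)
    return summary
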