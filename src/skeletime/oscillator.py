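"""Poincaré (amplitude--phase) oscillator ensemble simulator.

Each cell i carries a radial coordinate r_i and a phase phi_i evolving as

    dr/dt   = lambda * r * (A0 - r)
    dphi/dt = 2*pi / tau_i  (+ phase diffusion)

so the cell relaxes onto a limit cycle of radius A0 while its phase rotates
with an intrinsic period tau_i drawn per cell.  The population observable
(a bioluminescence-like signal) is an affine readout of the x-projection,
averaged over cells.  Damping of the ensemble rhythm arises from
desynchronization (period heterogeneity + phase diffusion), not from loss
of single-cell rhythmicity -- the behaviour seen in unstimulated explant
recordings.

Stimuli displace the Cartesian state along a fixed direction; an
instantaneous event adds the whole calibrated kick at once, while a
stimulus held for some duration (and the on-half of square-wave forcing)
acts as a constant drive delivering the calibrated kick magnitude per
hour of application, so a 1 h sustained bout matches one instantaneous
kick and a 12 h on-half delivers twelve times that impulse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .calibration import DoseCalibration, default_calibrations, dose_to_kick
from .series import LuminescenceSeries, write_series_csv

__all__ = [
    "OscillatorEnsembleParams",
    "StimulusEvent",
    "SquareWave",
    "StimulusSchedule",
    "EnsembleRecording",
    "CellTrajectorySet",
    "PHASE_CATEGORIES_H",
    "make_schedule",
    "simulate_ensemble",
    "simulate_cell_population",
]

#: Stimulus phase categories in hours after the reporter peak.
PHASE_CATEGORIES_H = {
    "peak": 0.0,
    "mid_descending": 6.0,
    "trough": 12.0,
    "mid_ascending": 18.0,
}


@dataclass(frozen=True)
class OscillatorEnsembleParams:
    """Parameters of the oscillator ensemble and its observation model.

    Defaults describe a synchronized explant whose population rhythm decays
    to roughly half its starting amplitude over 4-6 cycles through
    desynchronization, with a nonnegative bioluminescence-like observable.
    """

    n_cells: int = 100
    tau_h: float = 24.0               # intrinsic period (h)
    tau_sd_h: float = 0.5             # between-cell period SD (h)
    relax_rate: float = 0.15          # radial relaxation lambda (1/h)
    limit_radius: float = 1.0         # limit-cycle radius A0 (a.u.)
    phase_noise: float = 0.1          # phase diffusion (rad / sqrt(h))
    obs_baseline: float = 2.0         # additive offset (signal units)
    obs_gain: float = 1.0             # scale (signal units per a.u.)
    obs_noise_sd: float = 0.02        # observation noise SD (signal units)
    init_mode: str = "synchronized"   # or "desynchronized"
    init_phase_h: float = 0.0         # initial phase for synchronized init
    dt_h: float = 0.05                # integration step (h)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.tau_h <= 0:
            raise ValueError("tau_h must be > 0")
        if self.relax_rate <= 0:
            raise ValueError("relax_rate must be > 0")
        if self.limit_radius <= 0:
            raise ValueError("limit_radius must be > 0")
        if self.dt_h > 0.1:
            raise ValueError("dt_h must be <= 0.1 h")
        if self.init_mode not in ("synchronized", "desynchronized"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")

    @classmethod
    def deterministic(cls, **overrides) -> "OscillatorEnsembleParams":
        """Single noiseless oscillator (the deterministic reference mode)."""
        base = dict(
            n_cells=1,
            tau_sd_h=0.0,
            phase_noise=0.0,
            obs_noise_sd=0.0,
            init_mode="synchronized",
        )
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "OscillatorEnsembleParams":
        return replace(self, **overrides)


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus: onset time, duration (0 = instantaneous kick), dose."""

    t_h: float
    dose: float
    kind: str = "osmotic_mOsm"
    duration_h: float = 0.0

    def __post_init__(self) -> None:
        if self.t_h < 0:
            raise ValueError("event t_h must be >= 0")
        if self.duration_h < 0:
            raise ValueError("event duration_h must be >= 0")
        if self.dose < 0:
            raise ValueError("event dose must be >= 0")


@dataclass(frozen=True)
class SquareWave:
    """Sustained periodic forcing (e.g. 12 h on / 12 h off loading)."""

    period_h: float = 24.0
    on_fraction: float = 0.5
    dose: float = 0.5
    kind: str = "compression_MPa"
    phase_offset_h: float = 0.0
    end_h: Optional[float] = None  # forcing stops here; None = whole run

    def __post_init__(self) -> None:
        if not (0.0 < self.on_fraction < 1.0):
            raise ValueError("on_fraction must be in (0, 1)")
        if self.period_h <= 0:
            raise ValueError("period_h must be > 0")


@dataclass
class StimulusSchedule:
    """Ordered discrete events plus optional square-wave forcing."""

    events: list[StimulusEvent] = field(default_factory=list)
    square_wave: Optional[SquareWave] = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.t_h)

    @property
    def last_event_time_h(self) -> float:
        return max((e.t_h for e in self.events), default=0.0)


_PRESETS = (
    "single_pulse",
    "phase_series",
    "daily_pulses",
    "antiphase_12_12",
    "osmotic_cycles",
    "treadmill_in_vivo",
)


def make_schedule(preset: str, **overrides):
    """Build a stimulus schedule from a named preset.

    Presets
    -------
    single_pulse
        One event; ``t_h`` (default 72), ``dose`` (200 mOsm), ``kind``,
        ``duration_h``.
    phase_series
        One schedule per phase category {peak, mid_descending, trough,
        mid_ascending}, mapped to {0, 6, 12, 18} h after the reference
        reporter peak ``ref_peak_h``; returns a dict keyed by category.
    daily_pulses
        ``n_days`` pulses every ``interval_h`` starting at ``start_h``.
    antiphase_12_12
        Two square-wave schedules (12 h on / 12 h off loading) offset by
        12 h; returns a (schedule_a, schedule_b) tuple.
    osmotic_cycles
        Daily 12 h hyperosmotic / 12 h iso-osmotic square wave.
    treadmill_in_vivo
        Five daily 45-min loading pulses at the trough phase category.
    """
    if preset not in _PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; available presets: {', '.join(_PRESETS)}"
        )
    if preset == "single_pulse":
        ev = StimulusEvent(
            t_h=overrides.pop("t_h", 72.0),
            dose=overrides.pop("dose", 200.0),
            kind=overrides.pop("kind", "osmotic_mOsm"),
            duration_h=overrides.pop("duration_h", 0.0),
        )
        return StimulusSchedule(events=[ev])
    if preset == "phase_series":
        ref_peak = overrides.pop("ref_peak_h", 48.0)
        dose = overrides.pop("dose", 200.0)
        kind = overrides.pop("kind", "osmotic_mOsm")
        duration = overrides.pop("duration_h", 0.0)
        categories = overrides.pop("categories", tuple(PHASE_CATEGORIES_H))
        return {
            cat: StimulusSchedule(
                events=[
                    StimulusEvent(
                        t_h=ref_peak + PHASE_CATEGORIES_H[cat],
                        dose=dose,
                        kind=kind,
                        duration_h=duration,
                    )
                ]
            )
            for cat in categories
        }
    if preset == "daily_pulses":
        start = overrides.pop("start_h", 36.0)
        n_days = overrides.pop("n_days", 5)
        interval = overrides.pop("interval_h", 24.0)
        dose = overrides.pop("dose", 0.5)
        kind = overrides.pop("kind", "compression_MPa")
        duration = overrides.pop("duration_h", 0.75)
        events = [
            StimulusEvent(t_h=start + k * interval, dose=dose, kind=kind, duration_h=duration)
            for k in range(n_days)
        ]
        return StimulusSchedule(events=events)
    if preset == "antiphase_12_12":
        dose = overrides.pop("dose", 0.5)
        kind = overrides.pop("kind", "compression_MPa")
        days = overrides.pop("days", 3)
        end = overrides.pop("end_h", 24.0 * days)
        a = StimulusSchedule(
            square_wave=SquareWave(
                period_h=24.0, on_fraction=0.5, dose=dose, kind=kind,
                phase_offset_h=0.0, end_h=end,
            )
        )
        b = StimulusSchedule(
            square_wave=SquareWave(
                period_h=24.0, on_fraction=0.5, dose=dose, kind=kind,
                phase_offset_h=12.0, end_h=end,
            )
        )
        return a, b
    if preset == "osmotic_cycles":
        dose = overrides.pop("dose", 100.0)
        days = overrides.pop("days", 4)
        start = overrides.pop("start_h", 0.0)
        return StimulusSchedule(
            square_wave=SquareWave(
                period_h=24.0, on_fraction=0.5, dose=dose, kind="osmotic_mOsm",
                phase_offset_h=start, end_h=start + 24.0 * days,
            )
        )
    # treadmill_in_vivo: 5 daily 45-min loading bouts at the trough phase
    first_trough = overrides.pop(
        "start_h", overrides.pop("ref_peak_h", 24.0) + PHASE_CATEGORIES_H["trough"]
    )
    dose = overrides.pop("dose", 0.5)
    n_days = overrides.pop("n_days", 5)
    events = [
        StimulusEvent(
            t_h=first_trough + 24.0 * k, dose=dose,
            kind="compression_MPa", duration_h=0.75,
        )
        for k in range(n_days)
    ]
    return StimulusSchedule(events=events)


@dataclass
class EnsembleRecording:
    """Simulated recording: time grid, population signal, per-cell truth."""

    time_h: np.ndarray
    ensemble_signal: np.ndarray
    per_cell_signals: Optional[np.ndarray]  # cells x time
    phases_rad: np.ndarray                  # cells x time, ground truth
    radii: np.ndarray                       # cells x time, ground truth
    params: OscillatorEnsembleParams
    schedule: StimulusSchedule

    def to_series(self, trace_id: str = "ensemble") -> LuminescenceSeries:
        return LuminescenceSeries(
            time_h=self.time_h.copy(),
            signal=self.ensemble_signal.copy(),
            trace_id=trace_id,
        )

    def write_csv(self, path: str | Path, include_cells: bool = False) -> None:
        series = [self.to_series()]
        if include_cells and self.per_cell_signals is not None:
            for i, row in enumerate(self.per_cell_signals):
                series.append(
                    LuminescenceSeries(self.time_h.copy(), row.copy(), f"cell_{i:03d}")
                )
        write_series_csv(path, series)


@dataclass
class CellTrajectorySet:
    """Per-cell fluorescence-like trajectories with responder truth labels."""

    time_h: np.ndarray
    signals: np.ndarray            # cells x time
    responder_truth: np.ndarray    # bool per cell
    treat_time_h: float
    cell_ids: list[str]

    @property
    def n_cells(self) -> int:
        return self.signals.shape[0]

    def write_csv(self, path: str | Path) -> None:
        series = [
            LuminescenceSeries(self.time_h.copy(), self.signals[i].copy(), self.cell_ids[i])
            for i in range(self.n_cells)
        ]
        write_series_csv(path, series)


def _resolve_calibrations(calib) -> dict[str, DoseCalibration]:
    if calib is None:
        return default_calibrations()
    if isinstance(calib, DoseCalibration):
        return {calib.stimulus_kind: calib}
    return dict(calib)


def _init_state(params: OscillatorEnsembleParams, rng: np.random.Generator):
    n = params.n_cells
    r = np.full(n, params.limit_radius)
    if params.init_mode == "synchronized":
        phi = np.full(n, 2.0 * math.pi * params.init_phase_h / params.tau_h)
    else:
        phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    tau = params.tau_h + params.tau_sd_h * rng.standard_normal(n)
    tau = np.clip(tau, 0.25 * params.tau_h, 4.0 * params.tau_h)
    return r, phi, tau


def _apply_cartesian(r, phi, dx, dy):
    """Displace polar state by a Cartesian vector; origin maps to phase 0."""
    x = r * np.cos(phi) + dx
    y = r * np.sin(phi) + dy
    r_new = np.hypot(x, y)
    phi_new = np.where(r_new > 1e-12, np.arctan2(y, x), 0.0)
    return r_new, phi_new


def simulate_ensemble(
    params: OscillatorEnsembleParams,
    schedule: Optional[StimulusSchedule] = None,
    calib=None,
    t_end_h: float = 120.0,
    keep_cells: bool = False,
) -> EnsembleRecording:
    """Integrate the oscillator ensemble under a stimulus schedule.

    Fixed-step explicit integration in polar coordinates; instantaneous
    events are applied between steps at the first step boundary at or after
    their onset; events with a duration (and square-wave on-halves) act as
    a constant Cartesian drive delivering the calibrated kick magnitude per
    hour of application.  Deterministic for a given seed.
    """
    if t_end_h <= 0:
        raise ValueError("t_end_h must be > 0")
    schedule = schedule or StimulusSchedule()
    for ev in schedule.events:
        if ev.t_h >= t_end_h:
            raise ValueError(f"event at t={ev.t_h} h is outside the simulated range")
    calibs = _resolve_calibrations(calib)

    dt = params.dt_h
    n_steps = int(round(t_end_h / dt))
    time = np.arange(n_steps + 1) * dt
    rng = np.random.default_rng(params.seed)
    r, phi, tau = _init_state(params, rng)
    omega = 2.0 * math.pi / tau
    n = params.n_cells

    # instantaneous kicks indexed by the step at which they fire
    instant: dict[int, list[StimulusEvent]] = {}
    sustained: list[StimulusEvent] = []
    for ev in schedule.events:
        if ev.duration_h == 0.0:
            instant.setdefault(int(math.ceil(ev.t_h / dt - 1e-9)), []).append(ev)
        else:
            sustained.append(ev)

    sw = schedule.square_wave
    if sw is not None:
        sw_calib = calibs[sw.kind]
        sw_rate = dose_to_kick(sw.dose, sw_calib)  # kick magnitude per hour "on"
        sw_dir = sw_calib.kick_direction_rad

    radii = np.empty((n, n_steps + 1))
    phases = np.empty((n, n_steps + 1))
    radii[:, 0] = r
    phases[:, 0] = phi

    lam = params.relax_rate
    a0 = params.limit_radius
    sq_dt = math.sqrt(dt)

    for k in range(n_steps):
        t = k * dt
        # deterministic flow
        r = r + dt * lam * r * (a0 - r)
        phi = phi + dt * omega
        if params.phase_noise > 0.0:
            phi = phi + params.phase_noise * sq_dt * rng.standard_normal(n)
        # sustained drives active on (t, t+dt]
        dx = 0.0
        dy = 0.0
        t_mid = t + 0.5 * dt
        for ev in sustained:
            if ev.t_h <= t_mid < ev.t_h + ev.duration_h:
                c = calibs[ev.kind]
                rate = dose_to_kick(ev.dose, c)  # kick magnitude per hour held
                dx += dt * rate * math.cos(c.kick_direction_rad)
                dy += dt * rate * math.sin(c.kick_direction_rad)
        if sw is not None and (sw.end_h is None or t_mid < sw.end_h):
            if ((t_mid - sw.phase_offset_h) % sw.period_h) < sw.on_fraction * sw.period_h:
                dx += dt * sw_rate * math.cos(sw_dir)
                dy += dt * sw_rate * math.sin(sw_dir)
        if dx != 0.0 or dy != 0.0:
            r, phi = _apply_cartesian(r, phi, dx, dy)
        # instantaneous kicks at step boundary k+1
        for ev in instant.get(k + 1, ()):
            c = calibs[ev.kind]
            eps = dose_to_kick(ev.dose, c)
            r, phi = _apply_cartesian(
                r, phi,
                eps * math.cos(c.kick_direction_rad),
                eps * math.sin(c.kick_direction_rad),
            )
        radii[:, k + 1] = r
        phases[:, k + 1] = phi

    x = radii * np.cos(phases)
    per_cell = params.obs_baseline + params.obs_gain * x
    if params.obs_noise_sd > 0.0:
        per_cell = per_cell + params.obs_noise_sd * rng.standard_normal(per_cell.shape)
    ensemble = per_cell.mean(axis=0)

    return EnsembleRecording(
        time_h=time,
        ensemble_signal=ensemble,
        per_cell_signals=per_cell if keep_cells else None,
        phases_rad=phases,
        radii=radii,
        params=params,
        schedule=schedule,
    )


def simulate_cell_population(
    params: OscillatorEnsembleParams,
    treat_time_h: float,
    responder_fraction: float,
    t_end_h: float,
    boost: float = 2.5,
    bleach_rate: float = 0.008,
) -> CellTrajectorySet:
    """Simulate single-cell reporter trajectories with responder truth.

    Each cell is drawn as a responder with probability
    ``responder_fraction``; at ``treat_time_h`` responders receive a radial
    amplitude boost of magnitude ``boost`` (their limit-cycle excursion is
    transiently enlarged, so their next peak is higher), non-responders are
    untouched.  A slow multiplicative observation decay of ``bleach_rate``
    per hour emulates fluorophore bleaching, so unperturbed peak heights
    decline gently from cycle to cycle.
    """
    if not (0.0 < treat_time_h < t_end_h):
        raise ValueError("treat_time_h must lie inside (0, t_end_h)")
    if not (0.0 <= responder_fraction <= 1.0):
        raise ValueError("responder_fraction must be in [0, 1]")

    dt = params.dt_h
    n_steps = int(round(t_end_h / dt))
    time = np.arange(n_steps + 1) * dt
    rng = np.random.default_rng(params.seed)
    r, phi, tau = _init_state(params, rng)
    omega = 2.0 * math.pi / tau
    n = params.n_cells
    responders = rng.random(n) < responder_fraction

    radii = np.empty((n, n_steps + 1))
    phases = np.empty((n, n_steps + 1))
    radii[:, 0] = r
    phases[:, 0] = phi
    kick_step = int(math.ceil(treat_time_h / dt - 1e-9))

    lam = params.relax_rate
    a0 = params.limit_radius
    sq_dt = math.sqrt(dt)
    for k in range(n_steps):
        r = r + dt * lam * r * (a0 - r)
        phi = phi + dt * omega
        if params.phase_noise > 0.0:
            phi = phi + params.phase_noise * sq_dt * rng.standard_normal(n)
        if k + 1 == kick_step:
            r = np.where(responders, r + boost, r)
        radii[:, k + 1] = r
        phases[:, k + 1] = phi

    decay = np.exp(-bleach_rate * time)
    x = radii * np.cos(phases)
    signals = params.obs_baseline + params.obs_gain * decay[None, :] * x
    if params.obs_noise_sd > 0.0:
        signals = signals + params.obs_noise_sd * rng.standard_normal(signals.shape)

    return CellTrajectorySet(
        time_h=time,
        signals=signals,
        responder_truth=responders,
        treat_time_h=treat_time_h,
        cell_ids=[f"cell_{i:03d}" for i in range(n)],
    )
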