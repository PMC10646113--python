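"""Phase-response and phase-transition curves, dose-response tables.

The PRC tabulates the phase shift produced by a stimulus as a function of
the circadian (old) phase at which it was applied; the PTC maps old phase
to new phase.  The winding number of the PTC over one cycle classifies the
resetting: type 1 (winding 1, weak stimulus, the new-phase map is a
degree-1 circle map) versus type 0 (winding 0, strong stimulus, all old
phases are reset toward a common new phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .events import amplitude_percent_change, estimate_phase_shift, wrap_shift_h
from .series import LuminescenceSeries

__all__ = [
    "PhaseExperiment",
    "DoseExperiment",
    "PRCResult",
    "PTCResult",
    "DoseResponseTable",
    "build_prc",
    "build_ptc_classify",
    "build_dose_response",
]


@dataclass
class PhaseExperiment:
    """One stimulus-at-a-phase recording pair."""

    stimulus_phase_h: float
    event_time_h: float
    treated: LuminescenceSeries
    control: Optional[LuminescenceSeries] = None


@dataclass
class DoseExperiment:
    """One stimulus-at-a-dose recording pair (fixed phase)."""

    dose: float
    event_time_h: float
    treated: LuminescenceSeries
    control: Optional[LuminescenceSeries] = None


@dataclass
class PRCResult:
    """Phase-response table: shift and amplitude change per old phase."""

    old_phase_h: np.ndarray
    shift_h: np.ndarray
    amplitude_pct: np.ndarray
    stimulus: dict
    flags: list = field(default_factory=list)  # (phase, reason) for failures

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "old_phase_h": self.old_phase_h,
                "shift_h": self.shift_h,
                "amplitude_pct": self.amplitude_pct,
            }
        )


@dataclass
class PTCResult:
    """Phase-transition table with winding-number classification."""

    old_phase_h: np.ndarray
    new_phase_h: np.ndarray
    winding_number: Optional[int]
    resetting_type: str  # type1 | type0 | undetermined
    diagnostics: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"old_phase_h": self.old_phase_h, "new_phase_h": self.new_phase_h}
        )


def build_prc(
    experiments: Sequence[PhaseExperiment],
    method: str = "baseline_extrapolation",
    stimulus: Optional[dict] = None,
    amplitude_reference: str = "pre_event_peak",
    period_h: float = 24.0,
) -> PRCResult:
    """Assemble a PRC from per-phase stimulation experiments.

    Phases failing shift estimation are flagged (NaN entries) rather than
    silently dropped.
    """
    if len(experiments) < 4:
        raise ValueError("a PRC needs at least 4 stimulus phases")
    order = np.argsort([e.stimulus_phase_h for e in experiments])
    phases, shifts, amps, flags = [], [], [], []
    for i in order:
        exp = experiments[i]
        phases.append(exp.stimulus_phase_h % period_h)
        try:
            est = estimate_phase_shift(
                exp.treated, exp.event_time_h, control=exp.control,
                method=method, period_h=period_h,
            )
            shifts.append(est.shift_h)
        except ValueError as exc:
            shifts.append(np.nan)
            flags.append((exp.stimulus_phase_h, f"shift: {exc}"))
        try:
            amps.append(
                amplitude_percent_change(exp.treated, exp.event_time_h,
                                         reference=amplitude_reference)
            )
        except ValueError as exc:
            amps.append(np.nan)
            flags.append((exp.stimulus_phase_h, f"amplitude: {exc}"))
    return PRCResult(
        old_phase_h=np.asarray(phases),
        shift_h=np.asarray(shifts),
        amplitude_pct=np.asarray(amps),
        stimulus=stimulus or {},
        flags=flags,
    )


def build_ptc_classify(prc: PRCResult, period_h: float = 24.0) -> PTCResult:
    """Build the PTC from a PRC and classify resetting by winding number.

    new_phase = (old_phase + shift) mod period; successive new phases are
    unwrapped along sorted old phases with shortest-path jumps, and the
    winding number is the net number of cycles traversed as the old phase
    makes one full turn.  Fewer than 6 usable phases, or an ambiguous
    (near half-cycle) jump, yields the ``undetermined`` class.
    """
    ok = ~np.isnan(prc.shift_h)
    old = prc.old_phase_h[ok]
    new = (old + prc.shift_h[ok]) % period_h
    if old.size < 6:
        return PTCResult(old, new, None, "undetermined",
                         f"only {old.size} usable phases (need >= 6)")
    order = np.argsort(old)
    old, new = old[order], new[order]
    diffs = [wrap_shift_h(new[i + 1] - new[i], period_h) for i in range(old.size - 1)]
    closing = wrap_shift_h(new[0] - new[-1], period_h)
    jumps = np.abs(np.array(diffs + [closing]))
    if np.any(jumps >= period_h / 2.0 - 1e-9):
        return PTCResult(old, new, None, "undetermined",
                         f"ambiguous adjacent jump of {jumps.max():.2f} h")
    total = float(np.sum(diffs) + closing)
    w = int(round(total / period_h))
    if w == 1:
        kind = "type1"
    elif w == 0:
        kind = "type0"
    else:
        kind = "undetermined"
    return PTCResult(old, new, w, kind, f"net traversal {total:.2f} h")


@dataclass
class DoseResponseTable:
    """Dose -> (phase shift, amplitude %) table with monotonicity diagnostics."""

    dose: np.ndarray
    shift_h: np.ndarray
    shift_sd_h: np.ndarray
    amplitude_pct: np.ndarray
    amplitude_sd_pct: np.ndarray
    concordance: float  # Spearman rho of |shift| with dose

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose": self.dose,
                "shift_h": self.shift_h,
                "shift_sd_h": self.shift_sd_h,
                "amplitude_pct": self.amplitude_pct,
                "amplitude_sd_pct": self.amplitude_sd_pct,
            }
        )


def build_dose_response(
    experiments: Sequence[DoseExperiment],
    method: str = "baseline_extrapolation",
    amplitude_reference: str = "pre_event_peak",
    period_h: float = 24.0,
) -> DoseResponseTable:
    """Assemble the dose dependence of resetting at a fixed stimulus phase.

    Duplicate doses are aggregated as mean with SD.  The concordance field
    is the Spearman correlation of |shift| with dose (NaN-safe).
    """
    doses = sorted({e.dose for e in experiments})
    if len(doses) < 3 or 0.0 not in doses:
        raise ValueError("dose response needs >= 3 distinct doses including 0")
    rows = {d: {"shift": [], "amp": []} for d in doses}
    for exp in experiments:
        try:
            est = estimate_phase_shift(exp.treated, exp.event_time_h,
                                       control=exp.control, method=method,
                                       period_h=period_h)
            rows[exp.dose]["shift"].append(est.shift_h)
        except ValueError:
            rows[exp.dose]["shift"].append(np.nan)
        try:
            rows[exp.dose]["amp"].append(
                amplitude_percent_change(exp.treated, exp.event_time_h,
                                         reference=amplitude_reference)
            )
        except ValueError:
            rows[exp.dose]["amp"].append(np.nan)

    def _agg(values):
        arr = np.asarray(values, dtype=float)
        good = arr[~np.isnan(arr)]
        if good.size == 0:
            return np.nan, np.nan
        sd = float(np.std(good, ddof=1)) if good.size > 1 else 0.0
        return float(np.mean(good)), sd

    shift_m, shift_s, amp_m, amp_s = [], [], [], []
    for d in doses:
        m, s = _agg(rows[d]["shift"])
        shift_m.append(m)
        shift_s.append(s)
        m, s = _agg(rows[d]["amp"])
        amp_m.append(m)
        amp_s.append(s)
    dose_arr = np.asarray(doses, dtype=float)
    shift_arr = np.asarray(shift_m)
    good = ~np.isnan(shift_arr)
    if good.sum() >= 3:
        rho = float(_stats.spearmanr(dose_arr[good], np.abs(shift_arr[good])).statistic)
    else:
        rho = float("nan")
    return DoseResponseTable(dose_arr, shift_arr, np.asarray(shift_s),
                             np.asarray(amp_m), np.asarray(amp_s), rho)
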