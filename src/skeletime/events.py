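"""Peak detection and event-referenced rhythm quantifications.

Two quantities recur in loading/osmolarity resetting experiments: the
amplitude of the first post-stimulus peak expressed as a percentage of a
reference peak, and the phase shift of the post-stimulus rhythm relative
to either the extrapolated pre-stimulus rhythm or a parallel untreated
control.  Shifts are wrapped to (-12, +12] hours with advances positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .cosinor import Cosinor
from .series import LuminescenceSeries

__all__ = [
    "PeakSet",
    "PhaseShiftEstimate",
    "detect_peaks",
    "amplitude_percent_change",
    "estimate_phase_shift",
    "wrap_shift_h",
]


def wrap_shift_h(shift_h: float, period_h: float = 24.0) -> float:
    """Wrap a phase shift to (-period/2, +period/2]."""
    half = period_h / 2.0
    y = (shift_h + half) % period_h - half
    if y == -half:
        y = half
    return float(y)


@dataclass
class PeakSet:
    """Detected local maxima/minima of a smoothed, detrended trace."""

    peak_times_h: np.ndarray
    peak_heights: np.ndarray
    trough_times_h: np.ndarray
    trough_heights: np.ndarray

    def last_peak_at_or_before(self, t_h: float):
        idx = np.where(self.peak_times_h <= t_h)[0]
        if idx.size == 0:
            return None
        i = idx[-1]
        return float(self.peak_times_h[i]), float(self.peak_heights[i])

    def first_peak_after(self, t_h: float):
        idx = np.where(self.peak_times_h > t_h)[0]
        if idx.size == 0:
            return None
        i = idx[0]
        return float(self.peak_times_h[i]), float(self.peak_heights[i])

    def peak_nearest(self, t_h: float):
        if self.peak_times_h.size == 0:
            return None
        i = int(np.argmin(np.abs(self.peak_times_h - t_h)))
        return float(self.peak_times_h[i]), float(self.peak_heights[i])


def _smooth(signal: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return signal
    kernel = np.ones(w) / w
    # normalized 'same' convolution so edges keep correct averaging weight
    num = np.convolve(signal, kernel, mode="same")
    den = np.convolve(np.ones_like(signal), kernel, mode="same")
    return num / den


def detect_peaks(series: LuminescenceSeries, min_separation_h: float = 16.0,
                 smooth_window_h: float = 4.0) -> PeakSet:
    """Find circadian peaks and troughs on a uniform (detrended) trace.

    Local maxima of the smoothed signal with an enforced minimum peak
    separation; on conflicts the higher peak wins.  No detectable peak is
    a valid (empty) result, not an error.
    """
    dt = series.dt_h
    w = max(1, int(round(smooth_window_h / dt)))
    if w % 2 == 0:
        w += 1
    smoothed = _smooth(series.signal, w)
    distance = max(1, int(round(min_separation_h / dt)))
    pk, _ = find_peaks(smoothed, distance=distance)
    tr, _ = find_peaks(-smoothed, distance=distance)
    return PeakSet(
        peak_times_h=series.time_h[pk].copy(),
        peak_heights=smoothed[pk].copy(),
        trough_times_h=series.time_h[tr].copy(),
        trough_heights=smoothed[tr].copy(),
    )


def amplitude_percent_change(
    series: LuminescenceSeries,
    event_time_h: float,
    reference: str = "pre_event_peak",
    min_separation_h: float = 16.0,
    smooth_window_h: float = 4.0,
) -> float:
    """First post-event peak height as % of a reference peak height.

    ``reference="pre_event_peak"`` uses the last peak at or before the
    event; ``reference="peak_24h_after_start"`` uses the peak nearest
    t = start + 24 h.  Operates on detrended peak heights, so the result
    is invariant to mesor offsets.
    """
    if reference not in ("pre_event_peak", "peak_24h_after_start"):
        raise ValueError(f"unknown reference mode {reference!r}")
    peaks = detect_peaks(series, min_separation_h, smooth_window_h)
    post = peaks.first_peak_after(event_time_h)
    if post is None:
        raise ValueError(f"no peak found after the event at t={event_time_h} h")
    if reference == "pre_event_peak":
        ref = peaks.last_peak_at_or_before(event_time_h)
        if ref is None:
            raise ValueError(f"no reference peak at or before t={event_time_h} h")
    else:
        ref = peaks.peak_nearest(series.time_h[0] + 24.0)
        if ref is None:
            raise ValueError("no reference peak near 24 h after recording start")
    if ref[1] == 0:
        raise ValueError("reference peak height is zero; percentage undefined")
    return 100.0 * post[1] / ref[1]


@dataclass
class PhaseShiftEstimate:
    """Phase shift in hours, advance positive, wrapped to (-12, +12]."""

    shift_h: float
    method: str
    se_h: float
    pre_acrophase_h: Optional[float] = None
    post_acrophase_h: Optional[float] = None

    def __post_init__(self) -> None:
        if abs(self.shift_h) > 12.0:
            raise ValueError("shift_h must be within (-12, 12]")


def estimate_phase_shift(
    treated: LuminescenceSeries,
    event_time_h: float,
    control: Optional[LuminescenceSeries] = None,
    method: str = "baseline_extrapolation",
    period_h: float = 24.0,
    transient_h: float = 12.0,
) -> PhaseShiftEstimate:
    """Phase shift of a treated rhythm, advance positive.

    baseline_extrapolation
        Fit a fixed-period cosinor to the pre-event window and another to
        the post-event window (excluding a ``transient_h`` settling
        transient); the shift is the predicted-minus-observed peak time,
        wrapped to (-12, +12], so an earlier-than-predicted peak is a
        positive advance.
    control_referenced
        Same formula, with the control's post-window acrophase as the
        prediction.
    """
    if method == "baseline_extrapolation":
        pre_end = event_time_h
        if pre_end - treated.time_h[0] < 2.0 * period_h:
            raise ValueError("baseline_extrapolation needs >= 2 cycles before the event")
        if treated.time_h[-1] - event_time_h < 1.5 * period_h:
            raise ValueError("baseline_extrapolation needs >= 1.5 cycles after the event")
        pre = treated.window(treated.time_h[0], pre_end)
        post = treated.window(event_time_h + transient_h, treated.time_h[-1])
        fit_pre = Cosinor.from_series(pre, period_h=period_h).fit()
        fit_post = Cosinor.from_series(post, period_h=period_h).fit()
        if fit_pre.p_zero_amplitude > 0.5 and fit_post.p_zero_amplitude > 0.5:
            raise ValueError("no phase defined: both windows non-rhythmic")
        shift = wrap_shift_h(fit_pre.acrophase_h - fit_post.acrophase_h, period_h)
        se = math.hypot(fit_pre.acrophase_se_h, fit_post.acrophase_se_h)
        return PhaseShiftEstimate(shift, method, se,
                                  fit_pre.acrophase_h, fit_post.acrophase_h)
    if method == "control_referenced":
        if control is None:
            raise ValueError("control_referenced requires a control series")
        t_lo = event_time_h + transient_h
        if control.time_h[-1] < treated.time_h[-1] - 1e-9 or control.time_h[0] > t_lo:
            raise ValueError("control series does not cover the post-event window")
        post_t = treated.window(t_lo, treated.time_h[-1])
        post_c = control.window(t_lo, treated.time_h[-1])
        fit_t = Cosinor.from_series(post_t, period_h=period_h).fit()
        fit_c = Cosinor.from_series(post_c, period_h=period_h).fit()
        if fit_t.p_zero_amplitude > 0.5 and fit_c.p_zero_amplitude > 0.5:
            raise ValueError("no phase defined: both series non-rhythmic")
        shift = wrap_shift_h(fit_c.acrophase_h - fit_t.acrophase_h, period_h)
        se = math.hypot(fit_t.acrophase_se_h, fit_c.acrophase_se_h)
        return PhaseShiftEstimate(shift, method, se,
                                  fit_c.acrophase_h, fit_t.acrophase_h)
    raise ValueError("method must be 'baseline_extrapolation' or 'control_referenced'")
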