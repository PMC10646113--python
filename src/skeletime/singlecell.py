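"""Single-cell reporter trajectory normalization and responder calling.

A cell counts as responding to a treatment if the detrended height of its
first peak after the treatment exceeds the height of its reference peak
before the treatment (strict inequality).  Trajectories are displayed and
compared after either AUC normalization (divide by the mean level over the
first 48 h) or per-cell z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .events import detect_peaks
from .series import LuminescenceSeries, detrend_moving_average

__all__ = [
    "ResponderCall",
    "ResponderSummary",
    "normalize_trajectories",
    "classify_responder",
    "classify_population",
    "responder_fraction",
]


@dataclass
class ResponderCall:
    """Per-cell responder decision with the peaks it was based on."""

    cell_id: str
    pre_peak: Optional[tuple]   # (time_h, height) or None
    post_peak: Optional[tuple]
    responder: Optional[bool]   # None when undefined
    reason: str = ""


@dataclass
class ResponderSummary:
    percent: float
    ci_low_pct: float
    ci_high_pct: float
    n_responders: int
    n_defined: int
    n_undefined: int


def normalize_trajectories(
    time_h: np.ndarray,
    trajectories: np.ndarray,
    auc_window_h: float = 48.0,
    mode: str = "auc",
):
    """Normalize a cells x time trajectory matrix.

    ``auc`` divides each trajectory by its trapezoidal AUC over the first
    ``auc_window_h`` hours divided by the window length (i.e. its mean
    level), making the result scale-invariant; ``zscore`` centres and
    scales each trajectory to mean 0, SD 1 over its full length.

    Returns ``(normalized, excluded)`` where ``excluded`` maps row index
    to a reason for cells that could not be normalized (their rows are
    NaN).
    """
    time_h = np.asarray(time_h, dtype=float)
    X = np.asarray(trajectories, dtype=float)
    if X.ndim != 2 or X.shape[1] != time_h.size:
        raise ValueError("trajectories must be cells x time matching time_h")
    if mode not in ("auc", "zscore"):
        raise ValueError("mode must be 'auc' or 'zscore'")
    out = np.empty_like(X)
    excluded: dict[int, str] = {}
    if mode == "auc":
        if time_h[-1] - time_h[0] < auc_window_h:
            raise ValueError("trajectories do not cover the AUC window")
        mask = time_h <= time_h[0] + auc_window_h
        for i in range(X.shape[0]):
            auc = np.trapezoid(X[i, mask], time_h[mask]) / auc_window_h
            if auc <= 0:
                out[i] = np.nan
                excluded[i] = f"non-positive AUC ({auc:.3g}) over the first {auc_window_h:g} h"
            else:
                out[i] = X[i] / auc
    else:
        for i in range(X.shape[0]):
            sd = X[i].std()
            if sd == 0:
                out[i] = np.nan
                excluded[i] = "zero variance"
            else:
                out[i] = (X[i] - X[i].mean()) / sd
    return out, excluded


def classify_responder(
    cell: LuminescenceSeries,
    treat_time_h: float,
    search_window_h: float = 30.0,
    pre_rule: str = "highest",
    min_separation_h: float = 16.0,
    smooth_window_h: float = 4.0,
) -> ResponderCall:
    """Call one (detrended) cell trajectory as responder / non-responder.

    The pre-treatment reference peak is the highest (default) or last
    detected peak in (treat - search_window, treat]; the post peak is the
    first detected peak in (treat, treat + search_window].  The cell
    responds iff post height > pre height, strictly.  A missing peak makes
    the call undefined with the reason recorded.
    """
    if pre_rule not in ("highest", "last"):
        raise ValueError("pre_rule must be 'highest' or 'last'")
    if not (cell.time_h[0] < treat_time_h < cell.time_h[-1]):
        raise ValueError("treat_time_h must lie inside the recording")
    peaks = detect_peaks(cell, min_separation_h, smooth_window_h)
    lo = treat_time_h - search_window_h
    pre_mask = (peaks.peak_times_h > lo) & (peaks.peak_times_h <= treat_time_h)
    post_mask = (peaks.peak_times_h > treat_time_h) & (
        peaks.peak_times_h <= treat_time_h + search_window_h
    )
    pre = post = None
    if pre_mask.any():
        times = peaks.peak_times_h[pre_mask]
        heights = peaks.peak_heights[pre_mask]
        i = int(np.argmax(heights)) if pre_rule == "highest" else -1
        pre = (float(times[i]), float(heights[i]))
    if post_mask.any():
        times = peaks.peak_times_h[post_mask]
        heights = peaks.peak_heights[post_mask]
        post = (float(times[0]), float(heights[0]))
    if pre is None or post is None:
        missing = []
        if pre is None:
            missing.append("pre-treatment")
        if post is None:
            missing.append("post-treatment")
        return ResponderCall(cell.trace_id, pre, post, None,
                             f"missing {' and '.join(missing)} peak")
    return ResponderCall(cell.trace_id, pre, post, post[1] > pre[1])


def classify_population(
    time_h: np.ndarray,
    signals: np.ndarray,
    treat_time_h: float,
    cell_ids: Optional[Sequence[str]] = None,
    detrend_window_h: float = 24.0,
    **kwargs,
) -> list[ResponderCall]:
    """Detrend and classify every cell of a trajectory matrix."""
    calls = []
    ids = cell_ids or [f"cell_{i:03d}" for i in range(signals.shape[0])]
    for i in range(signals.shape[0]):
        cell = LuminescenceSeries(time_h, signals[i], ids[i])
        try:
            detr = detrend_moving_average(cell, window_h=detrend_window_h)
            calls.append(classify_responder(detr, treat_time_h, **kwargs))
        except ValueError as exc:
            calls.append(ResponderCall(ids[i], None, None, None, str(exc)))
    return calls


def responder_fraction(calls: Sequence[ResponderCall]) -> ResponderSummary:
    """Percentage of responding cells with an exact (Clopper-Pearson) CI.

    Undefined calls are reported separately and excluded from the
    denominator.
    """
    defined = [c for c in calls if c.responder is not None]
    if not defined:
        raise ValueError("no defined responder calls")
    n_resp = sum(c.responder for c in defined)
    lo, hi = proportion_confint(n_resp, len(defined), alpha=0.05, method="beta")
    return ResponderSummary(
        percent=100.0 * n_resp / len(defined),
        ci_low_pct=100.0 * lo,
        ci_high_pct=100.0 * hi,
        n_responders=n_resp,
        n_defined=len(defined),
        n_undefined=len(calls) - len(defined),
    )


def calls_to_frame(calls: Sequence[ResponderCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "cell_id": c.cell_id,
                "pre_time_h": c.pre_peak[0] if c.pre_peak else np.nan,
                "pre_height": c.pre_peak[1] if c.pre_peak else np.nan,
                "post_time_h": c.post_peak[0] if c.post_peak else np.nan,
                "post_height": c.post_peak[1] if c.post_peak else np.nan,
                "responder": c.responder,
                "reason": c.reason,
            }
        )
    return pd.DataFrame(rows)
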