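"""Recording time-series container, CSV I/O, detrending and resampling.

Recordings travel as wide CSV: first column ``time_h``, one column per
trace, optional ``#``-prefixed metadata header lines (``# key: value``).
Detrending follows standard practice for multi-day bioluminescence traces:
subtract (or divide by) a centred 24 h moving average, trimming the
half-window at each edge rather than padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LuminescenceSeries",
    "read_series_csv",
    "write_series_csv",
    "detrend_moving_average",
    "resample_uniform",
]


@dataclass
class LuminescenceSeries:
    """One recording trace: an increasing hour grid plus signal values."""

    time_h: np.ndarray
    signal: np.ndarray
    trace_id: str = "trace"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_h.ndim != 1 or self.signal.ndim != 1:
            raise ValueError("time_h and signal must be 1-D")
        if self.time_h.size != self.signal.size:
            raise ValueError("time_h and signal must have equal length")
        if self.time_h.size < 2:
            raise ValueError("a series needs at least 2 samples")
        if np.any(~np.isfinite(self.time_h)):
            raise ValueError("time_h contains non-finite values")
        diffs = np.diff(self.time_h)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise ValueError(
                f"time_h must be strictly increasing; violation at row {i + 1} "
                f"(t={self.time_h[i + 1]!r} after t={self.time_h[i]!r})"
            )

    @property
    def duration_h(self) -> float:
        return float(self.time_h[-1] - self.time_h[0])

    @property
    def dt_h(self) -> float:
        """Sampling step; raises if the grid is not uniform."""
        diffs = np.diff(self.time_h)
        dt = float(np.median(diffs))
        if not np.allclose(diffs, dt, rtol=1e-6, atol=1e-9):
            raise ValueError(f"series {self.trace_id!r} is not uniformly sampled")
        return dt

    def is_uniform(self) -> bool:
        diffs = np.diff(self.time_h)
        return bool(np.allclose(diffs, np.median(diffs), rtol=1e-6, atol=1e-9))

    def window(self, t_start: float, t_end: float) -> "LuminescenceSeries":
        """Sub-series with t_start <= t <= t_end."""
        mask = (self.time_h >= t_start) & (self.time_h <= t_end)
        if mask.sum() < 2:
            raise ValueError(
                f"window [{t_start}, {t_end}] contains fewer than 2 samples"
            )
        return LuminescenceSeries(
            self.time_h[mask], self.signal[mask], self.trace_id, dict(self.meta)
        )


def read_series_csv(path: str | Path) -> list[LuminescenceSeries]:
    """Read a wide recording CSV into one series per non-time column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, value = body.split(":", 1)
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    if df.columns[0] != "time_h":
        raise ValueError(f"first column must be 'time_h', got {df.columns[0]!r}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(f"non-numeric value in column {col!r}, row {row}")
        if df[col].isna().any():
            row = int(np.argmax(df[col].isna().to_numpy()))
            raise ValueError(f"missing value in column {col!r}, row {row}")
    time = df["time_h"].to_numpy(dtype=float)
    return [
        LuminescenceSeries(time.copy(), df[col].to_numpy(dtype=float), str(col), dict(meta))
        for col in df.columns[1:]
    ]


def write_series_csv(
    path: str | Path, series: list[LuminescenceSeries], meta: dict | None = None
) -> None:
    """Write series sharing one time grid as a wide CSV (12 sig. digits)."""
    if not series:
        raise ValueError("nothing to write")
    time = series[0].time_h
    for s in series[1:]:
        if s.time_h.shape != time.shape or not np.allclose(s.time_h, time):
            raise ValueError("all series in one CSV must share the time grid")
    df = pd.DataFrame({"time_h": time})
    for s in series:
        df[s.trace_id] = s.signal
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def detrend_moving_average(
    series: LuminescenceSeries, window_h: float = 24.0, mode: str = "subtract"
) -> LuminescenceSeries:
    """Remove the slow trend with a centred moving average of ``window_h``.

    The trend is the centred moving average over ``window_h``; the output
    is signal - trend (``mode="subtract"``) or signal / trend
    (``mode="divide"``), with the half-window trimmed at each edge.
    """
    if mode not in ("subtract", "divide"):
        raise ValueError("mode must be 'subtract' or 'divide'")
    dt = series.dt_h  # also enforces uniformity
    if series.duration_h < window_h:
        raise ValueError(
            f"series duration {series.duration_h:.1f} h is shorter than the "
            f"{window_h:.1f} h window"
        )
    n = int(round(window_h / dt))
    if n < 2:
        raise ValueError("window_h must cover at least 2 sampling steps")
    # trapezoid-weighted centred window spanning exactly window_h: the
    # half-weighted endpoints make the average of a cosine over one full
    # period vanish identically on a uniform grid
    kernel = np.ones(n + 1)
    kernel[0] = kernel[-1] = 0.5
    kernel /= n
    if n % 2 == 1:  # odd step count: keep the window symmetric on the grid
        kernel = np.convolve(kernel, [0.5, 0.5])
    trend = np.convolve(series.signal, kernel, mode="valid")
    half = (kernel.size - 1) // 2
    time = series.time_h[half : half + trend.size]
    core = series.signal[half : half + trend.size]
    if mode == "subtract":
        out = core - trend
    else:
        if np.any(trend == 0):
            raise ValueError("divide mode undefined: moving average hits 0")
        out = core / trend
    return LuminescenceSeries(time.copy(), out, series.trace_id, dict(series.meta))


def resample_uniform(series: LuminescenceSeries, dt_h: float) -> LuminescenceSeries:
    """Linearly interpolate onto a uniform grid spanning the series range."""
    if dt_h <= 0:
        raise ValueError("dt_h must be > 0")
    if dt_h > series.duration_h / 2.0:
        raise ValueError(
            f"dt_h={dt_h} h exceeds half the series duration "
            f"({series.duration_h:.1f} h)"
        )
    n = int(np.floor(series.duration_h / dt_h + 1e-9))
    grid = series.time_h[0] + dt_h * np.arange(n + 1)
    values = np.interp(grid, series.time_h, series.signal)
    return LuminescenceSeries(grid, values, series.trace_id, dict(series.meta))
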