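"""Cosinor rhythmometry: fixed-period and damped cosinor model objects.

The single-component cosinor model is

    y(t) = M + A * cos(2*pi*(t - phi_a) / T) + e

with mesor M, amplitude A >= 0, acrophase phi_a (hours after the reference
time at which the fitted curve peaks, in [0, T)) and period T.  With T
fixed the model is linear in (M, beta_c, beta_s) via the sin/cos
parameterization and is fitted by least squares; rhythmicity is assessed
by the zero-amplitude F test against the intercept-only model with
(2, n - 3) degrees of freedom.

The damped variant multiplies the oscillatory part by exp(-d * t) and
frees the period; it is fitted by multi-start nonlinear least squares over
a 1 h period grid.  Model classes follow the Model -> fit() -> Results
convention; Results objects carry estimates, uncertainties and a
summary() table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .series import LuminescenceSeries

__all__ = [
    "Cosinor",
    "CosinorResults",
    "DampedCosinor",
    "DampedCosinorResults",
    "PeriodEstimate",
    "estimate_period",
    "rhythmicity_test",
]


def _as_arrays(endog, time_h):
    y = np.asarray(endog, dtype=float)
    t = np.asarray(time_h, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("endog and time_h must be 1-D arrays of equal length")
    return y, t


class Cosinor:
    """Fixed-period cosinor model for one time series.

    Parameters
    ----------
    endog : array-like
        Observed signal.
    time_h : array-like
        Observation times in hours.
    period_h : float
        Fixed oscillation period.
    t0_ref : float
        Reference time; the acrophase is reported in hours after it.
    """

    def __init__(self, endog, time_h, period_h: float = 24.0, t0_ref: float = 0.0):
        self.endog, self.time_h = _as_arrays(endog, time_h)
        if period_h <= 0:
            raise ValueError("period_h must be > 0")
        if self.endog.size < 6:
            raise ValueError("cosinor fit needs at least 6 samples")
        if self.time_h.max() - self.time_h.min() < period_h:
            raise ValueError("cosinor fit needs data spanning at least one period")
        self.period_h = float(period_h)
        self.t0_ref = float(t0_ref)

    @classmethod
    def from_series(cls, series: LuminescenceSeries, period_h: float = 24.0,
                    t0_ref: float = 0.0) -> "Cosinor":
        return cls(series.signal, series.time_h, period_h=period_h, t0_ref=t0_ref)

    def fit(self) -> "CosinorResults":
        y, t = self.endog, self.time_h
        omega = 2.0 * math.pi / self.period_h
        tt = t - self.t0_ref
        X = np.column_stack([np.ones_like(tt), np.cos(omega * tt), np.sin(omega * tt)])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 3:
            raise ValueError(
                "rank-deficient cosinor design (all samples at one phase?)"
            )
        resid = y - X @ beta
        rss = float(resid @ resid)
        n = y.size
        rss0 = float(np.sum((y - y.mean()) ** 2))
        df_resid = n - 3
        sigma2 = rss / df_resid if df_resid > 0 else np.nan
        if rss <= 0 and rss0 <= 0:
            f_stat, p = 0.0, 1.0
        elif rss <= 0:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = ((rss0 - rss) / 2.0) / (rss / df_resid)
            f_stat = max(f_stat, 0.0)
            p = float(stats.f.sf(f_stat, 2, df_resid))
        cov = sigma2 * np.linalg.inv(X.T @ X)
        return CosinorResults(self, beta, cov, rss, rss0, f_stat, p)


class CosinorResults:
    """Results of a fixed-period cosinor fit."""

    def __init__(self, model: Cosinor, beta, cov, rss, rss0, f_zero_amplitude, p):
        self.model = model
        self.params = beta                      # (mesor, beta_cos, beta_sin)
        self.cov_params = cov
        self.rss = rss
        self.f_zero_amplitude = f_zero_amplitude
        self.p_zero_amplitude = p
        self.nobs = model.endog.size
        self.df_resid = self.nobs - 3
        self.r2 = 1.0 - rss / rss0 if rss0 > 0 else 0.0
        self.period_h = model.period_h

    @property
    def mesor(self) -> float:
        return float(self.params[0])

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.params[1], self.params[2]))

    @property
    def acrophase_h(self) -> float:
        """Hours after t0_ref at which the fitted curve peaks, in [0, T)."""
        psi = math.atan2(self.params[2], self.params[1])
        omega = 2.0 * math.pi / self.period_h
        value = (psi / omega) % self.period_h
        return 0.0 if value >= self.period_h - 1e-9 else value

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def amplitude_se(self) -> float:
        bc, bs = self.params[1], self.params[2]
        a = self.amplitude
        if a == 0:
            return float("nan")
        g = np.array([0.0, bc / a, bs / a])
        return float(np.sqrt(g @ self.cov_params @ g))

    @property
    def acrophase_se_h(self) -> float:
        bc, bs = self.params[1], self.params[2]
        a2 = bc * bc + bs * bs
        if a2 == 0:
            return float("nan")
        g = np.array([0.0, -bs / a2, bc / a2])  # d psi / d beta
        se_psi = float(np.sqrt(g @ self.cov_params @ g))
        return se_psi * self.period_h / (2.0 * math.pi)

    def predict(self, time_h) -> np.ndarray:
        t = np.asarray(time_h, dtype=float) - self.model.t0_ref
        omega = 2.0 * math.pi / self.period_h
        return self.params[0] + self.params[1] * np.cos(omega * t) + \
            self.params[2] * np.sin(omega * t)

    def peak_times_h(self, t_start: float, t_end: float) -> np.ndarray:
        """Predicted peak times of the fitted rhythm in [t_start, t_end]."""
        first = self.model.t0_ref + self.acrophase_h
        k_lo = math.floor((t_start - first) / self.period_h)
        k_hi = math.ceil((t_end - first) / self.period_h)
        peaks = first + self.period_h * np.arange(k_lo, k_hi + 1)
        return peaks[(peaks >= t_start) & (peaks <= t_end)]

    def summary(self) -> str:
        lines = [
            "Cosinor fit (fixed period)",
            "=" * 44,
            f"{'n obs':<22}{self.nobs:>22}",
            f"{'period (h)':<22}{self.period_h:>22.3f}",
            f"{'mesor':<22}{self.mesor:>22.4f}",
            f"{'amplitude':<22}{self.amplitude:>22.4f}",
            f"{'amplitude SE':<22}{self.amplitude_se:>22.4f}",
            f"{'acrophase (h)':<22}{self.acrophase_h:>22.3f}",
            f"{'acrophase SE (h)':<22}{self.acrophase_se_h:>22.3f}",
            f"{'R^2':<22}{self.r2:>22.4f}",
            f"{'zero-amplitude F':<22}{self.f_zero_amplitude:>22.3f}",
            f"{'zero-amplitude p':<22}{self.p_zero_amplitude:>22.3e}",
            "=" * 44,
        ]
        return "\n".join(lines)


class DampedCosinor:
    """Damped cosinor with free period, fitted by multi-start least squares.

    y(t) = M + A * exp(-d * t) * cos(2*pi*(t - phi_a)/T), with the period
    searched over ``period_bounds`` from a 1 h initialization grid.  Ties
    on equal residual sums are broken toward smaller damping, then period
    closer to 24 h.
    """

    def __init__(self, endog, time_h, period_bounds: tuple[float, float] = (18.0, 30.0),
                 t0_ref: float = 0.0):
        self.endog, self.time_h = _as_arrays(endog, time_h)
        lo, hi = period_bounds
        if not (0 < lo < hi):
            raise ValueError("invalid period_bounds")
        span = self.time_h.max() - self.time_h.min()
        if span < 2.0 * lo:
            raise ValueError("damped cosinor needs at least 2 full cycles of data")
        self.period_bounds = (float(lo), float(hi))
        self.t0_ref = float(t0_ref)

    @classmethod
    def from_series(cls, series: LuminescenceSeries,
                    period_bounds: tuple[float, float] = (18.0, 30.0),
                    t0_ref: float = 0.0) -> "DampedCosinor":
        return cls(series.signal, series.time_h, period_bounds=period_bounds,
                   t0_ref=t0_ref)

    def _residual(self, theta, t, y):
        m, a, d, T, phi = theta
        return m + a * np.exp(-d * t) * np.cos(2.0 * math.pi * (t - phi) / T) - y

    def fit(self) -> "DampedCosinorResults":
        y = self.endog
        t = self.time_h - self.t0_ref
        lo, hi = self.period_bounds
        grid = np.arange(lo, hi + 1e-9, 1.0)
        scale = float(np.std(y)) or 1.0
        candidates = []
        diagnostics = []
        for T0 in grid:
            try:
                lin = Cosinor(y, t, period_h=float(T0)).fit()
            except ValueError:
                continue
            x0 = np.array([lin.mesor, max(lin.amplitude, 1e-3 * scale), 0.005,
                           float(T0), lin.acrophase_h])
            try:
                sol = least_squares(
                    self._residual, x0, args=(t, y),
                    bounds=([-np.inf, 0.0, -0.2, lo, -hi], [np.inf, np.inf, 0.5, hi, 2 * hi]),
                    max_nfev=2000,
                )
            except Exception as exc:  # pragma: no cover - numerical guard
                diagnostics.append((float(T0), repr(exc)))
                continue
            if not sol.success:
                diagnostics.append((float(T0), sol.message))
                continue
            rss = float(sol.fun @ sol.fun)
            candidates.append((rss, sol))
        if not candidates:
            raise RuntimeError(
                f"damped cosinor failed to converge from any start: {diagnostics}"
            )
        best_rss = min(c[0] for c in candidates)
        # tie-break among near-equal fits: smaller damping, period nearer 24 h
        near = [c for c in candidates if c[0] <= best_rss * (1 + 1e-9) + 1e-12]
        near.sort(key=lambda c: (abs(c[1].x[2]), abs(c[1].x[3] - 24.0)))
        rss, sol = near[0]
        return DampedCosinorResults(self, sol, rss)


class DampedCosinorResults:
    """Results of a damped-cosinor fit."""

    def __init__(self, model: DampedCosinor, sol, rss):
        self.model = model
        m, a, d, T, phi = sol.x
        if a < 0:
            a, phi = -a, phi + T / 2.0
        self.mesor = float(m)
        self.amplitude = float(a)
        self.damping_rate = float(d)
        self.period_h = float(T)
        self.acrophase_h = float(phi % T)
        self.rss = float(rss)
        self.nobs = model.endog.size
        self.df_resid = self.nobs - 5
        rss0 = float(np.sum((model.endog - model.endog.mean()) ** 2))
        self.r2 = 1.0 - rss / rss0 if rss0 > 0 else 0.0
        # asymptotic covariance from the final Jacobian
        J = sol.jac
        sigma2 = rss / max(self.df_resid, 1)
        try:
            self.cov_params = sigma2 * np.linalg.inv(J.T @ J)
        except np.linalg.LinAlgError:
            self.cov_params = np.full((5, 5), np.nan)
        self.bse = np.sqrt(np.abs(np.diag(self.cov_params)))

    @property
    def period_se_h(self) -> float:
        return float(self.bse[3])

    def predict(self, time_h) -> np.ndarray:
        t = np.asarray(time_h, dtype=float) - self.model.t0_ref
        return self.mesor + self.amplitude * np.exp(-self.damping_rate * t) * \
            np.cos(2.0 * math.pi * (t - self.acrophase_h) / self.period_h)

    def summary(self) -> str:
        lines = [
            "Damped cosinor fit",
            "=" * 44,
            f"{'n obs':<22}{self.nobs:>22}",
            f"{'mesor':<22}{self.mesor:>22.4f}",
            f"{'amplitude':<22}{self.amplitude:>22.4f}",
            f"{'damping (1/h)':<22}{self.damping_rate:>22.5f}",
            f"{'period (h)':<22}{self.period_h:>22.3f}",
            f"{'period SE (h)':<22}{self.period_se_h:>22.3f}",
            f"{'acrophase (h)':<22}{self.acrophase_h:>22.3f}",
            f"{'R^2':<22}{self.r2:>22.4f}",
            f"{'RSS':<22}{self.rss:>22.4g}",
            "=" * 44,
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class PeriodEstimate:
    period_h: float
    se_h: float
    method: str


def estimate_period(series: LuminescenceSeries, method: str = "damped_cosinor",
                    period_bounds: tuple[float, float] = (18.0, 30.0)) -> PeriodEstimate:
    """Estimate the free-running period of a (detrended) recording.

    ``damped_cosinor`` reports the fitted period with its asymptotic SE;
    ``peak_to_peak`` reports the mean and SD of successive peak intervals.
    """
    if method == "damped_cosinor":
        res = DampedCosinor.from_series(series, period_bounds=period_bounds).fit()
        return PeriodEstimate(res.period_h, res.period_se_h, method)
    if method == "peak_to_peak":
        from .events import detect_peaks  # local import to avoid a cycle

        peaks = detect_peaks(series)
        if len(peaks.peak_times_h) < 3:
            raise ValueError(
                f"peak_to_peak needs >= 3 peaks, found {len(peaks.peak_times_h)}"
            )
        intervals = np.diff(peaks.peak_times_h)
        return PeriodEstimate(float(np.mean(intervals)), float(np.std(intervals, ddof=1)),
                              method)
    raise ValueError("method must be 'damped_cosinor' or 'peak_to_peak'")


def _f_stats_null(y_perm: np.ndarray, Q: np.ndarray, df_resid: int) -> np.ndarray:
    """Zero-amplitude F statistics for rows of permuted responses."""
    yc = y_perm - y_perm.mean(axis=1, keepdims=True)
    tss = np.sum(yc * yc, axis=1)
    proj = yc @ Q
    ess = np.sum(proj * proj, axis=1)
    rss = np.maximum(tss - ess, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ess / 2.0) / (rss / df_resid)
    f[~np.isfinite(f)] = np.inf
    return f


def rhythmicity_test(signal, time_h, period_h: float = 24.0, n_perm: int = 1000,
                     seed: Optional[int] = None) -> dict:
    """Zero-amplitude rhythmicity test with a permutation companion.

    Returns ``p_parametric`` (F-test), ``p_permutation`` (time-label
    permutations with the add-one correction (b+1)/(n_perm+1)), and the
    observed F statistic.
    """
    y, t = _as_arrays(signal, time_h)
    if y.size < 8:
        raise ValueError("rhythmicity test needs at least 8 observations")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is small; permutation p is coarse")
    omega = 2.0 * math.pi / period_h
    X = np.column_stack([np.cos(omega * t), np.sin(omega * t)])
    Xc = X - X.mean(axis=0)
    Q, _ = np.linalg.qr(Xc)
    df_resid = y.size - 3
    f_obs = float(_f_stats_null(y[None, :], Q, df_resid)[0])
    p_par = float(stats.f.sf(f_obs, 2, df_resid)) if np.isfinite(f_obs) else 0.0

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, y.size))
    for i in range(n_perm):
        perms[i] = y[rng.permutation(y.size)]
    f_null = _f_stats_null(perms, Q, df_resid)
    b = int(np.sum(f_null >= f_obs))
    p_perm = (b + 1) / (n_perm + 1)
    return {"F": f_obs, "p_parametric": p_par, "p_permutation": p_perm}
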