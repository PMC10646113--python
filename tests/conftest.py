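import numpy as np
import pytest

from skeletime import LuminescenceSeries, OscillatorEnsembleParams


@pytest.fixture
def det_params():
    """Single noiseless oscillator on its limit cycle, peak at t=0."""
    return OscillatorEnsembleParams.deterministic()


@pytest.fixture
def cosine_series():
    """y = 5 + 3*cos(2*pi*(t-6)/24), hourly over 48 h."""
    t = np.arange(0.0, 48.0 + 1e-9, 1.0)
    y = 5.0 + 3.0 * np.cos(2.0 * np.pi * (t - 6.0) / 24.0)
    return LuminescenceSeries(t, y, "cosine")


def brute_force_bh(pvals, alpha=0.05):
    """Step-up BH oracle: adjusted q-values by the direct definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


def grid_damped_cosinor_rss(t, y, period_grid, damping_grid):
    """Brute-force damped-cosinor RSS: linear solve at each (period, d)."""
    best = np.inf
    for T in period_grid:
        w = 2.0 * np.pi / T
        for d in damping_grid:
            env = np.exp(-d * t)
            X = np.column_stack([np.ones_like(t), env * np.cos(w * t), env * np.sin(w * t)])
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            best = min(best, rss)
    return best
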