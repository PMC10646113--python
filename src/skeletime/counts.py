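"""Synthetic rhythmic RNA count matrices with ground-truth labels.

Emulates a circadian bulk RNAseq design: samples every 4 h over two full
cycles (0-48 h), negative-binomial counts, multiplicative library-size
factors, a rhythmic gene fraction with log2 cosine profiles, and a subset
of "early response" genes that acquire a step fold change from the second
timepoint onward (the T0-vs-T4 differential design).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["RhythmicCountExperiment", "simulate_count_timeseries"]


@dataclass
class RhythmicCountExperiment:
    """Genes x samples counts with truth labels and the sample sheet."""

    counts: pd.DataFrame          # genes x samples, nonnegative ints
    sample_sheet: pd.DataFrame    # sample_id, time_h, replicate
    truth: pd.DataFrame           # per-gene truth labels
    dispersion: float
    lib_factors: np.ndarray

    @property
    def sample_time_h(self) -> np.ndarray:
        return self.sample_sheet["time_h"].to_numpy(dtype=float)

    @property
    def sample_replicate(self) -> np.ndarray:
        return self.sample_sheet["replicate"].to_numpy()

    def write_tsvs(self, out_dir: str | Path, prefix: str = "counts") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(out / f"{prefix}_matrix.tsv", sep="\t")
        self.truth.to_csv(out / f"{prefix}_truth.tsv", sep="\t")
        self.sample_sheet.to_csv(out / f"{prefix}_samples.tsv", sep="\t", index=False)


def simulate_count_timeseries(
    g_genes: int = 1000,
    frac_rhythmic: float = 0.2,
    times_h: Sequence[float] | None = None,
    n_reps: int = 1,
    nb_dispersion: float = 0.1,
    amplitude_log2: float = 1.0,
    frac_responsive: float = 0.05,
    response_log2fc: float = 2.0,
    mean_log2_range: tuple[float, float] = (5.0, 9.0),
    lib_size_range: tuple[float, float] = (0.7, 1.3),
    period_h: float = 24.0,
    seed: int = 0,
) -> RhythmicCountExperiment:
    """Draw a rhythmic negative-binomial count experiment with truth.

    Rhythmic genes follow ``log2 mu(t) = m_g + a_g * cos(2*pi*(t - theta_g)
    / period)``; genes flagged ``responsive_T4`` additionally gain
    ``true_log2FC`` from the second timepoint (t >= 4 h) onward.  Counts
    are negative binomial with variance ``mu + dispersion * mu^2`` and
    per-sample library-size factors.
    """
    if g_genes < 1:
        raise ValueError("g_genes must be >= 1")
    if not (0.0 <= frac_rhythmic <= 1.0):
        raise ValueError("frac_rhythmic must be in [0, 1]")
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    if times_h is None:
        times_h = np.arange(0.0, 48.0 + 1e-9, 4.0)  # 13 timepoints, two cycles
    times_h = np.asarray(list(times_h), dtype=float)

    rng = np.random.default_rng(seed)
    n_rhythmic = int(round(frac_rhythmic * g_genes))
    rhythmic = np.zeros(g_genes, dtype=bool)
    rhythmic[rng.choice(g_genes, size=n_rhythmic, replace=False)] = True
    amp = np.where(rhythmic, amplitude_log2, 0.0)
    acro = rng.uniform(0.0, period_h, size=g_genes)
    base = rng.uniform(*mean_log2_range, size=g_genes)
    responsive = rng.random(g_genes) < frac_responsive
    fc = np.where(responsive, response_log2fc * rng.choice([-1.0, 1.0], size=g_genes), 0.0)

    sample_ids, sample_times, sample_reps = [], [], []
    for t in times_h:
        for r in range(1, n_reps + 1):
            sample_ids.append(f"T{int(round(t)):02d}_R{r}")
            sample_times.append(t)
            sample_reps.append(r)
    sample_times = np.asarray(sample_times)
    n_samples = len(sample_ids)
    lib = rng.uniform(*lib_size_range, size=n_samples)

    phase = np.cos(2.0 * np.pi * (sample_times[None, :] - acro[:, None]) / period_h)
    log2_mu = base[:, None] + amp[:, None] * phase
    log2_mu = log2_mu + np.where(sample_times[None, :] >= 4.0, fc[:, None], 0.0)
    mu = (2.0 ** log2_mu) * lib[None, :]

    if nb_dispersion > 0:
        size = 1.0 / nb_dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mu)

    gene_ids = [f"gene_{i:05d}" for i in range(g_genes)]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    counts_df.index.name = "gene_id"
    truth = pd.DataFrame(
        {
            "rhythmic": rhythmic,
            "amplitude_log2": amp,
            "acrophase_h": acro,
            "mesor_log2": base,
            "responsive_T4": responsive,
            "true_log2FC": fc,
        },
        index=gene_ids,
    )
    truth.index.name = "gene_id"
    sheet = pd.DataFrame(
        {"sample_id": sample_ids, "time_h": sample_times, "replicate": sample_reps}
    )
    return RhythmicCountExperiment(counts_df, sheet, truth, nb_dispersion, lib)
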