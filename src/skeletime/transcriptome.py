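"""Rhythmic-gene detection, differential response and phase projection.

The count-matrix pipeline: strict minimum-count filtering, log2
counts-per-million normalization, per-gene cosinor rhythmicity with two
reporting tiers (raw p < 0.05 and Benjamini-Hochberg q < 0.05), a Welch
T0-vs-T4-style differential response test, and projection of query samples
onto a circadian reference time course by z-scored correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cosinor import Cosinor, rhythmicity_test

__all__ = [
    "filter_min_counts",
    "normalize_counts",
    "detect_rhythmic_genes",
    "differential_response",
    "project_sample_phase",
    "PhaseProjection",
]


def filter_min_counts(
    counts: pd.DataFrame,
    threshold: int = 50,
    sample_sheet: Optional[pd.DataFrame] = None,
    convention: str = "per_sample",
) -> pd.DataFrame:
    """Keep genes exceeding ``threshold`` counts in at least one timepoint.

    "Exceeding" is strict (a gene whose best timepoint equals the
    threshold is removed).  ``per_sample`` checks the per-sample maximum;
    ``mean_over_replicates`` first averages replicates within a timepoint
    (the two readings coincide for one-replicate designs).
    """
    if convention not in ("per_sample", "mean_over_replicates"):
        raise ValueError("convention must be 'per_sample' or 'mean_over_replicates'")
    if convention == "mean_over_replicates":
        if sample_sheet is None:
            raise ValueError("mean_over_replicates needs a sample sheet")
        times = sample_sheet.set_index("sample_id")["time_h"]
        grouped = counts.T.groupby(counts.columns.map(times)).mean().T
        best = grouped.max(axis=1)
    else:
        best = counts.max(axis=1)
    kept = counts.loc[best > threshold]
    if kept.empty:
        raise ValueError(
            f"no gene exceeds {threshold} counts in any timepoint; "
            "consider lowering the threshold"
        )
    return kept


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) normalization (library-size scaling to counts/million)."""
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if not zero.empty:
        raise ValueError(f"zero library size for sample {zero.index[0]!r}")
    cpm = counts / lib * 1e6
    return np.log2(cpm + 1.0)


def detect_rhythmic_genes(
    normalized: pd.DataFrame,
    sample_time_h: Sequence[float],
    period_h: float = 24.0,
    n_perm: int = 0,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene rhythmicity with BH adjustment and two reporting tiers.

    ``tier1`` flags raw p < alpha (the integrated-p style cut-off),
    ``tier2`` flags BH q < alpha; tier2 is a subset of tier1.  With
    ``n_perm > 0`` the raw p is the permutation p (per-gene independent
    time-label permutations), otherwise the parametric zero-amplitude
    F-test p.  Also reports the fitted log2 amplitude, acrophase and mesor.
    """
    t = np.asarray(list(sample_time_h), dtype=float)
    if t.size != normalized.shape[1]:
        raise ValueError("sample_time_h length must match the sample columns")
    if np.unique(t).size < 8:
        raise ValueError("rhythmic-gene detection needs >= 8 timepoints")
    rng = np.random.default_rng(seed)
    rows = []
    for gene, y in normalized.iterrows():
        yv = y.to_numpy(dtype=float)
        fit = Cosinor(yv, t, period_h=period_h).fit()
        if n_perm > 0:
            res = rhythmicity_test(yv, t, period_h=period_h, n_perm=n_perm,
                                   seed=int(rng.integers(2**31)))
            p = res["p_permutation"]
        else:
            p = fit.p_zero_amplitude
        rows.append(
            {
                "gene_id": gene,
                "p_raw": p,
                "amplitude_log2": fit.amplitude,
                "acrophase_h": fit.acrophase_h,
                "mesor_log2": fit.mesor,
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    out["q_bh"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    out["tier1"] = out["p_raw"] < alpha
    out["tier2"] = out["q_bh"] < alpha
    return out


def differential_response(
    normalized: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_cut: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch test per gene between two sample groups on log2 values.

    ``log2fc`` is mean(group_a) - mean(group_b); direction ``up`` means
    q < alpha and log2fc >= fc_cut, ``down`` the mirror image, else ``ns``.
    """
    a = normalized[list(group_a)].to_numpy(dtype=float)
    b = normalized[list(group_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 replicates for a variance estimate")
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    tt = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)
    q = multipletests(p, method="fdr_bh")[1]
    direction = np.where(
        (q < alpha) & (log2fc >= fc_cut), "up",
        np.where((q < alpha) & (log2fc <= -fc_cut), "down", "ns"),
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p_raw": p, "q_bh": q, "direction": direction},
        index=normalized.index,
    )


@dataclass
class PhaseProjection:
    """Assignment of a query sample to the best-matching reference time."""

    query_sample_id: str
    assigned_time_h: float
    correlation_profile: pd.Series  # Pearson r per reference timepoint


def project_sample_phase(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    reference_time_h: Sequence[float],
    gene_set: Optional[Sequence[str]] = None,
) -> list[PhaseProjection]:
    """Project query samples onto a circadian reference time course.

    Each gene is z-scored across reference timepoints; query samples are
    z-scored with the reference per-gene mean/SD, and each query is
    assigned the reference timepoint maximizing the Pearson correlation
    between z-vectors.
    """
    if gene_set is not None:
        genes = [g for g in gene_set if g in query.index and g in reference.index]
    else:
        genes = [g for g in query.index if g in reference.index]
    if len(genes) < 10:
        raise ValueError(
            f"only {len(genes)} shared genes; >= 10 required for a stable projection"
        )
    ref = reference.loc[genes].to_numpy(dtype=float)
    qry = query.loc[genes].to_numpy(dtype=float)
    times = np.asarray(list(reference_time_h), dtype=float)
    if times.size != ref.shape[1]:
        raise ValueError("reference_time_h length must match reference columns")
    mu = ref.mean(axis=1, keepdims=True)
    sd = ref.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    if keep.sum() < 10:
        raise ValueError("fewer than 10 informative (non-constant) shared genes")
    ref_z = (ref[keep] - mu[keep]) / sd[keep]
    qry_z = (qry[keep] - mu[keep]) / sd[keep]
    out = []
    for j, sample in enumerate(query.columns):
        profile = np.array(
            [stats.pearsonr(qry_z[:, j], ref_z[:, k]).statistic
             for k in range(times.size)]
        )
        series = pd.Series(profile, index=times)
        out.append(
            PhaseProjection(str(sample), float(times[int(np.argmax(profile))]), series)
        )
    return out
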