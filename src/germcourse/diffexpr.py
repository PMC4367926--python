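"""Consecutive-interval differential expression.

A gene's expression level at a time point is the mean of its replicate
Normalized Ratios there (``mRNA_i_t_j``).  The differential expression
profile is the sequence of consecutive-time-point ratios
``mRNA_i_t_{j+1} / mRNA_i_t_j`` (12 entries for the 13-point design),
and an interval call is made when a two-sided t-test for equality of
the replicate means is significant (p < alpha, default 0.05) *and* the
ratio exceeds the fold threshold (strictly >2 or <1/2 by default — the
2-fold bar screens significant but biologically irrelevant changes).

The t-test is the pooled-variance Student's test by default; Welch's
variant is available.  No multiple-testing correction is applied by
default; Benjamini-Hochberg adjustment is opt-in and, when enabled,
replaces the raw p-values in the calling rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datamodel import (
    ExperimentDesign,
    IntervalCallSet,
    NormalizedRatioMatrix,
    interval_label,
)

__all__ = [
    "timepoint_levels",
    "differential_profiles",
    "call_intervals",
    "DifferentialProfiles",
    "ConsecutiveIntervalDE",
]


def _replicate_stats(
    nrm: NormalizedRatioMatrix, design: ExperimentDesign, rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per (gene, time point): mean, n-1 variance and count of unmasked ratios."""
    t_max = design.n_timepoints
    n_g = rows.size
    mean = np.full((n_g, t_max), np.nan)
    var = np.full((n_g, t_max), np.nan)
    count = np.zeros((n_g, t_max), dtype=int)
    for t in range(1, t_max + 1):
        cols = design.columns_at(t)
        vals = nrm.values[np.ix_(rows, cols)]
        miss = nrm.mask[np.ix_(rows, cols)]
        n = (~miss).sum(axis=1)
        count[:, t - 1] = n
        s = np.where(miss, 0.0, vals).sum(axis=1)
        m = np.where(n >= 1, s / np.maximum(n, 1), np.nan)
        mean[:, t - 1] = m
        dev = np.where(miss, 0.0, vals - np.where(n >= 1, m, 0.0)[:, None])
        ssd = (dev * dev).sum(axis=1)
        var[:, t - 1] = np.where(n >= 2, ssd / np.maximum(n - 1, 1), np.nan)
    return mean, var, count


def timepoint_levels(
    nrm: NormalizedRatioMatrix,
    design: ExperimentDesign | None = None,
    kept_genes=None,
) -> pd.DataFrame:
    """Gene expression levels: mean Normalized Ratio per time point.

    Time points with no surviving replicate get NaN.  Rows are
    restricted to ``kept_genes`` (the highly expressed set) if given.
    """
    design = design if design is not None else nrm.design
    rows = nrm.gene_index(kept_genes)
    mean, _, _ = _replicate_stats(nrm, design, rows)
    genes = [nrm.gene_ids[i] for i in rows]
    return pd.DataFrame(
        mean,
        index=pd.Index(genes, name="gene_id"),
        columns=[f"t{j}" for j in range(1, design.n_timepoints + 1)],
    )


@dataclass
class DifferentialProfiles:
    """Ratios and p-values of every consecutive interval, gene x (T-1)."""

    ratios: pd.DataFrame
    p_values: pd.DataFrame
    levels: pd.DataFrame
    n_replicates: pd.DataFrame

    @property
    def interval_labels(self) -> list[str]:
        return list(self.ratios.columns)


def _pairwise_t(mean, var, count, welch: bool) -> np.ndarray:
    """Vectorized two-sided t-test p-values between consecutive time points."""
    m1, m2 = mean[:, :-1], mean[:, 1:]
    v1, v2 = var[:, :-1], var[:, 1:]
    n1, n2 = count[:, :-1].astype(float), count[:, 1:].astype(float)
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se2 = sp2 * (1 / n1 + 1 / n2)
        t = (m2 - m1) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate: both sides zero variance -> p = 1 if means equal else 0
    degenerate = valid & (se2 == 0)
    p = np.where(degenerate, np.where(m1 == m2, 1.0, 0.0), p)
    p = np.where(valid, p, np.nan)
    return p


def differential_profiles(
    nrm: NormalizedRatioMatrix,
    design: ExperimentDesign | None = None,
    kept_genes=None,
    welch: bool = False,
) -> DifferentialProfiles:
    """Consecutive-interval ratios and t-test p-values for each gene.

    A ratio is defined where both endpoint levels exist and the
    denominator is positive; a p-value where both sides retain at least
    two replicates.
    """
    design = design if design is not None else nrm.design
    rows = nrm.gene_index(kept_genes)
    mean, var, count = _replicate_stats(nrm, design, rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(mean[:, :-1] > 0, mean[:, 1:] / mean[:, :-1], np.nan)
    p = _pairwise_t(mean, var, count, welch)
    genes = pd.Index([nrm.gene_ids[i] for i in rows], name="gene_id")
    cols = [interval_label(j) for j in range(1, design.n_timepoints)]
    level_cols = [f"t{j}" for j in range(1, design.n_timepoints + 1)]
    return DifferentialProfiles(
        ratios=pd.DataFrame(ratios, index=genes, columns=cols),
        p_values=pd.DataFrame(p, index=genes, columns=cols),
        levels=pd.DataFrame(mean, index=genes, columns=level_cols),
        n_replicates=pd.DataFrame(count, index=genes, columns=level_cols),
    )


def call_intervals(
    profiles: DifferentialProfiles,
    alpha: float = 0.05,
    fold_threshold: float = 2.0,
    bh: bool = False,
) -> IntervalCallSet:
    """Enhanced/diminished calls: p < alpha and ratio strictly beyond the fold bar.

    With ``bh=True`` the p-values are Benjamini-Hochberg adjusted over
    all defined tests before thresholding.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    p = profiles.p_values.to_numpy().copy()
    if bh:
        defined = np.isfinite(p)
        if defined.any():
            p[defined] = stats.false_discovery_control(p[defined], method="bh")
    r = profiles.ratios.to_numpy()
    raw_p = profiles.p_values.to_numpy()
    with np.errstate(invalid="ignore"):
        significant = np.isfinite(p) & (p < alpha) & np.isfinite(r)
        enhanced = significant & (r > fold_threshold)
        diminished = significant & (r < 1.0 / fold_threshold)
    rows = []
    genes = profiles.ratios.index
    for g_idx, j_idx in zip(*np.nonzero(enhanced | diminished)):
        rows.append(
            {
                "gene_id": genes[g_idx],
                "interval": j_idx + 1,
                "direction": "enhanced" if enhanced[g_idx, j_idx] else "diminished",
                "fold": r[g_idx, j_idx],
                "p_value": raw_p[g_idx, j_idx],
            }
        )
    frame = pd.DataFrame(rows, columns=IntervalCallSet.COLUMNS)
    return IntervalCallSet(frame)


class ConsecutiveIntervalDE(BaseEstimator):
    """Estimator for interval-wise differential expression calls.

    Parameters
    ----------
    alpha : float, default=0.05
        Significance threshold of the two-sided t-test.
    fold_threshold : float, default=2.0
        Strict fold bar: enhanced needs ratio > fold_threshold,
        diminished ratio < 1/fold_threshold.
    welch : bool, default=False
        Use Welch's t-test instead of the pooled-variance Student test.
    bh : bool, default=False
        Benjamini-Hochberg adjust p-values before calling.

    Attributes
    ----------
    profiles_ : DifferentialProfiles
    calls_ : IntervalCallSet
    """

    def __init__(
        self,
        alpha: float = 0.05,
        fold_threshold: float = 2.0,
        welch: bool = False,
        bh: bool = False,
    ) -> None:
        self.alpha = alpha
        self.fold_threshold = fold_threshold
        self.welch = welch
        self.bh = bh

    def fit(self, X: NormalizedRatioMatrix, y=None, kept_genes=None) -> "ConsecutiveIntervalDE":
        if not isinstance(X, NormalizedRatioMatrix):
            raise TypeError("ConsecutiveIntervalDE expects a NormalizedRatioMatrix")
        self.profiles_ = differential_profiles(X, kept_genes=kept_genes, welch=self.welch)
        self.calls_ = call_intervals(
            self.profiles_, self.alpha, self.fold_threshold, self.bh
        )
        return self

    def fit_predict(self, X: NormalizedRatioMatrix, y=None, kept_genes=None) -> IntervalCallSet:
        return self.fit(X, kept_genes=kept_genes).calls_
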