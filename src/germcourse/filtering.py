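"""Selection of highly expressed genes.

Profiles are ranked by their overall expression level — the median of
all sample-channel (Cy3) signals across every replicate and time point
— and profiles below the first quartile of those levels are filtered
out.  A profile with a low overall level but a clear expression peak is
rescued: if its highest per-time-point median sample signal reaches the
quartile threshold and stands at least ``rescue_ratio`` times above its
own overall level, it re-enters the highly expressed set.  The rescue
rule is a deterministic stand-in for what is otherwise a manual
inspection step; ``rescue_ratio`` is a free parameter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datamodel import SignalMatrix

logger = logging.getLogger(__name__)

__all__ = ["overall_expression_levels", "select_highly_expressed", "HighExpressionFilter"]


def overall_expression_levels(matrix: SignalMatrix) -> pd.Series:
    """Median of each gene's unmasked sample-channel signals over all arrays.

    Genes with no unmasked signal get NaN and are excluded downstream.
    """
    levels = np.full(matrix.n_genes, np.nan)
    for g in range(matrix.n_genes):
        row = matrix.sample_signal[g, ~matrix.mask[g]]
        if row.size:
            levels[g] = np.median(row)
    return pd.Series(levels, index=pd.Index(matrix.gene_ids, name="gene_id"), name="overall_level")


def _timepoint_medians(matrix: SignalMatrix) -> np.ndarray:
    """Per-gene, per-time-point median of unmasked sample signals."""
    t_max = matrix.design.n_timepoints
    out = np.full((matrix.n_genes, t_max), np.nan)
    for t in range(1, t_max + 1):
        cols = matrix.design.columns_at(t)
        for g in range(matrix.n_genes):
            vals = matrix.sample_signal[g, cols[~matrix.mask[g, cols]]]
            if vals.size:
                out[g, t - 1] = np.median(vals)
    return out


def select_highly_expressed(
    levels: pd.Series,
    matrix: SignalMatrix,
    rescue_ratio: float = 4.0,
) -> pd.DataFrame:
    """Flag genes as highly expressed by the first-quartile rule + rescue.

    Returns a frame indexed by gene_id with columns ``overall_level``,
    ``highly_expressed``, ``rescued`` and attribute-like metadata:
    ``result.attrs["threshold"]`` carries the computed quartile cutoff.
    """
    if levels.empty:
        raise ValueError("no expression levels given")
    if rescue_ratio <= 0:
        raise ValueError("rescue_ratio must be > 0")
    defined = levels.dropna()
    threshold = float(np.quantile(defined.to_numpy(), 0.25))
    logger.info("highly-expressed threshold (first quartile of medians): %g", threshold)

    peak = _timepoint_medians(matrix)
    peak_max = np.where(np.all(np.isnan(peak), axis=1), np.nan, np.nanmax(peak, axis=1))
    peak_max = pd.Series(peak_max, index=levels.index)

    kept = levels >= threshold
    rescue = (~kept) & levels.notna() & (peak_max >= threshold) & (peak_max >= rescue_ratio * levels)
    out = pd.DataFrame(
        {
            "overall_level": levels,
            "highly_expressed": (kept | rescue) & levels.notna(),
            "rescued": rescue.fillna(False),
        }
    )
    out.attrs["threshold"] = threshold
    return out


class HighExpressionFilter(BaseEstimator):
    """Selector for highly expressed genes.

    Parameters
    ----------
    rescue_ratio : float, default=4.0
        Peak-over-overall-level factor required to rescue a
        below-threshold profile with a significant peak.

    Attributes
    ----------
    threshold_ : float
        The first-quartile cutoff of the per-gene overall levels.
    flags_ : DataFrame
        Per-gene overall level plus highly_expressed / rescued flags.
    kept_genes_ : list of str
    """

    def __init__(self, rescue_ratio: float = 4.0) -> None:
        self.rescue_ratio = rescue_ratio

    def fit(self, X: SignalMatrix, y=None) -> "HighExpressionFilter":
        if not isinstance(X, SignalMatrix):
            raise TypeError("HighExpressionFilter expects a SignalMatrix")
        levels = overall_expression_levels(X)
        flags = select_highly_expressed(levels, X, self.rescue_ratio)
        self.threshold_ = flags.attrs["threshold"]
        self.flags_ = flags
        self.kept_genes_ = list(flags.index[flags["highly_expressed"]])
        return self

    def get_support(self) -> np.ndarray:
        return self.flags_["highly_expressed"].to_numpy()
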