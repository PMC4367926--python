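"""Common-reference array normalization.

The arrays all share a pooled-RNA reference in the Cy5 channel, so the
per-array distributions of ``Log2Ratio = log2(Cy3 sample / Cy5
reference)`` are expected to scatter around a common location with
similar spread.  Normalization therefore (1) computes log-ratios,
(2) centers and scales every array so all per-array medians and median
absolute deviations coincide, (3) trims the extreme 0.02 quantile of
each tail per array, and (4) exponentiates back to the ratio scale
("Normalized Ratios").

The MAD used here is the raw median absolute deviation, without the
1.4826 normal-consistency factor — the factor would cancel in the
equalization anyway.  Quantiles use the linear-interpolation convention
(numpy's default) so results are bit-reproducible.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import LogRatioMatrix, NormalizedRatioMatrix, SignalMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "compute_log_ratios",
    "center_scale_arrays",
    "trim_array_tails",
    "exponentiate_ratios",
    "ArrayNormalizer",
]


def compute_log_ratios(matrix: SignalMatrix) -> LogRatioMatrix:
    """Per-cell ``log2(sample / reference)``.

    Cells where either channel is masked or not strictly positive become
    masked; their count is logged.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2(matrix.sample_signal) - np.log2(matrix.reference_signal)
    degenerate = (
        ~matrix.mask
        & ((matrix.sample_signal <= 0) | (matrix.reference_signal <= 0))
    )
    if degenerate.any():
        logger.warning("masked %d non-positive signal cells", int(degenerate.sum()))
    mask = matrix.mask | degenerate
    values = np.where(mask, 0.0, values)
    return LogRatioMatrix(matrix.gene_ids, matrix.design, values, mask)


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def center_scale_arrays(lrm: LogRatioMatrix) -> LogRatioMatrix:
    """Equalize every array's median and MAD.

    Each array is mapped by ``x -> (x - median_a) / MAD_a * MAD_target +
    median_target`` with the targets taken as the median of the
    per-array medians and of the per-array MADs.  An array whose MAD is
    zero cannot be scale-equalized and raises a ValueError naming it.
    """
    values = lrm.values.copy()
    medians = np.empty(values.shape[1])
    mads = np.empty(values.shape[1])
    for a, array_id in enumerate(lrm.design.array_ids):
        col = values[~lrm.mask[:, a], a]
        if col.size < 3:
            raise ValueError(f"array {array_id!r} has fewer than 3 unmasked values")
        medians[a] = np.median(col)
        mads[a] = _mad(col)
        if mads[a] == 0:
            raise ValueError(f"array {array_id!r} has zero MAD; cannot scale-equalize")
    median_target = float(np.median(medians))
    mad_target = float(np.median(mads))
    for a in range(values.shape[1]):
        unmasked = ~lrm.mask[:, a]
        values[unmasked, a] = (
            (values[unmasked, a] - medians[a]) / mads[a] * mad_target + median_target
        )
    return LogRatioMatrix(lrm.gene_ids, lrm.design, values, lrm.mask.copy())


def trim_array_tails(lrm: LogRatioMatrix, tail: float = 0.02) -> LogRatioMatrix:
    """Mask each array's extreme log-ratios beyond the tail quantiles.

    Per array, values strictly below the ``tail`` quantile or strictly
    above the ``1 - tail`` quantile of its unmasked values are masked.
    Masking is one-shot: quantiles are computed once on the input.
    """
    if not 0 <= tail < 0.5:
        raise ValueError("tail must be in [0, 0.5)")
    mask = lrm.mask.copy()
    if tail > 0:
        for a in range(lrm.values.shape[1]):
            unmasked = ~lrm.mask[:, a]
            col = lrm.values[unmasked, a]
            if col.size == 0:
                continue
            lo, hi = np.quantile(col, [tail, 1.0 - tail])
            extreme = unmasked & ((lrm.values[:, a] < lo) | (lrm.values[:, a] > hi))
            mask[:, a] |= extreme
    return LogRatioMatrix(lrm.gene_ids, lrm.design, lrm.values.copy(), mask)


def exponentiate_ratios(lrm: LogRatioMatrix) -> NormalizedRatioMatrix:
    """Return ``2**Log2Ratio`` — the Normalized Ratios; masks carry over."""
    values = np.where(lrm.mask, 1.0, 2.0 ** lrm.values)
    return NormalizedRatioMatrix(lrm.gene_ids, lrm.design, values, lrm.mask.copy())


class ArrayNormalizer(TransformerMixin, BaseEstimator):
    """Transformer running the full normalization chain on a SignalMatrix.

    Parameters
    ----------
    tail : float, default=0.02
        Per-tail trimming quantile; 0 disables trimming.
    center_scale : bool, default=True
        Whether to equalize per-array medians/MADs.  Disable for data
        known to carry no array-level distortion (e.g. a distortion-free
        simulation, where per-array MADs may legitimately be 0).

    Attributes
    ----------
    array_medians_, array_mads_ : ndarray
        Pre-normalization per-array statistics of the log-ratios.
    median_target_, mad_target_ : float
        The equalization targets (only when ``center_scale``).
    n_trimmed_ : int
        Number of cells masked by tail trimming.
    """

    def __init__(self, tail: float = 0.02, center_scale: bool = True) -> None:
        self.tail = tail
        self.center_scale = center_scale

    def fit(self, X: SignalMatrix, y=None) -> "ArrayNormalizer":
        if not isinstance(X, SignalMatrix):
            raise TypeError("ArrayNormalizer expects a SignalMatrix")
        if not 0 <= self.tail < 0.5:
            raise ValueError("tail must be in [0, 0.5)")
        lrm = compute_log_ratios(X)
        self.array_medians_ = lrm.array_medians()
        self.array_mads_ = lrm.array_mads()
        if self.center_scale:
            self.median_target_ = float(np.median(self.array_medians_))
            self.mad_target_ = float(np.median(self.array_mads_))
        return self

    def transform(self, X: SignalMatrix) -> NormalizedRatioMatrix:
        if not hasattr(self, "array_medians_"):
            raise RuntimeError("ArrayNormalizer is not fitted")
        lrm = compute_log_ratios(X)
        if self.center_scale:
            lrm = center_scale_arrays(lrm)
        before = int(lrm.mask.sum())
        lrm = trim_array_tails(lrm, self.tail)
        self.n_trimmed_ = int(lrm.mask.sum()) - before
        return exponentiate_ratios(lrm)
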