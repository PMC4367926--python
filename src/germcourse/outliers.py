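"""Replicate outlier rejection: Dixon's Q-test and Peirce's criterion.

Per gene and time point, the replicate Normalized Ratios are screened
for outliers.  Small replicate sets (3-9 values) use Dixon's Q-test in
its classical single-outlier r10 form; larger sets (>= 10) use Peirce's
criterion solved by Gould's iterative algorithm, which can reject more
than one value.  Whatever happens, at least two replicates are always
kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import ExperimentDesign, NormalizedRatioMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "OutlierDecision",
    "dixon_q_test",
    "peirce_criterion",
    "filter_replicate_sets",
    "ReplicateOutlierFilter",
    "DIXON_CRITICAL",
]

# Two-tailed critical values for Dixon's r10 ("Q") statistic,
# n = 3..10, from Rorabacher, Anal. Chem. 63 (1991) 139-146.
DIXON_CRITICAL: dict[float, dict[int, float]] = {
    0.90: {3: 0.941, 4: 0.765, 5: 0.642, 6: 0.560, 7: 0.507, 8: 0.468, 9: 0.437, 10: 0.412},
    0.95: {3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493, 10: 0.466},
    0.99: {3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680, 8: 0.634, 9: 0.598, 10: 0.568},
}


@dataclass
class OutlierDecision:
    """Outcome of screening one replicate set.

    ``kept`` and ``rejected`` partition the input multiset; ``statistic``
    is the Dixon Q value or Peirce's maximum allowable deviation ratio x
    (None when no test ran).
    """

    kept: list[float]
    rejected: list[float]
    method: str  # "q-test" | "peirce" | "none"
    statistic: float | None = None


def dixon_q_test(values, confidence: float = 0.95) -> OutlierDecision:
    """Screen the single most extreme value with Dixon's Q-test.

    Q = gap between the suspect value and its nearest neighbour, over
    the range.  The suspect (at whichever end shows the larger gap) is
    rejected iff Q exceeds the two-tailed critical value for the given
    confidence level.  At most one value is rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("too few replicates for the Q-test (need >= 3)")
    if x.size > 10:
        raise ValueError("Q-test supports at most 10 values; use peirce_criterion")
    if not np.all(np.isfinite(x)):
        raise ValueError("Q-test input must be finite")
    try:
        table = DIXON_CRITICAL[round(confidence, 2)]
    except KeyError:
        raise ValueError(f"no Q-test table for confidence {confidence}") from None

    order = np.argsort(x, kind="stable")
    s = x[order]
    rng = s[-1] - s[0]
    if rng == 0:
        return OutlierDecision(list(x), [], "q-test", 0.0)
    gap_low = s[1] - s[0]
    gap_high = s[-1] - s[-2]
    if gap_high >= gap_low:
        q = gap_high / rng
        suspect_pos = order[-1]
    else:
        q = gap_low / rng
        suspect_pos = order[0]
    q = float(q)
    if q > table[x.size]:
        keep = [float(v) for i, v in enumerate(x) if i != suspect_pos]
        return OutlierDecision(keep, [float(x[suspect_pos])], "q-test", q)
    return OutlierDecision([float(v) for v in x], [], "q-test", q)


def _gould_x2(n: int, k: int, m: int = 1, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Squared maximum allowable deviation ratio from Gould's fixed point.

    Solves Peirce's system for n observations, k suspect points and m
    unknown quantities (m = 1: the mean) by iterating between
    R = exp((x^2-1)/2) erfc(x/sqrt 2) and
    x^2 = 1 + (n-m-k)/k (1 - lambda^2), lambda^(n-k) = Q^n / R^k.
    Returns 0.0 when the system admits no positive solution (reject-all
    regime); raises on non-convergence.
    """
    if k >= n - m:
        return 0.0
    ln_qn = k * math.log(k) + (n - k) * math.log(n - k) - n * math.log(n)
    r_new, r_old = 1.0, 0.0
    x2 = 1.0
    for _ in range(max_iter):
        if abs(r_new - r_old) <= tol:
            return x2
        lam = math.exp((ln_qn - k * math.log(r_new)) / (n - k))
        x2 = 1.0 + (n - m - k) / k * (1.0 - lam * lam)
        if x2 < 0:
            return 0.0
        r_old = r_new
        x = math.sqrt(x2)
        r_new = math.exp((x2 - 1.0) / 2.0) * math.erfc(x / math.sqrt(2.0))
    raise RuntimeError(
        f"Peirce fixed point did not converge (n={n}, k={k}, last x^2={x2})"
    )


def peirce_criterion(values) -> OutlierDecision:
    """Reject outliers by Peirce's criterion (Gould's algorithm).

    Deviations are measured from the sample mean in units of the n-1
    sample standard deviation.  Starting from one suspect point, the
    allowable deviation ratio x is recomputed for k = 1, 2, ... and all
    values with ``|value - mean| > x * s`` are rejected, increasing k
    while at least k points are rejected.  Rejection is capped so at
    least two values always remain.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("too few replicates for Peirce's criterion (need >= 3)")
    if not np.all(np.isfinite(x)):
        raise ValueError("Peirce input must be finite")
    mean = float(x.mean())
    s = float(x.std(ddof=1))
    if s == 0:
        return OutlierDecision([float(v) for v in x], [], "peirce", None)
    dev = np.abs(x - mean)

    rejected = np.zeros(n, dtype=bool)
    ratio = None
    for k in range(1, n - 1):  # keep at least 2
        x2 = _gould_x2(n, k)
        if x2 <= 0:
            break
        ratio = math.sqrt(x2)
        candidate = dev > ratio * s
        if candidate.sum() > n - 2:
            # cap: reject only the n-2 largest deviations
            keep_idx = np.argsort(dev, kind="stable")[:2]
            candidate = np.ones(n, dtype=bool)
            candidate[keep_idx] = False
        if candidate.sum() >= k:
            rejected = candidate
        else:
            break
    return OutlierDecision(
        [float(v) for v in x[~rejected]],
        [float(v) for v in x[rejected]],
        "peirce",
        ratio,
    )


def filter_replicate_sets(
    nrm: NormalizedRatioMatrix,
    design: ExperimentDesign | None = None,
    confidence: float = 0.95,
    dixon_max: int = 9,
) -> NormalizedRatioMatrix:
    """Mask outlying replicate Normalized Ratios per gene and time point.

    Dispatch by replicate count n: n < 3 untouched; 3 <= n <= dixon_max
    Dixon's Q-test; larger sets Peirce's criterion.  Per-method usage
    and rejection counts are logged.  Test failures for a cell leave its
    values untouched.
    """
    design = design if design is not None else nrm.design
    mask = nrm.mask.copy()
    counts = {"q-test": 0, "peirce": 0, "none": 0}
    rejected_cells = 0
    for t in range(1, design.n_timepoints + 1):
        cols = design.columns_at(t)
        for g in range(len(nrm.gene_ids)):
            keep = ~nrm.mask[g, cols]
            reps = nrm.values[g, cols[keep]]
            n = reps.size
            if n < 3:
                counts["none"] += 1
                continue
            try:
                if n <= dixon_max:
                    decision = dixon_q_test(reps, confidence)
                else:
                    decision = peirce_criterion(reps)
            except (ValueError, RuntimeError) as exc:  # keep values on failure
                logger.warning("outlier test failed for gene row %d, t%d: %s", g, t, exc)
                counts["none"] += 1
                continue
            counts[decision.method] += 1
            if decision.rejected:
                rej = set()
                pool = list(decision.rejected)
                for local_i, v in zip(cols[keep], reps):
                    if v in pool:
                        pool.remove(v)
                        rej.add(local_i)
                for c in rej:
                    mask[g, c] = True
                rejected_cells += len(rej)
    logger.info(
        "replicate outlier filter: %d cells rejected (q-test sets: %d, peirce sets: %d, untouched: %d)",
        rejected_cells, counts["q-test"], counts["peirce"], counts["none"],
    )
    out = NormalizedRatioMatrix(nrm.gene_ids, nrm.design, nrm.values.copy(), mask)
    return out


class ReplicateOutlierFilter(TransformerMixin, BaseEstimator):
    """Transformer wrapper over :func:`filter_replicate_sets`.

    Parameters
    ----------
    confidence : {0.90, 0.95, 0.99}, default=0.95
        Two-tailed confidence level of the Q-test.
    dixon_max : int, default=9
        Largest replicate count handled by the Q-test; larger sets go to
        Peirce's criterion.

    Attributes
    ----------
    n_rejected_ : int
        Cells newly masked by the filter.
    """

    def __init__(self, confidence: float = 0.95, dixon_max: int = 9) -> None:
        self.confidence = confidence
        self.dixon_max = dixon_max

    def fit(self, X: NormalizedRatioMatrix, y=None) -> "ReplicateOutlierFilter":
        if not isinstance(X, NormalizedRatioMatrix):
            raise TypeError("ReplicateOutlierFilter expects a NormalizedRatioMatrix")
        if round(self.confidence, 2) not in DIXON_CRITICAL:
            raise ValueError(f"unsupported confidence {self.confidence}")
        return self

    def transform(self, X: NormalizedRatioMatrix) -> NormalizedRatioMatrix:
        self.fit(X)
        out = filter_replicate_sets(X, confidence=self.confidence, dixon_max=self.dixon_max)
        self.n_rejected_ = int(out.mask.sum()) - int(X.mask.sum())
        return out
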