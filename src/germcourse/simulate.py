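"""Synthetic two-channel germination time courses with known ground truth.

The generator emulates the study design: 13 time points (dormant spores,
heat-activated spores, then 30-min sampling up to 5.5 h) with replicate
arrays, a common reference channel mixed from RNA of all time points,
multiplicative log-normal replicate noise, per-array location/scale
distortion of the log-ratios, planted step fold changes at chosen
consecutive intervals, planted replicate outliers, and a decaying
dormant mRNA pool (transcripts stockpiled during sporulation that are
degraded on rehydration).

True interval calls are derived from the true abundance profile by the
same strict >2-fold rule the calling stage uses, so downstream stages
can be scored against an exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ExperimentDesign, SignalMatrix, interval_label, study_design
from .io import write_signal_tables

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_experiment",
    "generate_null_experiment",
    "export_fixture",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment.

    All log-scale parameters are on log2.  ``planted_effects`` are
    ``(gene_id, interval_j, fold)`` step changes: the gene's true
    abundance is multiplied by ``fold`` at every time point after t_j,
    so its true consecutive ratio at interval j equals ``fold`` and is 1
    elsewhere.  ``dormant_pool_decay`` models the stored spore mRNA
    pool: a ``dormant_pool_fraction`` of genes starts elevated by that
    fold at t1 and drops at the t1-t2 rehydration interval.
    """

    n_genes: int = 2000
    design: ExperimentDesign = field(default_factory=study_design)
    baseline_log_mean: float = 10.0
    baseline_log_sd: float = 1.5
    noise_log_sd: float = 0.3
    array_shift_sd: float = 0.2
    array_scale_range: tuple[float, float] = (0.8, 1.25)
    planted_effects: tuple[tuple[str, int, float], ...] = ()
    outlier_fraction: float = 0.0
    outlier_magnitude_log2: float = 4.0
    dormant_pool_decay: float = 4.0
    dormant_pool_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("baseline_log_sd", "noise_log_sd", "array_shift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.array_scale_range
        if not (0 < lo <= hi):
            raise ValueError("array_scale_range must satisfy 0 < lo <= hi")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.dormant_pool_decay < 1:
            raise ValueError("dormant_pool_decay must be >= 1")
        if not 0 <= self.dormant_pool_fraction <= 1:
            raise ValueError("dormant_pool_fraction must be in [0, 1]")
        t = self.design.n_timepoints
        known = set(self.gene_ids())
        for gene_id, j, fold in self.planted_effects:
            if gene_id not in known:
                raise ValueError(f"planted effect on unknown gene {gene_id!r}")
            if not 1 <= j <= t - 1:
                raise ValueError(f"planted effect at unknown interval {j}")
            if fold <= 0:
                raise ValueError("planted fold must be > 0")

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GroundTruth:
    """What the generator actually planted.

    ``true_calls`` holds ``(gene_id, interval_j, direction)`` triples
    derived from ``true_level`` with the strict >2-fold consecutive-ratio
    rule; ``outlier_cells`` holds ``(gene_id, array_id)`` pairs whose
    sample-channel signal was corrupted.
    """

    gene_ids: list[str]
    true_level: np.ndarray  # gene x time point
    true_calls: set[tuple[str, int, str]]
    outlier_cells: set[tuple[str, str]]

    def calls_frame(self) -> pd.DataFrame:
        rows = sorted(self.true_calls)
        return pd.DataFrame(rows, columns=["gene_id", "interval", "direction"])


def _true_calls_from_levels(
    gene_ids: list[str], level: np.ndarray, fold_threshold: float = 2.0
) -> set[tuple[str, int, str]]:
    """Strict >2-fold rule on consecutive true-abundance ratios."""
    calls: set[tuple[str, int, str]] = set()
    ratios = level[:, 1:] / level[:, :-1]
    for g, gene_id in enumerate(gene_ids):
        for j0 in range(ratios.shape[1]):
            r = ratios[g, j0]
            if r > fold_threshold:
                calls.add((gene_id, j0 + 1, "enhanced"))
            elif r < 1.0 / fold_threshold:
                calls.add((gene_id, j0 + 1, "diminished"))
    return calls


def generate_experiment(config: SimulationConfig) -> tuple[SignalMatrix, GroundTruth]:
    """Simulate one two-channel experiment from ``config``.

    The sample channel is true abundance times log-normal replicate
    noise; the reference channel per gene is the mean of its true
    abundance across all time points (the pooled-RNA common reference)
    times its own independent noise.  Per-array distortion is applied on
    the log-ratio scale (shift + scale), and outlier cells get an
    additive +/- ``outlier_magnitude_log2`` hit on the log2 sample
    signal.  The same seed gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design
    gene_ids = config.gene_ids()
    n_g, t = config.n_genes, design.n_timepoints

    log_base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_g)
    level = np.repeat(2.0 ** log_base[:, None], t, axis=1)

    if config.dormant_pool_fraction > 0:
        n_dormant = int(round(config.dormant_pool_fraction * n_g))
        dormant = rng.choice(n_g, size=n_dormant, replace=False)
        level[dormant, 0] *= config.dormant_pool_decay

    gene_row = {g: i for i, g in enumerate(gene_ids)}
    for gid, j, fold in config.planted_effects:
        level[gene_row[gid], j:] *= fold  # time points t_{j+1}..t_T (0-based j:)

    time_of = np.array([a.time_index - 1 for a in design.arrays])
    n_a = design.n_arrays

    sample_noise = rng.normal(0.0, config.noise_log_sd, size=(n_g, n_a))
    ref_noise = rng.normal(0.0, config.noise_log_sd, size=(n_g, n_a))
    shifts = rng.normal(0.0, config.array_shift_sd, size=n_a)
    lo, hi = config.array_scale_range
    scales = rng.uniform(lo, hi, size=n_a)

    ref_mean = level.mean(axis=1)  # pooled common reference per gene
    log_sample = np.log2(level[:, time_of]) + sample_noise
    log_ref = np.log2(ref_mean)[:, None] + ref_noise

    # distort the log-ratio per array, keeping the reference channel fixed
    log_ratio = log_sample - log_ref
    log_sample = log_ref + log_ratio * scales[None, :] + shifts[None, :]

    outlier_cells: set[tuple[str, str]] = set()
    if config.outlier_fraction > 0:
        n_out = int(round(config.outlier_fraction * n_g * n_a))
        flat = rng.choice(n_g * n_a, size=n_out, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        rows, cols = np.unravel_index(flat, (n_g, n_a))
        log_sample[rows, cols] += signs * config.outlier_magnitude_log2
        array_ids = design.array_ids
        outlier_cells = {(gene_ids[r], array_ids[c]) for r, c in zip(rows, cols)}

    matrix = SignalMatrix(
        gene_ids, design, 2.0 ** log_sample, 2.0 ** log_ref,
        np.zeros((n_g, n_a), dtype=bool),
    )
    truth = GroundTruth(
        gene_ids=gene_ids,
        true_level=level,
        true_calls=_true_calls_from_levels(gene_ids, level),
        outlier_cells=outlier_cells,
    )
    return matrix, truth


def generate_null_experiment(
    n_genes: int,
    design: ExperimentDesign | None = None,
    noise_log_sd: float = 0.3,
    seed: int = 0,
) -> tuple[SignalMatrix, GroundTruth]:
    """A no-signal experiment: no planted effects, outliers, decay or
    per-array distortion.  Its ground truth has no true calls, which
    makes it the calibration harness for the type-I error of the
    interval tests."""
    config = SimulationConfig(
        n_genes=n_genes,
        design=design if design is not None else study_design(),
        noise_log_sd=noise_log_sd,
        array_shift_sd=0.0,
        array_scale_range=(1.0, 1.0),
        planted_effects=(),
        outlier_fraction=0.0,
        dormant_pool_fraction=0.0,
        seed=seed,
    )
    matrix, truth = generate_experiment(config)
    assert not truth.true_calls
    return matrix, truth


def export_fixture(matrix: SignalMatrix, truth: GroundTruth, directory: str | Path) -> None:
    """Write signals.tsv/design.tsv plus ground-truth tables to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_signal_tables(matrix, directory / "signals.tsv", directory / "design.tsv")
    levels = pd.DataFrame(
        truth.true_level,
        index=pd.Index(truth.gene_ids, name="gene_id"),
        columns=[f"t{j}" for j in range(1, truth.true_level.shape[1] + 1)],
    )
    levels.to_csv(directory / "truth_levels.tsv", sep="\t", float_format="%.10g")
    calls = truth.calls_frame()
    calls["interval"] = [interval_label(j) for j in calls["interval"]]
    calls.to_csv(directory / "truth_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.outlier_cells), columns=["gene_id", "array_id"]
    ).to_csv(directory / "truth_outliers.tsv", sep="\t", index=False)
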