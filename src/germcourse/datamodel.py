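"""Shared data containers for the germination time-course pipeline.

The experiment is a two-channel (Cy3 sample / Cy5 common-reference)
microarray time course: 13 time points by default (t1 dormant spores,
t2 heat-activated spores, t3..t13 every 30 min up to 5.5 h of
cultivation), with several replicate arrays per time point.  All
containers carry an explicit boolean *missing mask* (True = missing);
missing values are never encoded as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArrayInfo",
    "ExperimentDesign",
    "study_design",
    "SignalMatrix",
    "LogRatioMatrix",
    "NormalizedRatioMatrix",
    "IntervalCallSet",
    "PathwayMap",
    "GeneAnnotation",
    "interval_label",
]

#: Number of time points in the study design.
STUDY_N_TIMEPOINTS = 13


def interval_label(j: int) -> str:
    """Label of consecutive interval *j* (1-based): ``"t{j}-t{j+1}"``."""
    return f"t{j}-t{j + 1}"


@dataclass(frozen=True)
class ArrayInfo:
    """One hybridized array: its id, time point index and replicate id."""

    array_id: str
    time_index: int
    replicate_id: str


@dataclass(frozen=True)
class ExperimentDesign:
    """Mapping of arrays to time points and replicates.

    Parameters
    ----------
    arrays
        One :class:`ArrayInfo` per hybridized array.
    time_labels
        ``time_index -> label`` for each time point; labels are either a
        special state ("dormant", "heat-activated") or minutes from
        inoculation as a string.
    """

    arrays: tuple[ArrayInfo, ...]
    time_labels: Mapping[int, str]

    def __post_init__(self) -> None:
        if not self.arrays:
            raise ValueError("design has no arrays")
        object.__setattr__(self, "arrays", tuple(self.arrays))
        object.__setattr__(self, "time_labels", dict(self.time_labels))
        t = self.n_timepoints
        if t < 2:
            raise ValueError("design needs at least 2 time points")
        present = {a.time_index for a in self.arrays}
        missing = set(range(1, t + 1)) - present
        if missing:
            raise ValueError(f"time indices with no array: {sorted(missing)}")
        if min(present) < 1:
            raise ValueError("time indices are 1-based")
        seen: set[tuple[int, str]] = set()
        ids: set[str] = set()
        for a in self.arrays:
            if a.array_id in ids:
                raise ValueError(f"duplicate array_id {a.array_id!r}")
            ids.add(a.array_id)
            key = (a.time_index, a.replicate_id)
            if key in seen:
                raise ValueError(f"duplicate (time, replicate) pair {key}")
            seen.add(key)

    @property
    def n_timepoints(self) -> int:
        return max(a.time_index for a in self.arrays)

    @property
    def n_arrays(self) -> int:
        return len(self.arrays)

    @property
    def array_ids(self) -> list[str]:
        return [a.array_id for a in self.arrays]

    def columns_at(self, time_index: int) -> np.ndarray:
        """Column indices of the arrays measuring time point *time_index*."""
        return np.array(
            [i for i, a in enumerate(self.arrays) if a.time_index == time_index],
            dtype=int,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "array_id": [a.array_id for a in self.arrays],
                "time_index": [a.time_index for a in self.arrays],
                "replicate_id": [a.replicate_id for a in self.arrays],
                "time_label": [self.time_labels.get(a.time_index, "") for a in self.arrays],
            }
        )


def study_design(n_replicates: int = 4) -> ExperimentDesign:
    """The default germination design: 13 time points x ``n_replicates``.

    t1 samples dormant spores, t2 heat-activated spores (10 min, 50 degC),
    and t3..t13 sample every 30 min of cultivation up to 5.5 h.
    """
    labels: dict[int, str] = {1: "dormant", 2: "heat-activated"}
    for j in range(3, STUDY_N_TIMEPOINTS + 1):
        labels[j] = str(30 * (j - 2))
    arrays = [
        ArrayInfo(f"T{j:02d}R{r}", j, f"R{r}")
        for j in range(1, STUDY_N_TIMEPOINTS + 1)
        for r in range(1, n_replicates + 1)
    ]
    return ExperimentDesign(tuple(arrays), labels)


def _check_matrix(values: np.ndarray, mask: np.ndarray, n_genes: int, n_arrays: int, name: str) -> None:
    if values.shape != (n_genes, n_arrays):
        raise ValueError(f"{name} has shape {values.shape}, expected {(n_genes, n_arrays)}")
    if mask.shape != values.shape:
        raise ValueError(f"{name} mask shape mismatch")
    if not np.all(np.isfinite(values[~mask])):
        raise ValueError(f"{name} contains non-finite unmasked values")


@dataclass
class SignalMatrix:
    """Per-gene two-channel intensities across arrays.

    ``sample_signal`` holds the Cy3 (sample) channel and
    ``reference_signal`` the Cy5 channel — a common reference mixed from
    RNA of every time point, so an unchanged gene has expected
    log-ratio 0 throughout.  ``mask`` is True where a cell is missing in
    either channel.
    """

    gene_ids: list[str]
    design: ExperimentDesign
    sample_signal: np.ndarray
    reference_signal: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        self.sample_signal = np.asarray(self.sample_signal, dtype=float)
        self.reference_signal = np.asarray(self.reference_signal, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.sample_signal.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        n_g, n_a = len(self.gene_ids), self.design.n_arrays
        _check_matrix(self.sample_signal, self.mask, n_g, n_a, "sample_signal")
        _check_matrix(self.reference_signal, self.mask, n_g, n_a, "reference_signal")
        for name, ch in (("sample", self.sample_signal), ("reference", self.reference_signal)):
            if np.any(ch[~self.mask] < 0):
                raise ValueError(f"negative {name} signal")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_arrays(self) -> int:
        return self.design.n_arrays

    def gene_index(self, gene_ids: Iterable[str] | None = None) -> np.ndarray:
        if gene_ids is None:
            return np.arange(self.n_genes)
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in gene_ids], dtype=int)


@dataclass
class LogRatioMatrix:
    """Gene x array Log2Ratio values, ``log2(Cy3 sample / Cy5 reference)``."""

    gene_ids: list[str]
    design: ExperimentDesign
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        _check_matrix(self.values, self.mask, len(self.gene_ids), self.design.n_arrays, "values")

    def array_medians(self) -> np.ndarray:
        """Per-array median of unmasked Log2Ratios."""
        return _masked_columnwise(self.values, self.mask, np.median)

    def array_mads(self) -> np.ndarray:
        """Per-array raw median absolute deviation (no consistency factor)."""

        def mad(x: np.ndarray) -> float:
            return float(np.median(np.abs(x - np.median(x))))

        return _masked_columnwise(self.values, self.mask, mad)


def _masked_columnwise(values: np.ndarray, mask: np.ndarray, fn) -> np.ndarray:
    out = np.full(values.shape[1], np.nan)
    for a in range(values.shape[1]):
        col = values[~mask[:, a], a]
        if col.size:
            out[a] = fn(col)
    return out


@dataclass
class NormalizedRatioMatrix:
    """Gene x array Normalized Ratios (exponentiated normalized log-ratios).

    All unmasked entries are strictly positive.
    """

    gene_ids: list[str]
    design: ExperimentDesign
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        _check_matrix(self.values, self.mask, len(self.gene_ids), self.design.n_arrays, "values")
        if np.any(self.values[~self.mask] <= 0):
            raise ValueError("Normalized Ratios must be > 0")

    def replicate_values(self, gene_row: int, time_index: int) -> np.ndarray:
        cols = self.design.columns_at(time_index)
        keep = ~self.mask[gene_row, cols]
        return self.values[gene_row, cols[keep]]

    def gene_index(self, gene_ids: Iterable[str] | None = None) -> np.ndarray:
        if gene_ids is None:
            return np.arange(len(self.gene_ids))
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in gene_ids], dtype=int)


class IntervalCallSet:
    """Enhanced/diminished gene calls per consecutive interval.

    Backed by a DataFrame with columns ``gene_id, interval, direction,
    fold, p_value``; ``interval`` is the 1-based index j of interval
    tj-t(j+1).  A gene has at most one direction per interval; every
    call satisfies ``p_value < alpha`` and ``max(fold, 1/fold) >
    fold_threshold`` for the thresholds it was produced with.
    """

    COLUMNS = ["gene_id", "interval", "direction", "fold", "p_value"]

    def __init__(self, frame: pd.DataFrame | None = None) -> None:
        if frame is None:
            frame = pd.DataFrame(columns=self.COLUMNS)
        frame = frame.reset_index(drop=True)[self.COLUMNS].copy()
        frame["interval"] = frame["interval"].astype(int)
        frame["fold"] = frame["fold"].astype(float)
        frame["p_value"] = frame["p_value"].astype(float)
        bad = ~frame["direction"].isin(["enhanced", "diminished"])
        if bad.any():
            raise ValueError(f"invalid direction values: {frame.loc[bad, 'direction'].unique()}")
        if frame.duplicated(["gene_id", "interval"]).any():
            raise ValueError("a gene may have at most one call per interval")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalCallSet):
            return NotImplemented
        a = self.frame.sort_values(["gene_id", "interval"]).reset_index(drop=True)
        b = other.frame.sort_values(["gene_id", "interval"]).reset_index(drop=True)
        return a.equals(b)

    def as_tuples(self) -> set[tuple[str, int, str]]:
        """Direction calls as ``(gene_id, interval, direction)`` triples."""
        return set(
            zip(self.frame["gene_id"], self.frame["interval"], self.frame["direction"])
        )

    def for_interval(self, j: int) -> pd.DataFrame:
        return self.frame[self.frame["interval"] == j]

    def for_gene(self, gene_id: str) -> pd.DataFrame:
        return self.frame[self.frame["gene_id"] == gene_id]


class PathwayMap:
    """Gene -> pathway -> functional-group ontology (KEGG snapshot).

    A gene may belong to several pathways; every pathway belongs to
    exactly one functional group (KEGG's top-level categories, e.g.
    "Amino acid metabolism").
    """

    COLUMNS = ["gene_id", "pathway_id", "pathway_name", "functional_group"]

    def __init__(self, records: pd.DataFrame) -> None:
        records = records.reset_index(drop=True)[self.COLUMNS].copy()
        if records.duplicated(["gene_id", "pathway_id"]).any():
            raise ValueError("(gene_id, pathway_id) pairs must be unique")
        groups_per_pathway = records.groupby("pathway_id")["functional_group"].nunique()
        offenders = groups_per_pathway[groups_per_pathway > 1]
        if len(offenders):
            raise ValueError(
                f"pathway assigned to more than one functional group: {list(offenders.index)}"
            )
        self.records = records

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.records["gene_id"])

    def pathways_of(self, gene_id: str) -> list[str]:
        return list(self.records.loc[self.records["gene_id"] == gene_id, "pathway_id"])

    def group_of(self, pathway_id: str) -> str:
        sub = self.records.loc[self.records["pathway_id"] == pathway_id, "functional_group"]
        if sub.empty:
            raise KeyError(pathway_id)
        return sub.iloc[0]

    def group_gene_counts(self) -> pd.Series:
        """Total number of distinct genes recorded in each functional group."""
        return self.records.groupby("functional_group")["gene_id"].nunique()

    def pathway_names(self) -> pd.Series:
        return self.records.drop_duplicates("pathway_id").set_index("pathway_id")["pathway_name"]


class GeneAnnotation:
    """gene_id -> (product, is_sigma_factor)."""

    def __init__(self, table: pd.DataFrame) -> None:
        table = table.reset_index(drop=True)[["gene_id", "product", "is_sigma_factor"]].copy()
        if table["gene_id"].duplicated().any():
            dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene_id in annotation: {dupes}")
        table["is_sigma_factor"] = table["is_sigma_factor"].astype(bool)
        self.table = table.set_index("gene_id")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sigma_factors(self) -> list[str]:
        return list(self.table.index[self.table["is_sigma_factor"]])

    def product_of(self, gene_id: str) -> str:
        return str(self.table.loc[gene_id, "product"])
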