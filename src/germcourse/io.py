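"""Readers and writers for the pipeline's tabular (TSV) interfaces.

All tables are UTF-8 TSV with a mandatory header and "." as the decimal
point.  The signal table carries one ``gene_id`` column plus one column
per array and channel, with channel suffixes ``_Cy3`` (sample) and
``_Cy5`` (common reference).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    ArrayInfo,
    ExperimentDesign,
    GeneAnnotation,
    IntervalCallSet,
    PathwayMap,
    SignalMatrix,
    interval_label,
)

logger = logging.getLogger(__name__)

SAMPLE_SUFFIX = "_Cy3"
REFERENCE_SUFFIX = "_Cy5"

__all__ = [
    "read_design_tsv",
    "write_design_tsv",
    "read_signal_tables",
    "write_signal_tables",
    "read_kegg_map_tsv",
    "read_annotation_tsv",
    "write_interval_calls_tsv",
    "read_interval_calls_tsv",
]


def read_design_tsv(path: str | Path) -> ExperimentDesign:
    """Read a design table mapping array_id -> (time_index, replicate_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"array_id", "time_index", "replicate_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design file {path} lacks columns {sorted(missing)}")
    arrays = tuple(
        ArrayInfo(str(r.array_id), int(r.time_index), str(r.replicate_id))
        for r in df.itertuples()
    )
    if "time_label" in df.columns:
        labels = {
            int(r.time_index): str(r.time_label) for r in df.itertuples()
        }
    else:
        labels = {a.time_index: str(a.time_index) for a in arrays}
    return ExperimentDesign(arrays, labels)


def write_design_tsv(design: ExperimentDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def _parse_numeric(column: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Parse a column to float, masking unparseable cells. Returns (values, mask)."""
    parsed = pd.to_numeric(column, errors="coerce")
    mask = parsed.isna().to_numpy()
    values = parsed.fillna(1.0).to_numpy(dtype=float)  # placeholder under mask
    return values, mask


def read_signal_tables(signals_path: str | Path, design_path: str | Path) -> SignalMatrix:
    """Read the two-channel signal table and its design into a SignalMatrix.

    Unparseable numeric cells become masked-missing; the number of such
    cells is logged as a warning.  An array column in the signal file
    with no design entry is a hard error naming the array.
    """
    design = read_design_tsv(design_path)
    df = pd.read_csv(signals_path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        raise ValueError(f"signal file {signals_path} lacks a gene_id column")
    gene_ids = df["gene_id"].tolist()
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"duplicate gene_id in {signals_path}: {dupes}")

    known = set(design.array_ids)
    for col in df.columns:
        if col == "gene_id":
            continue
        for suffix in (SAMPLE_SUFFIX, REFERENCE_SUFFIX):
            if col.endswith(suffix):
                array_id = col[: -len(suffix)]
                if array_id not in known:
                    raise ValueError(
                        f"array {array_id!r} in signal file has no design entry"
                    )
                break
        else:
            raise ValueError(f"unrecognized signal column {col!r} (expected *_Cy3/*_Cy5)")

    n_genes, n_arrays = len(gene_ids), design.n_arrays
    sample = np.zeros((n_genes, n_arrays))
    reference = np.zeros((n_genes, n_arrays))
    mask = np.zeros((n_genes, n_arrays), dtype=bool)
    n_bad = 0
    for a, array_id in enumerate(design.array_ids):
        for suffix, target in ((SAMPLE_SUFFIX, sample), (REFERENCE_SUFFIX, reference)):
            col = array_id + suffix
            if col not in df.columns:
                raise ValueError(f"signal file lacks column {col!r} for designed array")
            values, bad = _parse_numeric(df[col])
            n_bad += int(bad.sum())
            target[:, a] = values
            mask[:, a] |= bad
    if n_bad:
        logger.warning("masked %d unparseable signal cells", n_bad)
    sm = SignalMatrix(gene_ids, design, sample, reference, mask)
    sm.n_unparseable = n_bad  # type: ignore[attr-defined]
    return sm


def write_signal_tables(matrix: SignalMatrix, signals_path: str | Path, design_path: str | Path) -> None:
    """Write a SignalMatrix as signals.tsv + design.tsv (missing cells -> NA)."""
    data: dict[str, object] = {"gene_id": matrix.gene_ids}
    for a, array_id in enumerate(matrix.design.array_ids):
        for suffix, channel in (
            (SAMPLE_SUFFIX, matrix.sample_signal),
            (REFERENCE_SUFFIX, matrix.reference_signal),
        ):
            col = channel[:, a].astype(object)
            col[matrix.mask[:, a]] = "NA"
            data[array_id + suffix] = col
    pd.DataFrame(data).to_csv(signals_path, sep="\t", index=False, float_format="%.10g")
    write_design_tsv(matrix.design, design_path)


def read_kegg_map_tsv(path: str | Path) -> PathwayMap:
    """Read the gene -> pathway -> functional group ontology snapshot.

    Fully duplicated rows are collapsed with a warning; a pathway listed
    under two functional groups is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PathwayMap.COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"KEGG map {path} lacks columns {sorted(missing)}")
    n_before = len(df)
    df = df.drop_duplicates(PathwayMap.COLUMNS)
    if len(df) < n_before:
        logger.warning("collapsed %d duplicated KEGG map rows", n_before - len(df))
    return PathwayMap(df)


_TRUE_TOKENS = {"1", "true", "True", "TRUE"}
_FALSE_TOKENS = {"0", "false", "False", "FALSE"}


def read_annotation_tsv(path: str | Path) -> GeneAnnotation:
    """Read the gene annotation table (product text, sigma-factor flag)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "product", "is_sigma_factor"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation {path} lacks columns {sorted(missing)}")
    flags = []
    for i, token in enumerate(df["is_sigma_factor"]):
        if token in _TRUE_TOKENS:
            flags.append(True)
        elif token in _FALSE_TOKENS:
            flags.append(False)
        else:
            raise ValueError(
                f"row {i + 2} of {path}: bad is_sigma_factor token {token!r}"
            )
    df = df.assign(is_sigma_factor=flags)
    df["product"] = df["product"].fillna("")
    return GeneAnnotation(df)


def write_interval_calls_tsv(calls: IntervalCallSet, path: str | Path) -> None:
    """Write interval calls with interval labels like "t2-t3".

    fold and p_value are written at 12 significant digits so the table
    round-trips bit-identically at that precision.
    """
    out = calls.frame.copy()
    out["interval"] = [interval_label(j) for j in out["interval"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_interval_calls_tsv(path: str | Path) -> IntervalCallSet:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if len(df):
        df["interval"] = [int(str(s).split("-")[0][1:]) for s in df["interval"]]
    else:
        df["interval"] = df["interval"].astype(int)
    return IntervalCallSet(df)
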