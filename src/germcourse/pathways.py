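"""KEGG pathway, functional-group and sigma-factor summaries.

Interval calls are aggregated three ways: per-pathway enhanced and
diminished gene counts with an activation flag (a pathway counts as
activated at an interval when strictly more than ``pathway_gene_threshold``
of its genes are enhanced there); per-functional-group percentages of
the group's total KEGG gene census, with groups whose whole-course
changed-gene tally stays below ``group_min_changed`` marked excluded;
and an ordered sigma-factor profile table sorted by earliest enhanced
interval, then descending fold.

The two gene-count thresholds (strictly >3 for pathway activation,
exclusion below 3 changed genes for groups) are deliberately separate
parameters with those literal defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datamodel import GeneAnnotation, IntervalCallSet, PathwayMap, interval_label

__all__ = [
    "map_calls",
    "pathway_activation_counts",
    "functional_group_percentages",
    "sigma_factor_profiles",
    "summarize_counts",
    "PathwaySummarizer",
]


def map_calls(calls: IntervalCallSet, pmap: PathwayMap, n_intervals: int = 12) -> pd.DataFrame:
    """Per (pathway, interval) enhanced/diminished gene counts.

    Each called gene contributes to every pathway it maps to; called
    genes absent from the map are tallied separately in
    ``result.attrs["unmapped"]`` (per direction, unique genes).
    """
    merged = calls.frame.merge(pmap.records, on="gene_id", how="left")
    unmapped = merged[merged["pathway_id"].isna()]
    mapped = merged.dropna(subset=["pathway_id"])

    pathways = pmap.records["pathway_id"].unique()
    index = pd.MultiIndex.from_product(
        [pathways, range(1, n_intervals + 1)], names=["pathway_id", "interval"]
    )
    table = pd.DataFrame(0, index=index, columns=["enhanced_gene_count", "diminished_gene_count"])
    if len(mapped):
        counts = (
            mapped.groupby(["pathway_id", "interval", "direction"])["gene_id"]
            .nunique()
            .unstack("direction", fill_value=0)
        )
        for direction, col in (("enhanced", "enhanced_gene_count"), ("diminished", "diminished_gene_count")):
            if direction in counts.columns:
                table.loc[counts.index, col] = counts[direction].to_numpy()
    table.attrs["unmapped"] = {
        direction: int(unmapped.loc[unmapped["direction"] == direction, "gene_id"].nunique())
        for direction in ("enhanced", "diminished")
    }
    return table


def pathway_activation_counts(
    table: pd.DataFrame, pathway_gene_threshold: int = 3
) -> pd.DataFrame:
    """Add activation flags and per-interval activated/deactivated totals.

    A pathway is activated (deactivated) at an interval when its
    enhanced (diminished) gene count strictly exceeds the threshold.
    Per-interval totals are attached as ``result.attrs["per_interval"]``.
    """
    out = table.copy()
    out["activated"] = out["enhanced_gene_count"] > pathway_gene_threshold
    out["deactivated"] = out["diminished_gene_count"] > pathway_gene_threshold
    per_interval = out.groupby(level="interval")[["activated", "deactivated"]].sum()
    per_interval.columns = ["n_pathways_activated", "n_pathways_deactivated"]
    out.attrs["per_interval"] = per_interval
    out.attrs["unmapped"] = table.attrs.get("unmapped", {})
    return out


def functional_group_percentages(
    calls: IntervalCallSet,
    pmap: PathwayMap,
    group_min_changed: int = 3,
    n_intervals: int = 12,
) -> pd.DataFrame:
    """Percent of each functional group's gene census changed per interval.

    The denominator is the group's total number of distinct KEGG genes.
    Groups with fewer than ``group_min_changed`` distinct changed genes
    over the whole course are marked ``excluded``.
    """
    totals = pmap.group_gene_counts()
    if (totals == 0).any():
        raise ValueError("functional group with zero genes")
    gene_groups = pmap.records[["gene_id", "functional_group"]].drop_duplicates()
    merged = calls.frame.merge(gene_groups, on="gene_id", how="inner")

    index = pd.MultiIndex.from_product(
        [totals.index, range(1, n_intervals + 1)], names=["functional_group", "interval"]
    )
    out = pd.DataFrame(0.0, index=index, columns=["percent_enhanced", "percent_diminished"])
    if len(merged):
        counts = (
            merged.groupby(["functional_group", "interval", "direction"])["gene_id"]
            .nunique()
            .unstack("direction", fill_value=0)
        )
        for direction, col in (("enhanced", "percent_enhanced"), ("diminished", "percent_diminished")):
            if direction in counts.columns:
                denom = totals.loc[counts.index.get_level_values("functional_group")].to_numpy()
                out.loc[counts.index, col] = 100.0 * counts[direction].to_numpy() / denom
    changed = merged.groupby("functional_group")["gene_id"].nunique()
    changed = changed.reindex(totals.index, fill_value=0)
    excluded = changed < group_min_changed
    out["excluded"] = excluded.loc[out.index.get_level_values("functional_group")].to_numpy()
    out.attrs["group_totals"] = totals
    out.attrs["group_changed"] = changed
    return out


def sigma_factor_profiles(
    calls: IntervalCallSet,
    annotation: GeneAnnotation,
    n_intervals: int = 12,
) -> pd.DataFrame:
    """Ordered fold table of sigma factors with at least one call.

    Rows are sigma-factor genes sorted by the earliest interval at which
    they were enhanced (genes never enhanced sort after, by earliest
    diminished interval), ties broken by descending fold at that
    interval.  Cells hold the fold only where a call exists and NaN
    elsewhere.
    """
    sigma = set(annotation.sigma_factors)
    sub = calls.frame[calls.frame["gene_id"].isin(sigma)]
    cols = [interval_label(j) for j in range(1, n_intervals + 1)]
    if sub.empty:
        return pd.DataFrame(columns=cols)

    order = []
    for gene_id, grp in sub.groupby("gene_id"):
        enh = grp[grp["direction"] == "enhanced"]
        if len(enh):
            first = int(enh["interval"].min())
            fold = float(enh.loc[enh["interval"] == first, "fold"].iloc[0])
            key = (0, first, -fold)
        else:
            first = int(grp["interval"].min())
            fold = float(grp.loc[grp["interval"] == first, "fold"].iloc[0])
            key = (1, first, fold)
        order.append((key, gene_id))
    order.sort()

    rows = []
    for _, gene_id in order:
        grp = sub[sub["gene_id"] == gene_id]
        row = {c: np.nan for c in cols}
        for rec in grp.itertuples():
            row[interval_label(rec.interval)] = rec.fold
        rows.append(pd.Series(row, name=gene_id))
    out = pd.DataFrame(rows)
    out.index.name = "gene_id"
    return out


def summarize_counts(calls: IntervalCallSet, n_intervals: int = 12) -> dict:
    """Per-interval and whole-course unique gene counts of the calls.

    Returns a dict with ``per_interval`` (DataFrame indexed by interval
    with enhanced/diminished columns) and the unique tallies
    ``unique_enhanced`` / ``unique_diminished`` — genes whose expression
    was enhanced (diminished) at least once between two consecutive
    time points.
    """
    frame = calls.frame
    per_interval = pd.DataFrame(
        0, index=pd.Index(range(1, n_intervals + 1), name="interval"),
        columns=["enhanced", "diminished"],
    )
    if len(frame):
        counts = (
            frame.groupby(["interval", "direction"])["gene_id"].nunique().unstack(fill_value=0)
        )
        for col in ("enhanced", "diminished"):
            if col in counts.columns:
                per_interval.loc[counts.index, col] = counts[col]
    return {
        "per_interval": per_interval,
        "unique_enhanced": int(frame.loc[frame["direction"] == "enhanced", "gene_id"].nunique()),
        "unique_diminished": int(frame.loc[frame["direction"] == "diminished", "gene_id"].nunique()),
    }


class PathwaySummarizer(BaseEstimator):
    """Aggregates interval calls into pathway/group/sigma summaries.

    Attributes (after ``fit(calls)``): ``pathway_table_``,
    ``group_table_``, ``sigma_table_`` (when an annotation is given) and
    ``counts_``.
    """

    def __init__(
        self,
        pathway_gene_threshold: int = 3,
        group_min_changed: int = 3,
        n_intervals: int = 12,
    ) -> None:
        self.pathway_gene_threshold = pathway_gene_threshold
        self.group_min_changed = group_min_changed
        self.n_intervals = n_intervals

    def fit(
        self,
        X: IntervalCallSet,
        y=None,
        pathway_map: PathwayMap | None = None,
        annotation: GeneAnnotation | None = None,
    ) -> "PathwaySummarizer":
        if not isinstance(X, IntervalCallSet):
            raise TypeError("PathwaySummarizer expects an IntervalCallSet")
        self.counts_ = summarize_counts(X, self.n_intervals)
        if pathway_map is not None:
            table = map_calls(X, pathway_map, self.n_intervals)
            self.pathway_table_ = pathway_activation_counts(table, self.pathway_gene_threshold)
            self.group_table_ = functional_group_percentages(
                X, pathway_map, self.group_min_changed, self.n_intervals
            )
        if annotation is not None:
            self.sigma_table_ = sigma_factor_profiles(X, annotation, self.n_intervals)
        return self
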