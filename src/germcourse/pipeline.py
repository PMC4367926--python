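"""End-to-end pipeline: signals in, calls and summaries out.

Stage order: read -> log-ratios -> center/scale -> tail trim ->
exponentiate -> replicate outlier filter -> highly-expressed filter ->
expression levels -> differential profiles -> interval calls ->
pathway / functional-group / sigma-factor summaries.  Identical config
and inputs give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .datamodel import IntervalCallSet
from .diffexpr import ConsecutiveIntervalDE
from .filtering import HighExpressionFilter
from .io import (
    read_annotation_tsv,
    read_kegg_map_tsv,
    read_signal_tables,
    write_interval_calls_tsv,
)
from .normalization import ArrayNormalizer
from .outliers import DIXON_CRITICAL, ReplicateOutlierFilter
from .pathways import PathwaySummarizer

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every input path and threshold of one pipeline run.

    Defaults are the study's analysis parameters: 0.02 per-tail
    trimming, Q-test confidence 0.95, t-test alpha 0.05, strict 2-fold
    bar, pathway activation above 3 genes, group exclusion below 3
    changed genes.
    """

    signals: str = ""
    design: str = ""
    kegg: str | None = None
    annotation: str | None = None
    out_dir: str = "germcourse_out"
    tail: float = 0.02
    center_scale: bool = True
    outlier_confidence: float = 0.95
    dixon_max: int = 9
    rescue_ratio: float = 4.0
    alpha: float = 0.05
    fold_threshold: float = 2.0
    welch: bool = False
    bh: bool = False
    pathway_gene_threshold: int = 3
    group_min_changed: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} is not a flat key-value document")
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return validate_config(cls(**raw))


def validate_config(config: PipelineConfig) -> PipelineConfig:
    """Range-check every threshold; raises naming the offending key."""
    checks = [
        ("tail", 0 <= config.tail < 0.5),
        ("alpha", 0 < config.alpha < 1),
        ("fold_threshold", config.fold_threshold > 1),
        ("rescue_ratio", config.rescue_ratio > 0),
        ("pathway_gene_threshold", config.pathway_gene_threshold >= 0),
        ("group_min_changed", config.group_min_changed >= 0),
        ("dixon_max", 3 <= config.dixon_max <= 10),
        ("outlier_confidence", round(config.outlier_confidence, 2) in DIXON_CRITICAL),
    ]
    for key, ok in checks:
        if not ok:
            raise ValueError(f"config key {key!r} out of range: {getattr(config, key)!r}")
    return config


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the output tables plus a run report.

    Returns the report dict (also written as ``run_report.json``):
    every threshold applied, the computed highly-expressed cutoff,
    per-stage gene/array/call counts, and the package version.
    """
    config = validate_config(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    current = stage("read")
    try:
        matrix = read_signal_tables(config.signals, config.design)
        report: dict = {
            "version": __version__,
            "config": {
                k: v for k, v in dataclasses.asdict(config).items()
            },
            "n_genes_input": matrix.n_genes,
            "n_arrays": matrix.n_arrays,
            "n_timepoints": matrix.design.n_timepoints,
        }

        current = stage("normalize")
        normalizer = ArrayNormalizer(tail=config.tail, center_scale=config.center_scale)
        nrm = normalizer.fit(matrix).transform(matrix)
        report["n_cells_trimmed"] = normalizer.n_trimmed_

        current = stage("replicate_outliers")
        out_filter = ReplicateOutlierFilter(
            confidence=config.outlier_confidence, dixon_max=config.dixon_max
        )
        nrm = out_filter.fit(nrm).transform(nrm)
        report["n_outlier_cells_rejected"] = out_filter.n_rejected_

        current = stage("highly_expressed_filter")
        hef = HighExpressionFilter(rescue_ratio=config.rescue_ratio).fit(matrix)
        report["highly_expressed_threshold"] = hef.threshold_
        report["n_highly_expressed"] = len(hef.kept_genes_)
        report["n_rescued"] = int(hef.flags_["rescued"].sum())
        hef.flags_.to_csv(out_dir / "filter_flags.tsv", sep="\t", float_format="%.12g")

        current = stage("differential_expression")
        de = ConsecutiveIntervalDE(
            alpha=config.alpha,
            fold_threshold=config.fold_threshold,
            welch=config.welch,
            bh=config.bh,
        ).fit(nrm, kept_genes=hef.kept_genes_)
        calls: IntervalCallSet = de.calls_
        report["n_calls"] = len(calls)
        de.profiles_.levels.to_csv(out_dir / "expression_levels.tsv", sep="\t", float_format="%.12g")
        write_interval_calls_tsv(calls, out_dir / "calls.tsv")

        current = stage("summaries")
        pmap = read_kegg_map_tsv(config.kegg) if config.kegg else None
        annotation = read_annotation_tsv(config.annotation) if config.annotation else None
        summarizer = PathwaySummarizer(
            pathway_gene_threshold=config.pathway_gene_threshold,
            group_min_changed=config.group_min_changed,
            n_intervals=matrix.design.n_timepoints - 1,
        ).fit(calls, pathway_map=pmap, annotation=annotation)
        counts = summarizer.counts_
        report["n_genes_enhanced_at_least_once"] = counts["unique_enhanced"]
        report["n_genes_diminished_at_least_once"] = counts["unique_diminished"]
        counts["per_interval"].to_csv(out_dir / "interval_counts.tsv", sep="\t")
        if pmap is not None:
            summarizer.pathway_table_.to_csv(out_dir / "pathway_activation.tsv", sep="\t")
            summarizer.pathway_table_.attrs["per_interval"].to_csv(
                out_dir / "pathway_interval_totals.tsv", sep="\t"
            )
            summarizer.group_table_.to_csv(
                out_dir / "group_percentages.tsv", sep="\t", float_format="%.12g"
            )
            report["unmapped_called_genes"] = summarizer.pathway_table_.attrs["unmapped"]
        if annotation is not None:
            summarizer.sigma_table_.to_csv(
                out_dir / "sigma_profiles.tsv", sep="\t", float_format="%.12g"
            )
            report["n_sigma_factors_called"] = len(summarizer.sigma_table_)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
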