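"""Pathway activation, functional-group percentages, sigma-factor table."""

import numpy as np
import pandas as pd
import pytest

from germcourse.datamodel import GeneAnnotation, IntervalCallSet, PathwayMap
from germcourse.pathways import (
    PathwaySummarizer,
    functional_group_percentages,
    map_calls,
    pathway_activation_counts,
    sigma_factor_profiles,
    summarize_counts,
)


def _calls(rows) -> IntervalCallSet:
    return IntervalCallSet(
        pd.DataFrame(rows, columns=["gene_id", "interval", "direction", "fold", "p_value"])
    )


@pytest.fixture
def pmap(kegg_frame) -> PathwayMap:
    return PathwayMap(kegg_frame)


class TestMapCalls:
    def test_multi_pathway_gene_counts_in_both(self, pmap):
        calls = _calls([("g1", 2, "enhanced", 4.0, 0.01)])
        table = map_calls(calls, pmap)
        assert table.loc[("00010", 2), "enhanced_gene_count"] == 1
        assert table.loc[("00020", 2), "enhanced_gene_count"] == 1
        assert table["enhanced_gene_count"].sum() == 2

    def test_unmapped_gene_only_in_tally(self, pmap):
        calls = _calls([("gX", 3, "diminished", 0.2, 0.01)])
        table = map_calls(calls, pmap)
        assert table.to_numpy().sum() == 0
        assert table.attrs["unmapped"] == {"enhanced": 0, "diminished": 1}

    def test_empty_calls_all_zero(self, pmap):
        table = map_calls(IntervalCallSet(), pmap)
        assert table.to_numpy().sum() == 0


class TestActivation:
    def _table(self, pmap, n_genes_enhanced):
        rows = [
            (f"g{i}", 2, "enhanced", 4.0, 0.01) for i in range(1, n_genes_enhanced + 1)
        ]
        return map_calls(_calls(rows), pmap)

    def test_strictly_more_than_three_genes(self, kegg_frame):
        # pathway 00010 with 4 member genes enhanced -> activated;
        # with exactly 3 -> not activated under the default threshold
        extra = pd.DataFrame(
            {
                "gene_id": ["g5", "g6"],
                "pathway_id": ["00010", "00010"],
                "pathway_name": ["Glycolysis"] * 2,
                "functional_group": ["Carbohydrate metabolism"] * 2,
            }
        )
        pmap = PathwayMap(pd.concat([kegg_frame, extra]))
        rows4 = [(g, 2, "enhanced", 4.0, 0.01) for g in ("g1", "g2", "g5", "g6")]
        out4 = pathway_activation_counts(map_calls(_calls(rows4), pmap))
        assert bool(out4.loc[("00010", 2), "activated"])
        rows3 = rows4[:3]
        out3 = pathway_activation_counts(map_calls(_calls(rows3), pmap))
        assert not out3.loc[("00010", 2), "activated"]

    def test_threshold_zero_any_call_activates(self, pmap):
        calls = _calls([("g2", 5, "enhanced", 3.0, 0.01)])
        out = pathway_activation_counts(map_calls(calls, pmap), pathway_gene_threshold=0)
        assert bool(out.loc[("00010", 5), "activated"])

    def test_per_interval_totals(self, pmap):
        calls = _calls([("g1", 2, "enhanced", 4.0, 0.01)])
        out = pathway_activation_counts(map_calls(calls, pmap), pathway_gene_threshold=0)
        per = out.attrs["per_interval"]
        assert per.loc[2, "n_pathways_activated"] == 2  # g1 is in two pathways
        assert per.loc[3, "n_pathways_activated"] == 0


class TestGroupPercentages:
    def test_percentage_of_group_census(self, pmap):
        # Carbohydrate metabolism has 3 distinct genes; 2 enhanced at j=2
        calls = _calls(
            [
                ("g1", 2, "enhanced", 4.0, 0.01),
                ("g2", 2, "enhanced", 3.0, 0.01),
                ("g4", 1, "diminished", 0.2, 0.01),
            ]
        )
        out = functional_group_percentages(calls, pmap, group_min_changed=1)
        assert out.loc[("Carbohydrate metabolism", 2), "percent_enhanced"] == pytest.approx(
            100 * 2 / 3
        )
        assert out.loc[("Energy metabolism", 1), "percent_diminished"] == pytest.approx(50.0)

    def test_exclusion_below_three_changed_genes(self, pmap):
        calls = _calls(
            [
                ("g1", 2, "enhanced", 4.0, 0.01),
                ("g2", 7, "enhanced", 3.0, 0.01),
                ("g3", 9, "diminished", 0.3, 0.01),
                ("g4", 1, "diminished", 0.2, 0.01),
            ]
        )
        out = functional_group_percentages(calls, pmap)
        # Carbohydrate metabolism: 3 distinct changed genes -> stays
        assert not out.loc[("Carbohydrate metabolism", 1), "excluded"]
        # Energy metabolism: only 1 changed gene -> excluded
        assert bool(out.loc[("Energy metabolism", 1), "excluded"])

    def test_no_calls_everything_excluded(self, pmap):
        out = functional_group_percentages(IntervalCallSet(), pmap)
        assert (out[["percent_enhanced", "percent_diminished"]].to_numpy() == 0).all()
        assert out["excluded"].all()

    def test_percentages_unaffected_by_other_groups(self, pmap):
        base = [("g1", 2, "enhanced", 4.0, 0.01)]
        extra = base + [("g4", 2, "enhanced", 9.0, 0.001), ("g5", 2, "enhanced", 9.0, 0.001)]
        a = functional_group_percentages(_calls(base), pmap, group_min_changed=0)
        b = functional_group_percentages(_calls(extra), pmap, group_min_changed=0)
        pd.testing.assert_series_equal(
            a.loc["Carbohydrate metabolism", "percent_enhanced"],
            b.loc["Carbohydrate metabolism", "percent_enhanced"],
        )


class TestSigmaProfiles:
    @pytest.fixture
    def annotation(self):
        rows = [(g, "sigma factor", True) for g in ("sigA", "sigB", "sigC", "sigD")]
        rows.append(("other", "kinase", False))
        return GeneAnnotation(
            pd.DataFrame(rows, columns=["gene_id", "product", "is_sigma_factor"])
        )

    def test_sorted_by_earliest_enhanced_interval(self, annotation):
        calls = _calls(
            [
                ("sigB", 2, "enhanced", 10.0, 0.001),
                ("sigA", 1, "enhanced", 3.5, 0.01),
                ("other", 1, "enhanced", 99.0, 0.001),
            ]
        )
        table = sigma_factor_profiles(calls, annotation)
        assert list(table.index) == ["sigA", "sigB"]  # earliest interval first
        assert table.loc["sigA", "t1-t2"] == pytest.approx(3.5)
        assert np.isnan(table.loc["sigA", "t2-t3"])

    def test_tie_broken_by_descending_fold(self, annotation):
        calls = _calls(
            [
                ("sigA", 2, "enhanced", 3.0, 0.01),
                ("sigB", 2, "enhanced", 10.0, 0.001),
            ]
        )
        table = sigma_factor_profiles(calls, annotation)
        assert list(table.index) == ["sigB", "sigA"]

    def test_silent_sigma_factor_omitted(self, annotation):
        calls = _calls([("sigC", 4, "enhanced", 5.0, 0.01)])
        table = sigma_factor_profiles(calls, annotation)
        assert "sigD" not in table.index and list(table.index) == ["sigC"]

    def test_empty(self, annotation):
        assert sigma_factor_profiles(IntervalCallSet(), annotation).empty


class TestSummaries:
    def test_unique_vs_interval_tallies(self):
        calls = _calls(
            [
                ("g1", 2, "enhanced", 4.0, 0.01),
                ("g1", 7, "enhanced", 3.0, 0.01),
                ("g2", 2, "diminished", 0.2, 0.01),
            ]
        )
        summary = summarize_counts(calls)
        assert summary["unique_enhanced"] == 1
        assert summary["unique_diminished"] == 1
        per = summary["per_interval"]
        assert per.loc[2, "enhanced"] == 1 and per.loc[7, "enhanced"] == 1
        assert per["enhanced"].sum() == 2  # interval tallies count g1 twice

    def test_empty(self):
        summary = summarize_counts(IntervalCallSet())
        assert summary["unique_enhanced"] == 0
        assert (summary["per_interval"].to_numpy() == 0).all()

    def test_summarizer_estimator(self, pmap):
        calls = _calls([("g1", 2, "enhanced", 4.0, 0.01)])
        s = PathwaySummarizer().fit(calls, pathway_map=pmap)
        assert s.counts_["unique_enhanced"] == 1
        assert s.pathway_table_.loc[("00010", 2), "enhanced_gene_count"] == 1
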