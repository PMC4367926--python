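"""Data containers and TSV round-trips."""

import numpy as np
import pandas as pd
import pytest

from germcourse.datamodel import (
    ArrayInfo,
    ExperimentDesign,
    IntervalCallSet,
    PathwayMap,
    SignalMatrix,
    interval_label,
    study_design,
)
from germcourse.io import (
    read_annotation_tsv,
    read_interval_calls_tsv,
    read_kegg_map_tsv,
    read_signal_tables,
    write_interval_calls_tsv,
    write_signal_tables,
)


class TestExperimentDesign:
    def test_study_design_shape(self):
        d = study_design(4)
        assert d.n_timepoints == 13
        assert d.n_arrays == 52
        assert d.time_labels[1] == "dormant"
        assert d.time_labels[2] == "heat-activated"
        assert d.time_labels[3] == "30" and d.time_labels[13] == "330"

    def test_missing_timepoint_rejected(self):
        arrays = (ArrayInfo("a", 1, "r1"), ArrayInfo("b", 3, "r1"))
        with pytest.raises(ValueError, match="no array"):
            ExperimentDesign(arrays, {})

    def test_duplicate_replicate_pair_rejected(self):
        arrays = (
            ArrayInfo("a", 1, "r1"), ArrayInfo("b", 1, "r1"),
            ArrayInfo("c", 2, "r1"),
        )
        with pytest.raises(ValueError, match="duplicate"):
            ExperimentDesign(arrays, {})


class TestSignalIO:
    def test_round_trip(self, tmp_path, tiny_matrix):
        write_signal_tables(tiny_matrix, tmp_path / "s.tsv", tmp_path / "d.tsv")
        back = read_signal_tables(tmp_path / "s.tsv", tmp_path / "d.tsv")
        assert back.gene_ids == tiny_matrix.gene_ids
        assert back.sample_signal.shape == (3, 4)
        assert back.mask.sum() == 0
        np.testing.assert_allclose(back.sample_signal, tiny_matrix.sample_signal)
        np.testing.assert_allclose(back.reference_signal, tiny_matrix.reference_signal)

    def test_na_cell_masked_with_warning(self, tmp_path, tiny_matrix, caplog):
        write_signal_tables(tiny_matrix, tmp_path / "s.tsv", tmp_path / "d.tsv")
        text = (tmp_path / "s.tsv").read_text().replace("\t8.0\t", "\tNA\t", 1)
        (tmp_path / "s.tsv").write_text(text)
        with caplog.at_level("WARNING", logger="germcourse.io"):
            back = read_signal_tables(tmp_path / "s.tsv", tmp_path / "d.tsv")
        assert back.mask.sum() == 1
        assert back.n_unparseable == 1
        assert any("masked 1" in r.message for r in caplog.records)

    def test_array_without_design_entry_is_named(self, tmp_path, tiny_matrix):
        write_signal_tables(tiny_matrix, tmp_path / "s.tsv", tmp_path / "d.tsv")
        design = pd.read_csv(tmp_path / "d.tsv", sep="\t")
        design = design[design["array_id"] != "T2R2"]
        design.to_csv(tmp_path / "d.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="T2R2"):
            read_signal_tables(tmp_path / "s.tsv", tmp_path / "d.tsv")

    def test_duplicate_gene_id_rejected(self, tmp_path, tiny_matrix):
        write_signal_tables(tiny_matrix, tmp_path / "s.tsv", tmp_path / "d.tsv")
        lines = (tmp_path / "s.tsv").read_text().splitlines()
        lines.append(lines[1])  # repeat first gene row
        (tmp_path / "s.tsv").write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="duplicate gene_id"):
            read_signal_tables(tmp_path / "s.tsv", tmp_path / "d.tsv")

    def test_missing_encoded_as_na_not_zero(self, tiny_design):
        mask = np.zeros((1, 4), dtype=bool)
        mask[0, 0] = True
        sm = SignalMatrix(["g"], tiny_design, np.ones((1, 4)), np.ones((1, 4)), mask)
        import io as _io

        buf_s, buf_d = _io.StringIO(), _io.StringIO()
        write_signal_tables(sm, buf_s, buf_d)
        assert "NA" in buf_s.getvalue()


class TestKeggMap:
    def test_multiplicity(self, kegg_file):
        pmap = read_kegg_map_tsv(kegg_file)
        assert len(pmap) == 6
        assert pmap.pathways_of("g1") == ["00010", "00020"]

    def test_duplicate_row_collapsed(self, tmp_path, kegg_frame, caplog):
        df = pd.concat([kegg_frame, kegg_frame.iloc[[0]]])
        path = tmp_path / "k.tsv"
        df.to_csv(path, sep="\t", index=False)
        with caplog.at_level("WARNING", logger="germcourse.io"):
            pmap = read_kegg_map_tsv(path)
        assert len(pmap) == 6
        assert any("collapsed" in r.message for r in caplog.records)

    def test_pathway_in_two_groups_rejected(self, tmp_path, kegg_frame):
        kegg_frame.loc[2, "functional_group"] = "Energy metabolism"
        path = tmp_path / "k.tsv"
        kegg_frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="00010"):
            read_kegg_map_tsv(path)

    def test_group_gene_counts(self, kegg_file):
        pmap = read_kegg_map_tsv(kegg_file)
        counts = pmap.group_gene_counts()
        assert counts["Carbohydrate metabolism"] == 3  # g1, g2, g3
        assert counts["Energy metabolism"] == 2


class TestAnnotation:
    def _write(self, tmp_path, rows):
        path = tmp_path / "ann.tsv"
        pd.DataFrame(rows, columns=["gene_id", "product", "is_sigma_factor"]).to_csv(
            path, sep="\t", index=False
        )
        return path

    def test_sigma_factor_census(self, tmp_path):
        # the genome carries 45 annotated sigma factors
        rows = [(f"SCO{i:04d}", f"sigma factor {i}", 1) for i in range(45)]
        rows += [("SCO9000", "hypothetical protein", 0)]
        ann = read_annotation_tsv(self._write(tmp_path, rows))
        assert len(ann.sigma_factors) == 45

    def test_empty_table(self, tmp_path):
        ann = read_annotation_tsv(self._write(tmp_path, []))
        assert len(ann) == 0 and ann.sigma_factors == []

    def test_bad_boolean_token_names_row(self, tmp_path):
        path = self._write(tmp_path, [("g1", "p", 1), ("g2", "p", "maybe")])
        with pytest.raises(ValueError, match="row 3"):
            read_annotation_tsv(path)


class TestIntervalCalls:
    def test_interval_labels(self):
        assert interval_label(1) == "t1-t2"
        assert interval_label(12) == "t12-t13"

    def test_write_read_small(self, tmp_path):
        calls = IntervalCallSet(
            pd.DataFrame(
                {
                    "gene_id": ["g1", "g2"],
                    "interval": [2, 7],
                    "direction": ["enhanced", "diminished"],
                    "fold": [4.25, 0.21],
                    "p_value": [0.003, 0.049],
                }
            )
        )
        path = tmp_path / "calls.tsv"
        write_interval_calls_tsv(calls, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3 and lines[0].startswith("gene_id")
        assert "t2-t3" in lines[1]
        assert read_interval_calls_tsv(path) == calls

    def test_empty_set_header_only(self, tmp_path):
        path = tmp_path / "calls.tsv"
        write_interval_calls_tsv(IntervalCallSet(), path)
        assert len(path.read_text().splitlines()) == 1
        assert len(read_interval_calls_tsv(path)) == 0

    def test_round_trip_100_random_calls(self, tmp_path):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(100)]
        frame = pd.DataFrame(
            {
                "gene_id": genes,
                "interval": rng.integers(1, 13, size=100),
                "direction": rng.choice(["enhanced", "diminished"], size=100),
                "fold": np.exp(rng.normal(0, 2, size=100)),
                "p_value": rng.uniform(0, 0.05, size=100),
            }
        )
        calls = IntervalCallSet(frame)
        path = tmp_path / "calls.tsv"
        write_interval_calls_tsv(calls, path)
        back = read_interval_calls_tsv(path)
        a = calls.frame.sort_values(["gene_id", "interval"]).reset_index(drop=True)
        b = back.frame.sort_values(["gene_id", "interval"]).reset_index(drop=True)
        np.testing.assert_allclose(b["fold"], a["fold"], rtol=1e-11)
        np.testing.assert_allclose(b["p_value"], a["p_value"], rtol=1e-11)
        assert list(a["gene_id"]) == list(b["gene_id"])

    def test_one_direction_per_interval(self):
        frame = pd.DataFrame(
            {
                "gene_id": ["g1", "g1"],
                "interval": [2, 2],
                "direction": ["enhanced", "diminished"],
                "fold": [4.0, 0.2],
                "p_value": [0.01, 0.01],
            }
        )
        with pytest.raises(ValueError, match="at most one call"):
            IntervalCallSet(frame)

    def test_pathway_map_unique_pairs(self, kegg_frame):
        dup = pd.concat([kegg_frame, kegg_frame.iloc[[1]]])
        with pytest.raises(ValueError, match="unique"):
            PathwayMap(dup)
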