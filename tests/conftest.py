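import numpy as np
import pandas as pd
import pytest

from germcourse.datamodel import (
    ArrayInfo,
    ExperimentDesign,
    SignalMatrix,
    study_design,
)


@pytest.fixture
def tiny_design() -> ExperimentDesign:
    """Two time points x two replicates (4 arrays)."""
    arrays = tuple(
        ArrayInfo(f"T{t}R{r}", t, f"R{r}") for t in (1, 2) for r in (1, 2)
    )
    return ExperimentDesign(arrays, {1: "dormant", 2: "heat-activated"})


@pytest.fixture
def tiny_matrix(tiny_design) -> SignalMatrix:
    sample = np.array(
        [[8.0, 6.0, 10.0, 12.0],
         [2.0, 3.0, 2.5, 2.0],
         [100.0, 90.0, 110.0, 105.0]]
    )
    reference = np.full((3, 4), 2.0)
    return SignalMatrix(["gA", "gB", "gC"], tiny_design, sample, reference)


@pytest.fixture
def signal_files(tmp_path, tiny_matrix):
    """tiny_matrix written out as signals.tsv + design.tsv."""
    from germcourse.io import write_signal_tables

    signals = tmp_path / "signals.tsv"
    design = tmp_path / "design.tsv"
    write_signal_tables(tiny_matrix, signals, design)
    return signals, design


@pytest.fixture
def kegg_frame() -> pd.DataFrame:
    # one gene (g1) in two pathways; two functional groups
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g1", "g2", "g3", "g4", "g5"],
            "pathway_id": ["00010", "00020", "00010", "00020", "00030", "00030"],
            "pathway_name": [
                "Glycolysis", "TCA cycle", "Glycolysis", "TCA cycle",
                "Pentose phosphate", "Pentose phosphate",
            ],
            "functional_group": [
                "Carbohydrate metabolism", "Carbohydrate metabolism",
                "Carbohydrate metabolism", "Carbohydrate metabolism",
                "Energy metabolism", "Energy metabolism",
            ],
        }
    )


@pytest.fixture
def kegg_file(tmp_path, kegg_frame):
    path = tmp_path / "kegg_map.tsv"
    kegg_frame.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture(scope="session")
def full_design() -> ExperimentDesign:
    return study_design(n_replicates=4)
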