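import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from fragseq.io import (
    CountMatrix,
    FragmentExperiment,
    make_cell_annotation,
    make_fragment_table,
)


@pytest.fixture
def toy_experiment() -> FragmentExperiment:
    """3 fragments, 6 cells, 4 genes; consistent cross-references."""
    genes = ["g1", "g2", "g3", "g4"]
    cells = [f"c{i}" for i in range(1, 7)]
    rng = np.random.default_rng(42)
    counts = sp.csr_matrix(rng.poisson(3.0, size=(4, 6)))
    cm = CountMatrix(genes, cells, counts)
    ann = make_cell_annotation(
        cells,
        sample=["S1"] * 3 + ["S2"] * 3,
        fragment=["F1", "F1", "F2", "F2", "F3", "F3"],
        cell_type=["LEC", "KC", "LEC", "LEC", "KC", "metastatic"],
    )
    frags = make_fragment_table(
        ["F1", "F2", "F3"], sample=["S1", "S1", "S2"], tof=[400.0, 500.0, 600.0]
    )
    return FragmentExperiment(cm, ann, frags).recount_fragments()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture
def random_count_matrix(rng) -> CountMatrix:
    n_g, n_c = 30, 50
    dense = rng.poisson(0.8, size=(n_g, n_c))
    return CountMatrix(
        [f"gene{i}" for i in range(n_g)],
        [f"cell{i}" for i in range(n_c)],
        sp.csr_matrix(dense),
    )
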