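import numpy as np
import pandas as pd
import pytest

from crossdeg import ExpressionStudy, HomologMap, SimulationConfig


@pytest.fixture
def tiny_matrix():
    """4 genes × 6 samples with two clean group differences."""
    cols = ["c1", "c2", "c3", "t1", "t2", "t3"]
    data = np.array(
        [
            [5.0, 5.2, 4.8, 7.0, 7.2, 6.8],  # up ~2
            [8.0, 8.1, 7.9, 6.0, 6.1, 5.9],  # down ~2
            [6.0, 6.1, 5.9, 6.05, 6.0, 6.1],  # null
            [4.0, 4.2, 3.8, 4.1, 4.0, 3.9],  # null
        ]
    )
    return pd.DataFrame(data, index=["g1", "g2", "g3", "g4"], columns=cols)


@pytest.fixture
def tiny_study(tiny_matrix):
    samples = pd.DataFrame(
        {
            "group": ["control"] * 3 + ["case"] * 3,
            "time": [np.nan] * 3 + [6.0] * 3,
            "is_control": [True] * 3 + [False] * 3,
        },
        index=tiny_matrix.columns,
    )
    return ExpressionStudy(matrix=tiny_matrix, samples=samples, name="tiny")


@pytest.fixture
def small_config():
    """A small but fully featured two-species design for pipeline tests."""
    return SimulationConfig(
        n_genes_a=400,
        n_genes_b=500,
        n_shared=300,
        n_controls_a=4,
        n_per_group_a=4,
        n_controls_b=6,
        groups_b=(
            ("sepsis", 24.0, 6),
            ("sepsis", 72.0, 6),
            ("shock", 24.0, 6),
            ("shock", 72.0, 6),
        ),
        frac_shared_de=0.1,
        frac_exclusive_de=0.03,
        frac_discordant=0.01,
        effect_size=3.0,
        seed=7,
    )


@pytest.fixture
def toy_homolog_map():
    return HomologMap(
        probes_a=pd.DataFrame(
            {"probe_id": ["p1", "p2", "p3", "p4"], "gene_id": ["1", "1", "2", "3"]}
        ),
        probes_b=pd.DataFrame(
            {"probe_id": ["q1", "q2", "q3"], "gene_id": ["10", "20", "40"]}
        ),
        pairs=pd.DataFrame(
            {"gene_a": ["1", "2", "3"], "gene_b": ["10", "20", "30"]}
        ),
    )
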