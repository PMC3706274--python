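import numpy as np
import pandas as pd
import pytest

from xyloseq.io import ExpressionMatrix, GOMapping, RegulationTable


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """2 conditions x 2 replicates, 3 features, hand-pickable values."""
    values = pd.DataFrame(
        {
            "c_r1": [1.0, 10.0, 5.0],
            "c_r2": [1.0, 12.0, 5.0],
            "e_r1": [7.0, 11.0, 5.0],
            "e_r2": [7.0, 9.0, 5.0],
        },
        index=["gA", "gB", "gC"],
    )
    cond = {"c_r1": "ctl", "c_r2": "ctl", "e_r1": "exp", "e_r2": "exp"}
    return ExpressionMatrix(values=values, condition_of=cond)


@pytest.fixture
def small_regulation() -> RegulationTable:
    edges = pd.DataFrame(
        [
            ("A", "g1", "documented-direct"),
            ("A", "g2", "documented-direct"),
            ("A", "g3", "documented-indirect"),
            ("B", "g4", "documented-direct"),
            ("B", "g5", "documented-direct"),
            ("C", "g9", "documented-direct"),
        ],
        columns=["tf", "target", "evidence"],
    )
    return RegulationTable(edges=edges)


@pytest.fixture
def go_mapping() -> GOMapping:
    entries = pd.DataFrame(
        [
            ("g1", "GO:0000001", "process one"),
            ("g1", "GO:0000002", "process two"),
            ("g2", "GO:0000002", "process two"),
        ],
        columns=["gene", "go_id", "go_description"],
    )
    return GOMapping(entries=entries)


def random_expression_matrix(rng: np.random.Generator, n_features=4, r_ctl=2, r_exp=2):
    """Independent helper for randomized oracle tests."""
    feats = [f"f{i}" for i in range(n_features)]
    cols = [f"c{i}" for i in range(r_ctl)] + [f"e{i}" for i in range(r_exp)]
    vals = pd.DataFrame(
        rng.uniform(0, 40, size=(n_features, r_ctl + r_exp)), index=feats, columns=cols
    )
    cond = {c: ("ctl" if c.startswith("c") else "exp") for c in cols}
    return ExpressionMatrix(values=vals, condition_of=cond)
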