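import numpy as np
import pandas as pd
import pytest

from lymphagg.io import CellMap
from lymphagg.synthetic import TissueSimParams, generate_tissue


@pytest.fixture
def tiny_cellmap() -> CellMap:
    """Three cells with chemokine counts, hand-checkable."""
    df = pd.DataFrame({
        "cell_id": ["c1", "c2", "c3"],
        "x": [0.0, 50.0, 500.0],
        "y": [0.0, 0.0, 0.0],
        "cell_type": ["B", "T_CM", "tumor"],
        "CCL19": [1, 0, 0],
        "CXCL13": [0, 1, 0],
    })
    return CellMap(sample_id="tiny", cells=df)


@pytest.fixture(scope="session")
def small_tissue():
    """One deterministic synthetic tissue with 5 planted LAs."""
    params = TissueSimParams(seed=11, n_las=5, n_background=1500,
                             width=4000.0, height=4000.0)
    return generate_tissue(params)


def random_cellmap(rng: np.random.Generator, n: int = 200,
                   width: float = 1000.0, p_pos: float = 0.3) -> CellMap:
    """Random cells with random chemokine positivity for oracle tests."""
    types = np.array(["B", "PC", "T_CM", "tumor"])
    df = pd.DataFrame({
        "cell_id": [f"r{i:04d}" for i in range(n)],
        "x": rng.uniform(0, width, n),
        "y": rng.uniform(0, width, n),
        "cell_type": rng.choice(types, n),
        "CCL19": (rng.uniform(size=n) < p_pos).astype(int),
        "CXCL13": (rng.uniform(size=n) < p_pos).astype(int),
    })
    return CellMap(sample_id="rand", cells=df)
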