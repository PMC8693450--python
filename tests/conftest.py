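import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dysbindex.io_formats import CohortMetadata, FeatureTable, read_tree

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def counts_table() -> FeatureTable:
    data = pd.DataFrame(
        [[10, 0, 5], [3, 7, 0], [2, 2, 4], [0, 6, 6]],
        index=["S1", "S2", "S3", "S4"],
        columns=["A", "B", "C"],
    )
    return FeatureTable(data, unit="counts")


@pytest.fixture
def small_meta() -> CohortMetadata:
    frame = pd.DataFrame(
        {"group": ["control", "control", "T2D", "T2D"]},
        index=["S1", "S2", "S3", "S4"],
    )
    return CohortMetadata(frame)


@pytest.fixture
def four_leaf_tree(tmp_path):
    path = tmp_path / "t.nwk"
    path.write_text("((A:1,B:1):1,(C:1,D:1):1);\n")
    return read_tree(path)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
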