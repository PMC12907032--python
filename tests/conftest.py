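import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from halo.core_io import CommunityTable


@pytest.fixture
def toy_table():
    """4 taxa × 4 samples with simple structure."""
    df = pd.DataFrame(
        [[10, 10, 10, 10],
         [20, 0, 0, 0],
         [0, 5, 5, 0],
         [3, 3, 3, 3]],
        index=["tA", "tB", "tC", "tD"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return CommunityTable(df)


@pytest.fixture
def cherry_tree():
    return TreeNode.read(["(A:1,B:1):0;"])


@pytest.fixture
def small_tree():
    return TreeNode.read(["((A:1,B:1):1,C:2):0;"])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
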