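import numpy as np
import pandas as pd
import pytest

from tsnba import GeneNetwork, GeneSet


@pytest.fixture
def toy_network() -> GeneNetwork:
    """5-gene network: path A-B-C plus triangle C-D-E (and C-E closing it)."""
    return GeneNetwork.from_edges(
        [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("C", "E")]
    )


@pytest.fixture
def toy_expression() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    genes = list("ABCDE")
    samples = [f"s{i}" for i in range(6)]
    values = rng.uniform(50, 500, size=(5, 6))
    return pd.DataFrame(values, index=genes, columns=samples)


@pytest.fixture
def benchmark_set() -> GeneSet:
    return GeneSet("benchmark", ["A", "C", "E"])
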