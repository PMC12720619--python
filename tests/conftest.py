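import numpy as np
import pandas as pd
import pytest

from omicnets import synth


@pytest.fixture(scope="session")
def small_annotation():
    """20 genes (10 TFs) on two chromosomes with 3 probes each."""
    return synth.generate_annotation(n_genes=20, n_tf=10, probes_per_gene=3, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def counts_matrix():
    """A small raw-count matrix with two vials for one subject."""
    cols = ["SUBJ0-V1", "SUBJ0-V2", "SUBJ1-V1", "SUBJ2-V1"]
    data = np.array(
        [
            [10, 20, 5, 0],
            [30, 60, 15, 0],
            [0, 0, 100, 1],
            [5, 10, 2, 3],
        ]
    )
    return pd.DataFrame(data, index=[f"g{i}" for i in range(4)], columns=cols)
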