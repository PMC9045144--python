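import numpy as np
import pandas as pd
import pytest

from cstnet.io import AbundanceTable


@pytest.fixture
def tiny_table() -> AbundanceTable:
    """4 samples x 3 species, two duplicated compositional patterns."""
    data = pd.DataFrame(
        [
            [0.7, 0.2, 0.1],
            [0.7, 0.2, 0.1],
            [0.1, 0.2, 0.7],
            [0.1, 0.2, 0.7],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["spA", "spB", "spC"],
    )
    return AbundanceTable(data)


@pytest.fixture
def tiny_metadata() -> pd.DataFrame:
    meta = pd.DataFrame(
        {"group": ["athlete", "athlete", "non_athlete", "non_athlete"]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    meta["group"] = meta["group"].astype("category")
    return meta


def three_mode_table(n_per_mode=10, n_species=30, seed=0):
    """Samples drawn from 3 well-separated Dirichlet modes, plus true labels."""
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for mode in range(3):
        alpha = np.full(n_species, 0.2)
        alpha[mode * 3 : mode * 3 + 3] = 40.0
        blocks.append(rng.dirichlet(alpha, size=n_per_mode))
        labels += [mode] * n_per_mode
    values = np.vstack(blocks)
    ids = [f"s{i}" for i in range(values.shape[0])]
    cols = [f"sp{j}" for j in range(n_species)]
    return AbundanceTable(pd.DataFrame(values, index=ids, columns=cols)), np.array(labels)
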