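import numpy as np
import pytest

from sccalink import SyntheticSpec, generate_blocks, prepare_block
from sccalink.scca import DataBlock


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def make_block(X, prefix="v", ids=None, standardize=True) -> DataBlock:
    names = [f"{prefix}{j}" for j in range(X.shape[1])]
    ids = list(range(X.shape[0])) if ids is None else list(ids)
    if standardize:
        return prepare_block(X, names, ids)
    return DataBlock(np.asarray(X, float), names, ids, state="raw")


@pytest.fixture
def planted_pair():
    """Standardized block pair with one planted mode (r = 0.7, n = 200)."""
    spec = SyntheticSpec(n_participants=200, seed=11)
    b1, b2, cov, truth = generate_blocks(spec)
    p1 = prepare_block(b1.matrix, b1.variable_names, b1.participant_ids)
    p2 = prepare_block(b2.matrix, b2.variable_names, b2.participant_ids)
    return p1, p2, truth
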