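import numpy as np
import pytest

from ibnra.network import BipartiteNetwork
from ibnra.synthetic import PlantedBlockSpec, generate_dataset


def make_net(I, protein_ids=None, lncrna_ids=None) -> BipartiteNetwork:
    I = np.asarray(I, dtype=float)
    protein_ids = protein_ids or [f"p{i+1}" for i in range(I.shape[0])]
    lncrna_ids = lncrna_ids or [f"l{j+1}" for j in range(I.shape[1])]
    return BipartiteNetwork(protein_ids, lncrna_ids, I)


def random_binary_network(rng, max_n=8, min_n=2):
    """A random binary interaction matrix with no all-zero rows/columns."""
    while True:
        n_p = rng.integers(min_n, max_n + 1)
        n_l = rng.integers(min_n, max_n + 1)
        I = (rng.random((n_p, n_l)) < 0.5).astype(float)
        if I.sum(axis=0).min() > 0 and I.sum(axis=1).min() > 0:
            return I


@pytest.fixture(scope="session")
def planted():
    """Default planted-block dataset: network, expression, PPI, blocks."""
    return generate_dataset(PlantedBlockSpec(seed=1))


@pytest.fixture
def tiny_net():
    """2 proteins x 2 lncRNAs; p2 interacts only with l2."""
    return make_net([[1, 1], [0, 1]])
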