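import numpy as np
import pytest

from phylohex import fixtures
from phylohex.hexgrid import PresenceMatrix


@pytest.fixture(scope="session")
def toy():
    """The worked 4-tip / 3-cell example with hand-computed index values."""
    return fixtures.toy_example()


def random_instance(seed, n_tips=10, n_cells=8):
    """Random (tree, PresenceMatrix, tip map, label cells) for oracle tests.

    Every cell holds at least one species and every species occupies at
    least one cell, so all indices are defined.
    """
    rng = np.random.default_rng(seed)
    tree = fixtures.gen_tree(n_tips, seed=seed)
    while True:
        A = rng.random((n_cells, n_tips)) < rng.uniform(0.2, 0.6)
        if A.any(axis=1).all() and A.any(axis=0).all():
            break
    cells = np.sort(rng.choice(np.arange(10**6, 10**7), size=n_cells, replace=False)).astype(np.uint64)
    species = np.arange(1, n_tips + 1, dtype=np.int64)
    records = A.sum(axis=1) + rng.integers(1, 4, n_cells)
    matrix = PresenceMatrix(4, cells, species, A, records)
    tip_to_key = fixtures.tip_key_map(tree)
    # label view of the incidence for the brute-force oracles
    key_to_label = {v: k for k, v in tip_to_key.items()}
    label_cells = {
        int(c): {key_to_label[int(k)] for k in species[A[i]]}
        for i, c in enumerate(cells)
    }
    return tree, matrix, tip_to_key, label_cells
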