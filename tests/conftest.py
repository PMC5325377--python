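import numpy as np
import pytest

from clonelines import (GenotypeMatrix, SimConfig, hg3_config, hg3_tree,
                        simulate_single_cell_clones)


@pytest.fixture(scope="session")
def hg3():
    """HG3 preset: tree, 60-clone genotype matrix, truth labels."""
    tree = hg3_tree()
    cfg = hg3_config(seed=11)
    matrix, labels = simulate_single_cell_clones(tree, cfg)
    return tree, cfg, matrix, labels


def make_matrix(rows, mutation_ids=None, wt=None):
    """Genotype matrix from a list of 0/1/-1 rows (clones)."""
    rows = np.asarray(rows, dtype=np.int8)
    n_clones, n_mut = rows.shape
    return GenotypeMatrix(
        clone_ids=tuple(f"c{i}" for i in range(n_clones)),
        mutation_ids=tuple(mutation_ids or (f"m{j}" for j in range(n_mut))),
        calls=rows,
        wt_detected=wt,
    )
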