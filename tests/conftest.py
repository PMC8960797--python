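import numpy as np
import pandas as pd
import pytest

from traitatlas import SyntheticSpec, TraitMatrix, gen_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Noiseless planted dataset: recovery must be exact."""
    spec = SyntheticSpec(
        n_genomes=40, n_traits=48, n_gfc_blocks=4, n_ltc_blocks=4,
        block_trait_occupancy=1.0, background_occupancy=0.0,
        annotation_dropout=0.0, taxon_concordance=1.0, seed=11,
    )
    return gen_dataset(spec)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Moderately noisy planted dataset at reduced scale."""
    spec = SyntheticSpec(
        n_genomes=60, n_traits=80, n_gfc_blocks=4, n_ltc_blocks=5,
        annotation_dropout=0.1, taxon_concordance=0.9, seed=13,
    )
    return gen_dataset(spec)


@pytest.fixture
def tiny_matrix():
    """Hand-built 5 genomes x 6 traits matrix, 3 interaction-flagged."""
    values = np.array(
        [
            [1, 1, 0, 0, 1, 0],
            [1, 0, 1, 0, 0, 0],
            [0, 1, 1, 1, 0, 1],
            [0, 0, 0, 1, 1, 1],
            [1, 1, 1, 1, 1, 1],
        ],
        dtype=np.int8,
    )
    traits = [f"kegg_module:M{i}" for i in range(6)]
    meta = pd.DataFrame(
        {
            "category": "kegg_module",
            "interaction": [True, True, False, True, False, False],
            "substrate": "",
            "role": "",
        },
        index=pd.Index(traits, name="trait_id"),
    )
    return TraitMatrix(values, [f"g{i}" for i in range(5)], traits, meta)
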