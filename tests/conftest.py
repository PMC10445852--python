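import numpy as np
import pytest

from annotqc.synthetic_data import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Desk-scale config with noise switched off for exact-recovery tests."""
    return SimConfig(
        seed=7,
        n_scaffolds=4,
        scaffold_len_range=(20_000, 30_000),
        satellite_array_counts=(5,),
        satellite_identity_range=(1.0, 1.0),
        mito_len=2_000,
        n_genes=40,
        n_contigs=40,
        n_orthologs=60,
        n_hom_scaffolds=3,
        score_noise=0.0,
    )
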