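import numpy as np
import pytest

from oncostump.io import Msa
from oncostump.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240729)


@pytest.fixture
def toy_msa():
    # 5 sequences, 8 columns; column 0 fully conserved, column 7 gappy
    return Msa(
        ids=[f"s{i}" for i in range(5)],
        rows=[
            "ACDEFGHI",
            "ACDEFGHI",
            "ACDEYGH-",
            "ACKEFAH-",
            "ACDWFGK-",
        ],
    )


@pytest.fixture
def small_dataset():
    return generate_dataset(
        SyntheticConfig(n_oncogenic=60, n_benign=60, n_proteins=10,
                        positions_per_protein=8, seed=11)
    )
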