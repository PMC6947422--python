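import numpy as np
import pytest

from seqbind.dataset import LabeledDataset
from seqbind.features import FeatureConfig
from seqbind.simulate import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """Four short synthetic proteins with strong PSSM + PSA signal."""
    cfg = SimConfig(n_proteins=4, length_range=(30, 60), positive_rate=0.1,
                    patch_len_range=(3, 6), effect_size=4.0, n_signal_cols=6,
                    psa_effect=0.4, noise_sd=2.0, seed=7)
    records, pssms, psas = simulate_dataset(cfg)
    return cfg, records, pssms, psas


@pytest.fixture
def imbalanced_ds(rng):
    """300-row 5-feature dataset at roughly 1:9 imbalance."""
    X = rng.normal(size=(300, 5))
    y = np.zeros(300, dtype=int)
    y[rng.choice(300, size=30, replace=False)] = 1
    return LabeledDataset(X=X, y=y)


@pytest.fixture
def default_cfg():
    return FeatureConfig()
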