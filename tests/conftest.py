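import numpy as np
import pandas as pd
import pytest

from spongenet.io_formats import CountMatrix, SampleSheet
from spongenet.synthdata import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated study reused by read-only tests."""
    cfg = SimConfig(
        seed=7, n_samples_per_group=6, n_mrna=120, n_lncrna=60, n_mirna=80,
        n_de_per_class=10, n_modules=1, module_size=30, n_triplets=2,
        shared_mirnas_per_triplet=12,
    )
    return generate_dataset(cfg)


@pytest.fixture
def tiny_counts():
    """3 features x 4 samples with both groups, hand-checkable numbers."""
    counts = pd.DataFrame(
        [[10, 12, 40, 44], [5, 6, 20, 22], [100, 110, 90, 95]],
        index=["f1", "f2", "f3"],
        columns=["N1", "N2", "PP1", "PP2"],
    )
    cm = CountMatrix(counts=counts, rna_class="mrna")
    sheet = SampleSheet(table=pd.DataFrame({
        "sample_id": ["N1", "N2", "PP1", "PP2"],
        "group": ["normal", "normal", "PP", "PP"],
    }))
    return cm, sheet


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
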