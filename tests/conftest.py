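import numpy as np
import pytest

from succinet.seqdata import balance_undersample, build_site_dataset
from succinet.synthgen import SynthConfig, generate


@pytest.fixture(scope="session")
def small_synth():
    """Small synthetic dataset shared by fast tests (~25 proteins)."""
    cfg = SynthConfig(n_proteins=25, length_range=(80, 120), plm_width=16,
                      positive_fraction=0.45, seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def small_records(small_synth):
    positives = [(p, q) for p, q, lab in small_synth.site_labels if lab == 1]
    records = build_site_dataset(small_synth.proteins, positives)
    return balance_undersample(records, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
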