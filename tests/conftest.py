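import numpy as np
import pytest

from shapsel import io_prep, syndata


@pytest.fixture(scope="session")
def small_dataset():
    """60 samples, 80 + 20 features, strong planted signal."""
    cfg = syndata.SynthConfig(
        n_samples=60,
        n_mrna=80,
        n_mirna=20,
        n_informative_mrna=8,
        n_informative_mirna=2,
        effect_size=2.0,
        noise_sd=1.0,
        seed=11,
    )
    return syndata.generate_dataset(cfg)


@pytest.fixture
def toy_block():
    """4 features x 6 samples with hand-set values."""
    values = np.array(
        [
            [1.0, 3.0, 5.0, 2.0, 4.0, 6.0],
            [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
            [0.0, 0.0, 1.0, 9.0, 10.0, 11.0],
            [2.0, 2.0, 2.0, 8.0, 8.0, 8.0],
        ]
    )
    return io_prep.ExpressionBlock(
        ["fA", "fB", "fC", "fD"], [f"s{i}" for i in range(6)], values, "mRNA"
    )


@pytest.fixture
def toy_labels():
    return io_prep.SampleLabels([f"s{i}" for i in range(6)], np.array([0, 0, 0, 1, 1, 1]))
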