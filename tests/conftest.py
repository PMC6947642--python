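import numpy as np
import pytest

from cpgselect.data import MethylationDataset
from cpgselect.synth import SynthConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_dataset():
    """3 samples x 2 sites, ages 1/5/9, no missing cells."""
    return MethylationDataset(
        sample_ids=["a", "b", "c"],
        site_ids=["cg1", "cg2"],
        beta=np.array([[0.1, 0.9], [0.2, 0.8], [0.3, 0.7]]),
        age=np.array([1.0, 5.0, 9.0]),
    )


@pytest.fixture
def small_cohort():
    """Low-noise cohort with 4 planted sites among 40, n=60."""
    cfg = SynthConfig(
        n_samples=60, n_sites=40, n_informative=4,
        noise_sd_per_regime=(0.01, 0.01, 0.01), seed=42,
    )
    return generate_cohort(cfg)


def make_matrix_file(path, text):
    path.write_text(text)
    return path
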