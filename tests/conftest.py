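import hypothesis
import numpy as np
import pytest

from l1l2sig import LabeledDataset, SyntheticSpec, generate_dataset

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_strong_dataset():
    """Small, strongly separable two-class dataset with known signal."""
    spec = SyntheticSpec(n_samples=60, n_variables=40, block_size=4,
                         n_blocks=4, within_block_corr=0.5, n_informative=5,
                         effect_size=2.0, seed=7)
    return generate_dataset(spec)


@pytest.fixture
def tiny_dataset():
    X = np.array([[1.0, 2.0], [3.0, 0.5], [2.0, 1.0], [0.0, 3.0]])
    y = np.array([1.0, -1.0, 1.0, -1.0])
    return LabeledDataset(X, y, ["vA", "vB"], ["s1", "s2", "s3", "s4"])
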