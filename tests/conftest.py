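import numpy as np
import pytest

from enrichopt import BenchmarkConfig, DescriptorDataset, generate_benchmark, zscore_normalize


@pytest.fixture
def toy_dataset() -> DescriptorDataset:
    """6 compounds x 3 descriptors with labels and pKi, no set structure."""
    rng = np.random.default_rng(11)
    X = rng.normal(size=(6, 3))
    return DescriptorDataset(
        compound_ids=[f"c{i}" for i in range(6)],
        X=X,
        descriptor_names=["d0", "d1", "d2"],
        activity=np.array([8.5, 8.2, 5.5, 5.0, 6.0, 5.2]),
        labels=np.array([1, 1, 0, 0, 0, 0]),
    )


@pytest.fixture(scope="session")
def small_bench():
    """Scaled-down screening benchmark: 20/100 train+valid, 20 actives + 400 decoys test."""
    cfg = BenchmarkConfig(
        n_descriptors=15,
        k_informative=4,
        n_active_train=20,
        n_inactive_train=100,
        n_active_valid=20,
        n_inactive_valid=100,
        n_active_test=20,
        n_decoys=400,
        effect_size=3.0,
        noise_sd=0.3,
        seed=77,
    )
    return generate_benchmark(cfg)


@pytest.fixture(scope="session")
def small_train(small_bench):
    """Normalized training subset of the session benchmark."""
    normed, params = zscore_normalize(small_bench.dataset)
    return normed.subset("train")
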