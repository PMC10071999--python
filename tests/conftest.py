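import numpy as np
import pytest

from bitbrain import pipeline as pl
from bitbrain import sampling as sp
from bitbrain import synthetic_data as sd


@pytest.fixture(scope="session")
def small_benchmark():
    """10-class disc benchmark at reduced size: 50 train / 20 test per class."""
    return sd.default_benchmark(
        n_classes=10, n_train_per_class=50, n_test_per_class=20, seed=0
    )


@pytest.fixture(scope="session")
def ink_target(small_benchmark):
    train, _ = small_benchmark
    return sp.sqrt_transform(sp.accumulate_global_distribution(train.images))


@pytest.fixture(scope="session")
def tiny_model(small_benchmark):
    """A small trained model (3 ADs, w=128) shared by read-only tests."""
    train, _ = small_benchmark
    return pl.train(pl.three_ad_config(w=128), train)
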