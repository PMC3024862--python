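import warnings

import numpy as np
import pytest

from regmine import synthetic


@pytest.fixture(scope="session")
def benchmark_frame():
    """The standard labeled benchmark (300 pos / 300 neg, seed 42)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic.benchmark_dataset(seed=42)


@pytest.fixture(scope="session")
def wide_benchmark_frame():
    """Benchmark variant with a 1:7 negative surplus for ratio sweeps."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic.benchmark_dataset(n_pos=300, n_neg=2100, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def write_tsv(path, text):
    path.write_text(text.replace(" | ", "\t"))
    return path
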