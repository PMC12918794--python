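import numpy as np
import pandas as pd
import pytest

from chromdep.io_model import DependencyMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dep(rng) -> DependencyMatrix:
    """20 cell lines x 50 genes of uniform dependency values."""
    values = rng.uniform(0, 1, size=(20, 50))
    return DependencyMatrix(pd.DataFrame(
        values,
        index=[f"cl{i:02d}" for i in range(20)],
        columns=[f"G{j:04d}" for j in range(50)],
    ))


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Full synthetic input bundle, generated once per session."""
    from chromdep.synthetic import generate_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    truth = generate_bundle(outdir, seed=7)
    return outdir, truth
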