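import numpy as np
import pytest

from emdav.dataset import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """10 samples x 8 features, three planted all-zero columns."""
    rng = np.random.default_rng(0)
    x = rng.lognormal(1.0, 0.5, size=(10, 8)) + 2.0
    x[:, [1, 4, 6]] = 0.0
    y = rng.uniform(1.0, 5.0, size=10)
    return ExpressionDataset(values=x,
                             feature_ids=tuple(f"f{i}" for i in range(8)),
                             target=y, target_id="t")
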