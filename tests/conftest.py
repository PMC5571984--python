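import numpy as np
import pytest

from tdfe import MultiViewSet, SyntheticConfig, ViewMatrix, generate_two_view


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_view(values, name="view"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ViewMatrix(
        values,
        feature_ids=[f"f{i + 1}" for i in range(n)],
        sample_ids=[f"s{j + 1}" for j in range(m)],
        name=name,
    )


def random_case1_set(rng, shapes, m_samples):
    """Random Case I views: one (n_k x m_samples) matrix per entry of shapes."""
    views = [
        make_view(rng.normal(size=(n, m_samples)), name=f"view{k + 1}")
        for k, n in enumerate(shapes)
    ]
    return MultiViewSet(views, case="shared_samples")


@pytest.fixture
def small_synthetic():
    """A small, fast instance of the two-view benchmark."""
    return generate_two_view(
        SyntheticConfig(c=0.8, n_features=120, n_signal=20, n_samples=30,
                        seed=7)
    )
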