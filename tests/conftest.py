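import numpy as np
import pytest

from kadaif import CommunitySpec, FeatureTable, generate_communities


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """20 sparse compositional samples x 40 taxa."""
    vals = rng.gamma(0.3, size=(20, 40))
    vals[rng.random((20, 40)) < 0.5] = 0.0
    vals /= vals.sum(axis=1, keepdims=True)
    return FeatureTable([f"s{i}" for i in range(20)], [f"t{j}" for j in range(40)], vals)


@pytest.fixture
def outlier_table():
    """21 samples: one composition duplicated (with jitter) 20x plus one
    far outlier living on disjoint taxa."""
    rng = np.random.default_rng(7)
    base = np.zeros(30)
    base[:15] = rng.dirichlet(np.full(15, 5.0))
    rows = np.clip(base + rng.normal(0, 1e-3, size=(20, 30)), 0, None)
    rows[:, 15:] = 0.0
    outlier = np.zeros(30)
    outlier[15:] = rng.dirichlet(np.full(15, 5.0))
    vals = np.vstack([rows, outlier])
    vals /= vals.sum(axis=1, keepdims=True)
    ids = [f"n{i}" for i in range(20)] + ["outlier"]
    return FeatureTable(ids, [f"t{j}" for j in range(30)], vals)


@pytest.fixture(scope="session")
def community_pair():
    """A modest normal/anomalous source pair with disjoint support."""
    spec = CommunitySpec(n_taxa=120, sparsity=0.4, sample_log_sd=0.4,
                         anomaly_support_fraction=0.2, seed=11)
    return generate_communities(spec, 80, 30)
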