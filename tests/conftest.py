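import io

import numpy as np
import pytest

from wkelm.data import FEATURE_NAMES, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable_toy():
    """Two well-separated Gaussian clusters in 4-D; linearly separable."""
    rng = np.random.default_rng(7)
    n = 30
    X = np.vstack(
        [
            rng.normal(loc=-3.0, scale=0.3, size=(n // 2, 4)),
            rng.normal(loc=3.0, scale=0.3, size=(n - n // 2, 4)),
        ]
    )
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    return X, y


@pytest.fixture
def rings():
    """Concentric 2-class rings (n=120): separable only by a kernel with a
    suitable local width, not by any linear rule."""
    rng = np.random.default_rng(0)
    n = 120
    radius = np.where(np.arange(n) < n // 2, 1.0, 3.0)
    theta = rng.uniform(0, 2 * np.pi, n)
    X = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    X += 0.1 * rng.standard_normal((n, 2))
    y = (np.arange(n) >= n // 2).astype(int)
    return X, y


@pytest.fixture
def sim_dataset():
    return simulate_dataset(SimConfig(n_samples=120, effect_size=1.5, seed=11))


@pytest.fixture
def uci_csv(tmp_path):
    """A tiny 3-row file in the UCI Parkinson's dialect with all 22 columns."""
    rng = np.random.default_rng(3)
    header = "name," + ",".join(FEATURE_NAMES) + ",status"
    rows = []
    for i, status in enumerate((1, 0, 1)):
        values = ",".join(f"{v:.5f}" for v in rng.uniform(0.1, 200.0, len(FEATURE_NAMES)))
        rows.append(f"phon_R01_S{i:02d}_1,{values},{status}")
    path = tmp_path / "parkinsons.csv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path
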