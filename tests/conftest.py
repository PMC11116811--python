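import numpy as np
import pandas as pd
import pytest

from cmsffpe import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A fast cohort: 60 samples, 20 genes per module + 40 background."""
    sizes = {"immune": 20, "epithelial": 20, "metabolic": 20, "stromal": 20,
             "background": 40}
    return SimConfig(n_samples=60, module_sizes=sizes, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_expr() -> pd.DataFrame:
    """4 genes x 5 samples, distinct values so pair encodings are tie-free."""
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.uniform(1, 100, size=(4, 5)),
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(5)],
    )
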