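import numpy as np
import pandas as pd
import pytest

from coexnet.simulate import SynthConfig, generate_expression


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = SynthConfig(
        n_genes=120,
        n_control=80,
        n_case=60,
        module_sizes=(30, 30),
        seed=42,
    )
    expr, meta, truth = generate_expression(cfg)
    return cfg, expr, meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_frame(arr, prefix_r="g", prefix_c="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix_r}{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix_c}{j}" for j in range(arr.shape[1])],
    )
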