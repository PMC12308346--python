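import numpy as np
import pandas as pd
import pytest

from countersignal import make_qc_fixture, series_2


@pytest.fixture(scope="session")
def qc_fixture() -> pd.DataFrame:
    return make_qc_fixture()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_series():
    """A small simulated series shared by pipeline-level tests."""
    from countersignal import simulate_experiment
    cfg = series_2(n_per_arm=10, seed=42)
    return cfg, *simulate_experiment(cfg)


def paired_lognormal(rng, n, sigma=1.15, shift=0.0):
    """Paired (baseline, post) rates with within-male tracking."""
    base = rng.lognormal(0.0, sigma, n)
    post = base * rng.lognormal(shift, 0.3, n)
    return base, post
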