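import numpy as np
import pytest

from shrinktune import Dataset, main_scenario


@pytest.fixture(scope="session")
def main_scn():
    return main_scenario()


def make_logistic_dataset(n=60, p=3, seed=0, beta=None, intercept=0.0):
    """Small logistic dataset with known coefficients (test helper)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if beta is None:
        beta = np.linspace(1.0, 0.2, p)
    prob = 1.0 / (1.0 + np.exp(-(intercept + X @ beta)))
    y = (rng.random(n) < prob).astype(float)
    if y.min() == y.max():  # pragma: no cover - seeds below avoid this
        raise RuntimeError("degenerate draw; pick another seed")
    return Dataset(X, y)


@pytest.fixture
def tiny_dataset():
    return make_logistic_dataset(n=60, p=3, seed=42)


@pytest.fixture
def two_by_two():
    """2x2 table as a dataset: cells (y=1,x=1)=20, (y=1,x=0)=10,
    (y=0,x=1)=10, (y=0,x=0)=20; MLE slope is log(20*20/(10*10)) = log 4."""
    x = np.concatenate([np.ones(30), np.zeros(30)])[:, None]
    y = np.concatenate([np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)])
    return Dataset(x, y)
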