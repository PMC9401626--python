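import numpy as np
import pytest

from tcellopt.doe import FactorSpec, make_ccd


@pytest.fixture(scope="session")
def six_factors():
    """Six cytokine-like factors with log-spanning concentration ranges."""
    names = ["SCF", "FLT3L", "TPO", "IL7", "IL3", "TNFa"]
    lows = [0.001, 0.005, 0.002, 0.001, 0.0005, 0.0001]
    highs = [0.1, 0.02, 0.05, 0.1, 0.01, 0.005]
    return [
        FactorSpec(n, lo, hi, units="ug/ml") for n, lo, hi in zip(names, lows, highs)
    ]


@pytest.fixture(scope="session")
def ccd6(six_factors):
    return make_ccd(six_factors, alpha=2.366, n_center=8)


@pytest.fixture(scope="session")
def two_factors():
    return [FactorSpec("A", 0.005, 0.02), FactorSpec("B", 0.1, 1.0)]


@pytest.fixture(scope="session")
def ccd2(two_factors):
    return make_ccd(two_factors, alpha=1.414, n_center=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
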