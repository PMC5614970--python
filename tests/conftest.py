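import numpy as np
import pytest

import mlcfa


@pytest.fixture(scope="session")
def pop03():
    """Generating model at factor ICC = 0.3."""
    return mlcfa.with_icc(mlcfa.harter_population(), 0.3)


@pytest.fixture(scope="session")
def small_sample(pop03):
    """A tiny balanced sample (12 clusters of 5) for exact-arithmetic tests."""
    cond = mlcfa.SimulationCondition(12, 5, 0.3, seed=101)
    return mlcfa.generate_dataset(pop03, cond, 0)


@pytest.fixture(scope="session")
def medium_sample(pop03):
    """A moderate sample (60 clusters of 20) for estimation behavior tests."""
    cond = mlcfa.SimulationCondition(60, 20, 0.3, seed=42)
    return mlcfa.generate_dataset(pop03, cond, 0)


@pytest.fixture(scope="session")
def medium_moments(medium_sample):
    return mlcfa.compute_moments(medium_sample)


@pytest.fixture(scope="session")
def medium_fits(medium_moments):
    """All five specifications fitted to the medium sample."""
    ref2 = mlcfa.reference_info(medium_moments, False)
    out = {}
    for name in mlcfa.MODEL_SPEC_NAMES:
        out[name] = mlcfa.fit(name, medium_moments, reference=ref2)
    return out


@pytest.fixture(scope="session")
def big_sample(pop03):
    """One large sample (300 clusters of 200) for asymptotic checks."""
    cond = mlcfa.SimulationCondition(300, 200, 0.3, seed=7)
    return mlcfa.generate_dataset(pop03, cond, 0)


def rel_err(a, b):
    return np.max(np.abs(np.asarray(a) - np.asarray(b))
                  / (1.0 + np.abs(np.asarray(b))))
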