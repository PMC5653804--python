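import numpy as np
import pytest

from rtrisk.cohort import SynthConfig, generate_cohort
from rtrisk.dvh import DVH


@pytest.fixture(scope="session")
def small_cohort():
    """64-patient synthetic cohort (emulated-study scale), fixed seed."""
    return generate_cohort(SynthConfig(n_per_arm=32), seed=101)


@pytest.fixture(scope="session")
def medium_cohort():
    """300-patient synthetic cohort for selection/fit checks."""
    return generate_cohort(SynthConfig(n_per_arm=150), seed=202)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dvh(rng, nbins=None, organ="organ", max_dose=70.0):
    """Random valid differential DVH for property tests."""
    nbins = nbins or int(rng.integers(2, 30))
    edges = np.sort(rng.uniform(0.5, max_dose, size=nbins))
    edges = np.concatenate([[0.0], np.unique(edges)])
    vals = rng.gamma(1.0, 1.0, size=edges.size - 1)
    vals = 100.0 * vals / vals.sum()
    return DVH(organ, "differential", edges, vals)
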