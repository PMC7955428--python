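import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """One RRI-backed cohort reused by read-only survival/QC tests."""
    from disten.synth import CohortGenParams, generate_cohort

    return generate_cohort(CohortGenParams(n_subjects=2500, seed=11))


def random_rri_series(rng, n=None, low=30, high=150):
    """A plausible random RRI series with mixed dynamics."""
    if n is None:
        n = int(rng.integers(low, high + 1))
    t = np.arange(n)
    x = (
        850.0
        + rng.normal(0, rng.uniform(2, 30), n)
        + rng.uniform(0, 30) * np.sin(2 * np.pi * t / rng.uniform(3.5, 6.0))
    )
    return np.clip(x, 428.0, 2000.0)
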