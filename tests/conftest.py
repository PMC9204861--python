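import numpy as np
import pandas as pd
import pytest

import sepsis_audit as sa


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient reference-calibrated cohort for cheap structural tests."""
    return sa.generate_cohort(sa.default_spec(400, seed=7))


@pytest.fixture(scope="session")
def large_null_cohort():
    """A 50,000-patient exchangeable-null cohort (no calibration targets)."""
    spec = sa.null_spec(50_000, subgroup_share=0.2)
    import dataclasses

    spec = dataclasses.replace(spec, seed=13)
    return sa.generate_cohort(spec)


@pytest.fixture(scope="session")
def large_calibrated_cohort():
    """A 50,000-patient cohort calibrated to the packaged summary table."""
    return sa.generate_cohort(sa.default_spec(50_000, seed=29))


def random_score_label_fixture(rng, n, informative=True):
    labels = (rng.random(n) < 0.4).astype(int)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[0] = 0
    noise = rng.normal(size=n)
    scores = labels + noise if informative else noise
    return scores, labels
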