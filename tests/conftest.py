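import numpy as np
import pytest

from homacut import GeneratorConfig, HomaCutoffModel, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort with its latent truth."""
    return generate_cohort(GeneratorConfig(seed=101))


@pytest.fixture(scope="session")
def small_cohort():
    """A 500-subject cohort for cheaper tests."""
    return generate_cohort(GeneratorConfig(n=500, seed=11))


@pytest.fixture(scope="session")
def recovery_runs():
    """End-to-end pipeline runs over 25 seeds at default generator settings.

    Yields per-seed tuples (agreement, fitted cutoff, oracle cutoff,
    max scan MCC), shared by the recovery and calibration tests.
    """
    out = []
    for seed in range(25):
        cohort, truth = generate_cohort(GeneratorConfig(seed=seed))
        res = HomaCutoffModel(cohort).fit(seed=seed)
        a = float(np.mean(res.assignment.is_resistant.astype(int) == truth.latent_label))
        out.append((max(a, 1.0 - a), res.cutoff, truth.oracle_cutoff, res.mcc))
    return out
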