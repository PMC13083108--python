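import dataclasses
import warnings

import pytest

from vcipreterm import growth_reference, synthetic_cohort


@pytest.fixture(scope="session")
def sim_config():
    return dataclasses.replace(synthetic_cohort.SimConfig(), seed=7)


@pytest.fixture(scope="session")
def cohort_mid(sim_config):
    """Default-size cohort, midtrimester visit only."""
    return synthetic_cohort.generate_cohort(sim_config)


@pytest.fixture(scope="session")
def cohort(sim_config, cohort_mid):
    """Default-size cohort with the predelivery visit attached."""
    return synthetic_cohort.attach_late_visit(cohort_mid, sim_config)


@pytest.fixture(scope="session")
def curves(cohort):
    return growth_reference.fit_reference_curves(cohort[cohort["group"] == "control"])


@pytest.fixture(scope="session")
def scored(cohort, curves):
    return growth_reference.score_cohort(cohort, curves)


@pytest.fixture(scope="session")
def scored_vci(scored):
    return scored[scored["group"] == "vci"].reset_index(drop=True)


@pytest.fixture(scope="session")
def scored_controls(scored):
    return scored[scored["group"] == "control"].reset_index(drop=True)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """Model pipelines on small resamples emit expected statistical warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        yield
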