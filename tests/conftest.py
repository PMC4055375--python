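import pytest

from treatthresh import SimulationConfig, build_default_vignettes, simulate_cohort


@pytest.fixture(scope="session")
def vignettes():
    return build_default_vignettes()


@pytest.fixture(scope="session")
def noise_free_eut_cohort():
    config = SimulationConfig(
        n_participants=41, generating_model="EUT", decision_noise=0.0, seed=11
    )
    responses, truth = simulate_cohort(config)
    return responses, truth


@pytest.fixture(scope="session")
def dual_cohort():
    config = SimulationConfig(
        n_participants=60, generating_model="dual", decision_noise=0.05, seed=7
    )
    responses, truth = simulate_cohort(config)
    return responses, truth
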