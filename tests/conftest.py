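import pytest

import clustercausal as cc


@pytest.fixture(scope="session")
def small_config():
    """Modest clustered scenario used by most unit tests (1000 patients)."""
    return cc.ScenarioConfig(
        n_clusters=20, mean_cluster_size=50, total_target=1000, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return cc.ParametricSimulator(small_config).simulate(0)


def randomized_config(**overrides):
    """Treatment independent of everything; outcome model unchanged."""
    base = dict(
        n_clusters=20, mean_cluster_size=100, total_target=2000,
        gamma_z=0.0, beta_x_treat=(0.0,) * 5, beta_instrument=0.0,
        delta_interaction=0.0, seed=17,
    )
    base.update(overrides)
    return cc.ScenarioConfig(**base)


def collapsible_randomized_config(**overrides):
    """Randomized treatment and no other outcome-model effects, so the
    marginal and conditional log-OR coincide at tau."""
    base = dict(
        beta_x_out=(0.0,) * 5, beta_riskfactor=0.0, gamma_z_out=0.0,
    )
    base.update(overrides)
    return randomized_config(**base)


@pytest.fixture(scope="session")
def randomized_cohort():
    return cc.ParametricSimulator(randomized_config()).simulate(0)
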