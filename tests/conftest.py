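import numpy as np
import pandas as pd
import pytest

from miccea.synthetic_data import ClusterSD, DropoutModel, TrialConfig, simulate


@pytest.fixture(scope="session")
def small_config():
    """A fast trial: 2 homes/arm, ~30 residents each, no clustering."""
    return TrialConfig(
        homes_per_arm=2,
        residents_per_home_mean=30,
        cluster_sd=ClusterSD(0, 0, 0, 0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_trial(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """No deaths, no dropout, no missing components: fully observed data."""
    return TrialConfig(
        homes_per_arm=2,
        residents_per_home_mean=40,
        mortality_prob=0.0,
        no_baseline_prob=0.0,
        cost_missing_prob=0.0,
        participation_prob=1.0,
        dropout_model=DropoutModel(0.0, 0.0, 0.0),
        cluster_sd=ClusterSD(0, 0, 0, 0),
        seed=17,
    )


@pytest.fixture(scope="session")
def clean_trial(clean_config):
    return simulate(clean_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def toy_pairs():
    """Deterministic little cloud of cost-effect pairs for CEA tests."""
    from miccea.uncertainty import CEPairs

    df = pd.DataFrame(
        {
            "delta_cost": [10.0, -5.0, 20.0, -8.0],
            "delta_effect": [1.0, -1.0, -2.0, 3.0],
            "imputation": 0,
            "replicate": range(4),
        }
    )
    return CEPairs(replicates=df, outcome_kind="demo", effect_direction="higher")
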