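import numpy as np
import pytest

from hipwait import (SimulationConfig, apply_exclusions, assess_demand,
                     merge_episodes, simulate_cohort)


@pytest.fixture(scope="session")
def tiny_config():
    """Five hospitals, one year: the smallest run that exercises every stage."""
    return SimulationConfig(
        n_hospitals=5, start="2004-01-01", end="2004-12-31",
        arrival_rate_per_hospital_day=0.6, transfer_split_fraction=0.1,
        seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    """Analysis cohort with demand assessment, built through the real stages."""
    abstracts, truth, capacity = simulate_cohort(tiny_config)
    episodes = merge_episodes(abstracts)
    cohort, _ = apply_exclusions(episodes)
    dem = assess_demand(cohort)
    cohort = cohort.join(dem)
    return cohort[cohort["demand_category"].notna()].reset_index(drop=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
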