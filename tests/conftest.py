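import numpy as np
import pytest

from crowdasym.bayes_model import ModelSpec, build_design_matrix, fit
from crowdasym.observer_sim import (
    PopulationConfig,
    sample_population,
    truth_threshold_table,
)


@pytest.fixture(scope="session")
def small_cohort_table():
    """Threshold table for a small cohort: ground-truth thresholds plus
    lognormal measurement noise of roughly staircase magnitude."""
    pop = PopulationConfig.uniform(n_participants=10)
    observers = sample_population(pop, rng_seed=42)
    table = truth_threshold_table(observers)
    rng = np.random.default_rng(42)
    table["threshold_deg"] *= np.exp(rng.normal(0.0, 0.05, len(table)))
    return table


@pytest.fixture(scope="session")
def small_fit(small_cohort_table):
    """One smoke-preset fit shared by the model/analysis tests."""
    data = build_design_matrix(small_cohort_table, ModelSpec())
    draws = fit(data, ModelSpec(), mcmc="smoke", seed=5)
    return data, draws
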