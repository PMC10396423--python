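import numpy as np
import pytest

from splitmr import EffectSpec, SimulationConfig, StudyConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but analysable cohort: 5 strong causal variants among 40.

    Effects are parameterized on the non-centrality scale at n/3, so even a
    900-individual cohort yields genome-wide significant discoveries.
    """
    config = SimulationConfig(
        n_individuals=900,
        n_variants=40,
        n_null_variants=35,
        effect_spec=EffectSpec(25.0, 50.0),
        seed=42,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_study(small_cohort):
    from splitmr import run_study

    config = StudyConfig(
        n_iterations=6,
        strategies=("primary", "strict", "no_full_replication"),
        seed=7,
    )
    return run_study(small_cohort, 6, config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
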