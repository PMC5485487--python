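import numpy as np
import pytest

import sipcall as sc


@pytest.fixture
def small_table() -> sc.CountTable:
    return sc.CountTable(
        ["taxA", "taxB", "taxC"],
        ["s1", "s2"],
        np.array([[30, 5], [70, 10], [0, 85]]),
    )


@pytest.fixture(scope="session")
def default_experiment() -> sc.SimulatedExperiment:
    """The reference simulated experiment (seed 1); session-scoped because
    several suites only read from it."""
    return sc.simulate_experiment(sc.default_scenario(seed=1))


@pytest.fixture(scope="session")
def default_labeling(default_experiment) -> sc.LabelingResult:
    return sc.labeling_analysis(
        default_experiment.pools,
        default_experiment.design,
        default_experiment.scenario.taxa,
    )


@pytest.fixture
def block_profile() -> sc.AbundanceProfile:
    """Two planted three-sample blocks with near-perfect within-block
    correlation; 60 taxa so taxon bootstraps are stable."""
    rng = np.random.default_rng(7)
    base1, base2 = rng.random(60), rng.random(60)
    cols = [base1 + 0.01 * rng.random(60) for _ in range(3)]
    cols += [base2 + 0.01 * rng.random(60) for _ in range(3)]
    x = np.column_stack(cols)
    x = 100.0 * x / x.sum(axis=0)
    return sc.AbundanceProfile(
        [f"t{i}" for i in range(60)],
        ["A0", "A1", "A2", "B0", "B1", "B2"],
        x,
    )
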