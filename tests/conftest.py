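import numpy as np
import pandas as pd
import pytest

from coresat import CountMatrix, SimulationConfig, simulate_counts, \
    simulate_pathway_assignments


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """3 taxa x 4 samples, two groups, hand-checkable numbers."""
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 90],
            "s2": [30, 10, 60],
            "s3": [0, 50, 50],
            "s4": [25, 25, 50],
        },
        index=["tA", "tB", "tC"],
    )
    groups = pd.Series({"s1": "hc", "s2": "hc", "s3": "cp", "s4": "cp"})
    return CountMatrix(counts, groups)


@pytest.fixture
def random_matrix() -> CountMatrix:
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(8.0, size=(25, 12)),
        index=[f"t{i}" for i in range(25)],
        columns=[f"s{j}" for j in range(12)],
    )
    counts += 1  # no all-zero samples
    groups = pd.Series(
        {f"s{j}": ("g1" if j < 6 else "g2") for j in range(12)})
    return CountMatrix(counts, groups)


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated cohort, small enough for fast downstream tests."""
    cfg = SimulationConfig(seed=11, samples_per_group=8, depth=20_000)
    m, truth = simulate_counts(cfg)
    contrib = simulate_pathway_assignments(cfg, truth, m)
    return cfg, m, truth, contrib


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort at the default study conditions."""
    cfg = SimulationConfig(seed=5)
    m, truth = simulate_counts(cfg)
    return cfg, m, truth
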