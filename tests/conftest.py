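import numpy as np
import pytest

from enodal import (
    ExperimentDesign,
    OmicsMatrix,
    RunConfig,
    SimulationSpec,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_design() -> ExperimentDesign:
    """Balanced 2-treatment design with 2 nutrition variables, n = 12."""
    rng = np.random.default_rng(42)
    n = 12
    return ExperimentDesign(
        sample_ids=[f"s{i}" for i in range(n)],
        W=rng.normal(0, 1, (n, 2)),
        D=np.array(["ctrl", "drug"] * (n // 2), dtype=object),
        control_level="ctrl",
        nutrition_names=["protein", "carb"],
    )


@pytest.fixture(scope="session")
def factorial_dataset():
    """Simulated 10-diet x 4-treatment study with features from every model class."""
    spec = SimulationSpec(
        feature_counts={"M1": 20, "M2": 20, "M3": 20, "M4": 20, "M5": 20},
        seed=7,
        phenotype_links=(("M1_P1", 3.0),),
        n_null_phenotypes=2,
    )
    return simulate_dataset(spec)


@pytest.fixture()
def fast_config() -> RunConfig:
    return RunConfig(n_permutations=199, seed=1)
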