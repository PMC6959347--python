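import numpy as np
import pandas as pd
import pytest

from ednanet.synthetic import CommunityScenario, GeneratorOutput, simulate


@pytest.fixture(scope="session")
def default_output() -> GeneratorOutput:
    """One shared default-scenario dataset (seed 7)."""
    return simulate(CommunityScenario(seed=7))


@pytest.fixture(scope="session")
def small_scenario() -> CommunityScenario:
    return CommunityScenario(n_taxa=40, n_modules=3, seed=5)


@pytest.fixture(scope="session")
def small_output(small_scenario) -> GeneratorOutput:
    return simulate(small_scenario)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def field_replicate_groups(metadata: pd.DataFrame) -> dict[int, list[str]]:
    field = metadata[metadata["sample_type"] == "field"]
    return {int(t): list(g.index) for t, g in field.groupby("timepoint", sort=True)}
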