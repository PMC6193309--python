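import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from paleokaryo import AncestralKaryotypeModel, ScenarioConfig, simulate_scenario


@pytest.fixture(scope="session")
def scenario_sim():
    """Default full-history simulation (17 chromosomes, 1R, 7 fusions, 2R,
    4 + 1 dated fusions, 35% retention, mild rearrangement)."""
    return simulate_scenario(seed=1)


@pytest.fixture(scope="session")
def scenario_fit(scenario_sim):
    return AncestralKaryotypeModel.from_simulation(scenario_sim).fit()


@pytest.fixture(scope="session")
def clean_sim():
    """Two WGDs only: no fusions, no rearrangement, duplicate loss at 35%."""
    cfg = ScenarioConfig(
        genes_per_chromosome=150,
        inter_wgd_fusions=0,
        post2r_fusions_early=0,
        post2r_fusions_late=0,
        branch_inversions=0,
        branch_translocations=0,
    )
    return simulate_scenario(cfg, seed=5)


@pytest.fixture(scope="session")
def clean_fit(clean_sim):
    return AncestralKaryotypeModel.from_simulation(clean_sim).fit()
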