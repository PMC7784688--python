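import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def defense_scenario():
    from prophagenet import simulate as sim
    return sim.generate_defense_scenario(
        n_strains=4, motif_set=("GAATTC", "GCCGGC"), spacer_plants=2,
        mismatch_counts=(0,), seed=11, genome_length=3000)


@pytest.fixture()
def small_panel():
    from prophagenet import simulate as sim
    cfg = sim.PanelConfig(seed=7)
    matrix, strains = sim.generate_infection_panel(cfg)
    return matrix, strains, cfg
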