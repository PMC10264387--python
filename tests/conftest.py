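import pytest

from darkox.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-size synthetic cohort (21 wells), shared across tests."""
    return generate_cohort(GeneratorConfig(master_seed=7))


@pytest.fixture()
def simple_ions():
    return {"Na": 50.0, "K": 2.0, "Ca": 60.0, "Mg": 15.0,
            "Cl": 40.0, "SO4": 80.0, "HCO3": 250.0, "CO3": 0.0}
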