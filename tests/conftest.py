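import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

from glycomine.synthetic_data import (  # noqa: E402
    GenomePlan,
    PlantSpec,
    SimulationConfig,
    default_paper_plan,
    generate_genome_set,
    make_reference_anchors,
)


@pytest.fixture(scope="session")
def anchors():
    return make_reference_anchors()


@pytest.fixture(scope="session")
def small_truth():
    """A 10-genome synthetic set with the study-structure plan."""
    config = SimulationConfig(plans=default_paper_plan(10, seed=11), seed=11)
    return generate_genome_set(config)


@pytest.fixture(scope="session")
def tiny_config():
    """One genome, one of each placement kind — fast and fully enumerable."""
    plans = [
        GenomePlan(
            "GT01",
            planted=[
                PlantSpec("AZL", "inside"),
                PlantSpec("AZL", "flank", "+", 1500, 0),
                PlantSpec("YQL", "flank", "-", 25_000, 7),
                PlantSpec("AZL2", "flank", "+", 30_000, 6),
            ],
        )
    ]
    return SimulationConfig(plans=plans, seed=5)


@pytest.fixture(scope="session")
def tiny_truth(tiny_config):
    return generate_genome_set(tiny_config)
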