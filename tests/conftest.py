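import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_genome():
    from acetylscan import generate_genome

    return generate_genome(1, 100_000, 0.45, seed=11)


@pytest.fixture(scope="session")
def planted_world():
    """Small genome with planted regions, tags and truth shared across tests."""
    from acetylscan import (
        SampleDesign,
        generate_genome,
        plant_regions,
        simulate_chip_tags,
    )

    genome = generate_genome(1, 200_000, 0.45, seed=5)
    motif_spec = {"Gata2": ("WGATAR", 3.0, 1.0), "Cebpa": ("TTGCNNAA", 1.0, 1.0)}
    genome, regions = plant_regions(
        genome, 50, 400, motif_spec, fraction_group_effect=0.4,
        effect_fold=0.25, seed=7, base_enrichment=10.0,
    )
    design = SampleDesign(replicates_per_condition=2)
    tags = simulate_chip_tags(genome, regions, design, depth=50_000, seed=13)
    return genome, regions, design, tags
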