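import numpy as np
import pytest
from hypothesis import settings

from acgh.intervals import GenomeBuild
from acgh.simulate import make_genome, make_probe_map

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_build() -> GenomeBuild:
    return GenomeBuild("toy", (("chr1", 240_000), ("chr2", 240_000)))


@pytest.fixture(scope="session")
def toy_map(toy_build):
    return make_probe_map(toy_build, mean_spacing=1200, seed=2)


@pytest.fixture(scope="session")
def small_genome():
    """2 x 300 kb genome at the default GC target; shared across tests."""
    return make_genome({"chr1": 300_000, "chr2": 300_000}, seed=11)


@pytest.fixture(scope="session")
def desk_genome():
    """Desk-scale genome (5 x 2 Mb) with GC islands, for wave experiments."""
    return make_genome({f"chr{i + 1}": 2_000_000 for i in range(5)}, seed=7)


@pytest.fixture(scope="session")
def desk_map(desk_genome):
    return make_probe_map(desk_genome, mean_spacing=1200, seed=7)
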