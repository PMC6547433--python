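import numpy as np
import pytest

from ribote.sim import SimulationConfig, build_toy_genome


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=30, seed=7, library_depth=100_000)


@pytest.fixture(scope="session")
def toy(small_config):
    genome, annotation = build_toy_genome(small_config)
    return genome, annotation


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_genome(rng, length: int, chrom: str = "chrI") -> dict:
    return {chrom: "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])}
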