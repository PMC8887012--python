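import numpy as np
import pytest

from nucleochrom import synthetic
from nucleochrom.core import CompartmentalizedGenome


@pytest.fixture(scope="session")
def sim_config():
    return synthetic.default_config(seed=11, depth=100_000)


@pytest.fixture(scope="session")
def genome(sim_config) -> CompartmentalizedGenome:
    return synthetic.simulate_genome(sim_config)


@pytest.fixture(scope="session")
def dyads(genome, sim_config):
    return synthetic.plant_dyads(genome, sim_config)


@pytest.fixture(scope="session")
def atac(genome, sim_config, dyads):
    return synthetic.simulate_atac_fragments(genome, sim_config, dyads)


@pytest.fixture(scope="session")
def kas(genome, sim_config):
    return synthetic.simulate_kas_fragments(genome, sim_config)


@pytest.fixture(scope="session")
def input_lib(genome, sim_config):
    return synthetic.simulate_input_fragments(genome, sim_config)


@pytest.fixture(scope="session")
def hic_pairs(genome, sim_config):
    return synthetic.simulate_hic_pairs(genome, sim_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_genome(rng, lengths: dict[str, int], alphabet: str = "ACGT") -> dict[str, str]:
    bases = np.array(list(alphabet))
    return {
        name: "".join(bases[rng.integers(0, len(bases), size=n)])
        for name, n in lengths.items()
    }
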