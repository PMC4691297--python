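import numpy as np
import pytest

from ssrscan import GeneratorConfig, PlantInstruction, generate_dataset


def random_sequence(rng, length, alphabet="ACGT", probs=None):
    return "".join(rng.choice(list(alphabet), size=length, p=probs))


@pytest.fixture(scope="session")
def small_planted_dataset():
    """100 genes with 20 class I trimer and 50 class II hexamer plants."""
    cfg = GeneratorConfig(
        n_genes=100,
        gene_length=(300, 900),
        plants=(
            PlantInstruction("AGC", 7, 20),
            PlantInstruction("AACGGT", 2, 50),
        ),
        seed=42,
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20150304)
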