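import numpy as np
import pytest
from hypothesis import settings

import burstscan as bs
from burstscan.simulate import GAMMARID_LIKE_NEWICK

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gammarid_tree():
    return bs.parse_newick(GAMMARID_LIKE_NEWICK)


@pytest.fixture(scope="session")
def neutral_model():
    return bs.CodonModel(kappa=2.0, omega=1.0)


@pytest.fixture(scope="session")
def small_dataset(gammarid_tree):
    """30 neutral genes on the clade-like tree, fixed seed."""
    cfg = bs.preset_config("gammarid-like", seed=2024, n_genes=30,
                           gene_length_range=(150, 250))
    return bs.simulate_dataset(cfg)


def random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [bs.SENSE_CODONS[i] for i in rng.integers(0, len(bs.SENSE_CODONS), n)]
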