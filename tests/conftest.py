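import numpy as np
import pytest

from dermafluor import make_default_grid
from dermafluor.fluorophores import Phenotype, compose_template, default_basis_set
from dermafluor.simulate import LesionRecipe, generate_lesion


@pytest.fixture(scope="session")
def grid():
    return make_default_grid()


@pytest.fixture(scope="session")
def bases(grid):
    return default_basis_set(grid)


@pytest.fixture(scope="session")
def templates(grid):
    return {p: compose_template(p, grid) for p in Phenotype}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sk_scan():
    """A small default-recipe SK lesion, reused across read-only tests."""
    return generate_lesion(LesionRecipe(n_spectra=60, seed=42))
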