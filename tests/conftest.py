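import numpy as np
import pytest

from pocketdiff.complexes import AtomTypeVocabulary
from pocketdiff.diffusion import NoiseSchedule
from pocketdiff.e3former import E3former, E3formerConfig
from pocketdiff.fixtures import make_fixture_complex


@pytest.fixture(scope="session")
def vocab():
    return AtomTypeVocabulary()


@pytest.fixture(scope="session")
def fixture_complex():
    return make_fixture_complex(seed=3, n_residues=2, n_ligand_atoms=10)


@pytest.fixture(scope="session")
def schedule():
    return NoiseSchedule()


@pytest.fixture()
def tiny_model(vocab):
    return E3former(E3formerConfig(n_types=vocab.K), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()
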