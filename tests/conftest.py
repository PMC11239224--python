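import warnings

import pytest

from prostar.fixtures import FixtureSpec, gen_corpus, training_tables
from prostar.models import default_model
from prostar.training import TrainingConfig, train_model

warnings.filterwarnings("ignore", module="sklearn")


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def small_spec():
    """Small helical corpus over a 5-residue alphabet (fast training)."""
    return FixtureSpec(n_structures=8, residues_per_chain=20,
                       residue_alphabet=("ALA", "HIS", "GLU", "LEU", "GLY"),
                       seed=5)


@pytest.fixture(scope="session")
def small_tables(small_spec):
    return training_tables(small_spec)


@pytest.fixture(scope="session")
def small_model(small_tables):
    return train_model(small_tables, TrainingConfig(k_max=4, seed=5))


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    """On-disk corpus of 10 structure/PAE/confidence triples."""
    out = tmp_path_factory.mktemp("corpus")
    gen_corpus(FixtureSpec(n_structures=10, residues_per_chain=25, seed=42), out)
    return out
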