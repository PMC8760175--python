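import numpy as np
import pytest
from hypothesis import settings

from aievote.dataio import Dataset, MoleculeRecord
from aievote.featurize import featurize_all
from aievote.synthetic import GeneratorConfig, generate_dataset

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

# A dozen hand-picked molecules spanning both classes of the rotor rule.
TOY_MOLECULES = [
    ("tpe", "C(=C(c1ccccc1)c1ccccc1)(c1ccccc1)c1ccccc1", "AIE"),
    ("tpa", "N(c1ccccc1)(c1ccccc1)c1ccccc1", "AIE"),
    ("tpm", "C(c1ccccc1)(c1ccccc1)c1ccccc1", "AIE"),
    ("tpb", "c1ccc(-c2cc(-c3ccccc3)cc(-c3ccccc3)c2)cc1", "AIE"),
    ("tnaphe", "C(=C(c1ccc2ccccc2c1)c1ccccc1)(c1ccccc1)c1ccccc1", "AIE"),
    ("pyrene", "c1cc2ccc3cccc4ccc(c1)c2c34", "ACQ"),
    ("anthracene", "c1ccc2cc3ccccc3cc2c1", "ACQ"),
    ("naphthalene", "c1ccc2ccccc2c1", "ACQ"),
    ("biphenyl", "c1ccc(-c2ccccc2)cc1", "ACQ"),
    ("toluene", "Cc1ccccc1", "ACQ"),
    ("chrysene", "c1ccc2c(c1)ccc1c2ccc2ccccc21", "ACQ"),
    ("stilbene", "C(=Cc1ccccc1)c1ccccc1", "ACQ"),
]


@pytest.fixture(scope="session")
def toy_dataset() -> Dataset:
    return Dataset([MoleculeRecord(i, s, l) for i, s, l in TOY_MOLECULES])


@pytest.fixture(scope="session")
def small_synth() -> Dataset:
    """A 60-molecule planted-rule dataset for fast model/CV tests."""
    return generate_dataset(GeneratorConfig(n=60, n_positive=24, seed=11))


@pytest.fixture(scope="session")
def small_blocks(small_synth):
    return featurize_all(small_synth)


@pytest.fixture(scope="session")
def study_dataset() -> Dataset:
    """The reference-scale noise-free dataset: 356 molecules, 134 AIE."""
    return generate_dataset(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def study_blocks(study_dataset):
    return featurize_all(study_dataset)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
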