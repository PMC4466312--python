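import numpy as np
import pytest
from rdkit import Chem
from rdkit import RDLogger

from tcomfa import chem_io, synthetic
from tcomfa.alignment import TemplateAligner

RDLogger.DisableLog("rdApp.warning")


def mol(smiles: str, name: str = "") -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    assert m is not None, smiles
    if name:
        chem_io.set_mol_id(m, name)
    return m


@pytest.fixture(scope="session")
def small_spec():
    return synthetic.SyntheticSpec(n_molecules=24, seed=3)


@pytest.fixture(scope="session")
def small_series(small_spec):
    """24 synthetic 2D molecules plus their 3-template set."""
    templates, mols = synthetic.make_series(small_spec)
    return templates, mols


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """Aligned 24-molecule dataset with planted field-linear activities."""
    return synthetic.make_dataset(small_spec)


@pytest.fixture(scope="session")
def aligner(small_series):
    templates, _ = small_series
    return TemplateAligner(templates)


@pytest.fixture(scope="session")
def recovery_dataset():
    """The planted-signal recovery fixture at study size (n=200)."""
    return synthetic.make_dataset(synthetic.SyntheticSpec(n_molecules=200, seed=101))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
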