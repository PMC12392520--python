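import numpy as np
import pytest

from adaptor import FingerprintDataset, make_synthetic_qsar

# small drug-like SMILES set for exercising the chemistry I/O path
DEMO_SMILES = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O", 4.2),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", 4.8),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", 5.1),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1", 4.5),
    ("benzene", "c1ccccc1", 4.0),
    ("toluene", "Cc1ccccc1", 4.1),
    ("phenol", "Oc1ccccc1", 4.3),
    ("naphthalene", "c1ccc2ccccc2c1", 5.0),
    ("indole", "c1ccc2[nH]ccc2c1", 5.6),
    ("pyridine", "c1ccncc1", 4.4),
    ("imatinib", "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1", 7.4),
    ("gefitinib", "COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1", 7.1),
]


@pytest.fixture
def smiles_csv(tmp_path):
    """Delimited molecule table with one deliberately invalid SMILES row."""
    path = tmp_path / "molecules.csv"
    lines = ["id,smiles,response"]
    lines += [f"{mid},{smi},{resp}" for mid, smi, resp in DEMO_SMILES]
    lines.append("broken,not_a_molecule,5.0")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def synth300() -> FingerprintDataset:
    """Mid-sized synthetic dataset shared across model-level tests."""
    return make_synthetic_qsar(300, seed=7).data


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
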