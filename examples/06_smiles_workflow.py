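"""Chemistry-path workflow: from SMILES strings to a fitted model.

Writes a small molecule table (id, SMILES, response), reads it back
with validation (rows with unparseable SMILES are dropped and logged),
computes MHFP6 fingerprints and fits a compact model. With a table this
small the model is only a smoke demonstration; the point is the I/O and
featurization path used for real per-cell-line tables.
"""

import logging
import tempfile
from pathlib import Path

import adaptor as ad

logging.basicConfig(level=logging.WARNING, format="%(levelname)s: %(message)s")

rows = [
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
    ("bad_row", "this_is_not_a_smiles", 5.0),  # dropped with a warning
]

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "molecules.csv"
    path.write_text(
        "id,smiles,response\n"
        + "\n".join(f"{i},{s},{r}" for i, s, r in rows)
        + "\n"
    )
    table = ad.read_molecule_table(path)

print(f"molecules read: {len(table)} (one row excluded for invalid SMILES)")

data = ad.FingerprintDataset.from_molecule_table(table, kind="mhfp6")
model = ad.fit_adaptor(
    data, ad.AnchorConfig(Kr=3, anchor_fraction=0.25, P=2, seed=0)
)
pred = model.predict(data)
for mid, y, y_hat in zip(data.ids, data.responses, pred):
    print(f"  {mid:12s} observed {y:.2f}  fitted {y_hat:.2f}")
# GI50 values in molar units can be converted at read time with
# read_molecule_table(path, response_transform="nloggi50").
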