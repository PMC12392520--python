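"""Molecule tables, fingerprints and distance matrices.

The modeling stack operates entirely in distance space: molecules are
encoded as ECFP4 bit vectors or MHFP6 min-hash vectors, and the model
consumes sample-by-anchor distance matrices in the structure space
(Jaccard / min-hash mismatch distances, all in [0, 1]) and in the
response space (absolute response differences).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FingerprintKind(str, Enum):
    ECFP4 = "ecfp4"
    MHFP6 = "mhfp6"


class DistanceSpace(str, Enum):
    STRUCTURE = "structure"
    RESPONSE = "response"


class MoleculeTableError(ValueError):
    """Raised for malformed or empty molecule tables."""


class FingerprintError(ValueError):
    """Raised for unparseable SMILES or incompatible fingerprints."""


def nloggi50(gi50: float) -> float:
    """Negative log10 of a GI50 concentration (molar).

    NLOGGI50 = -log10(GI50); higher values mean stronger growth
    inhibition. GI50 must be strictly positive.
    """
    if gi50 <= 0:
        raise ValueError(f"GI50 must be > 0 to take -log10, got {gi50}")
    return float(-np.log10(gi50))


@dataclass
class MoleculeRecord:
    molecule_id: str
    smiles: str
    response: float


@dataclass
class MoleculeTable:
    """Identified molecules with SMILES strings and scalar responses.

    One table corresponds to one dataset unit (e.g. one cell line).
    Molecule ids are unique and every record carries a finite response.
    """

    records: list[MoleculeRecord]
    name: str = ""

    def __post_init__(self) -> None:
        ids = [r.molecule_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MoleculeTableError(f"duplicate molecule ids: {dupes[:5]}")
        for r in self.records:
            if not np.isfinite(r.response):
                raise MoleculeTableError(
                    f"non-finite response for molecule {r.molecule_id!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.molecule_id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def responses(self) -> np.ndarray:
        return np.array([r.response for r in self.records], dtype=float)

    def subset(self, ids: Sequence[str]) -> "MoleculeTable":
        by_id = {r.molecule_id: r for r in self.records}
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise KeyError(f"unknown molecule ids: {missing[:5]}")
        return MoleculeTable([by_id[i] for i in ids], name=self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "smiles": self.smiles,
                "response": self.responses,
            }
        )


def _smiles_is_valid(smiles: str) -> bool:
    from rdkit import Chem

    return isinstance(smiles, str) and Chem.MolFromSmiles(smiles) is not None


def read_molecule_table(
    path: str | Path,
    response_transform: str = "none",
    id_col: str = "id",
    smiles_col: str = "smiles",
    response_col: str = "response",
    name: str | None = None,
) -> MoleculeTable:
    """Read a delimited molecule table, dropping invalid-SMILES rows.

    Parameters
    ----------
    path
        CSV or TSV file with header columns for id, SMILES and response
        (delimiter sniffed from the extension; ``.tsv`` means tab).
    response_transform
        ``"none"`` uses responses as given; ``"nloggi50"`` treats the
        response column as molar GI50 and applies -log10.

    Rows whose SMILES cannot be parsed are dropped and counted in a log
    message rather than aborting the read.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in (id_col, smiles_col, response_col) if c not in df.columns]
    if missing:
        raise MoleculeTableError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )

    if response_transform not in ("none", "nloggi50"):
        raise ValueError(f"unknown response_transform {response_transform!r}")

    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    try:
        valid_mask = df[smiles_col].map(_smiles_is_valid)
    finally:
        RDLogger.EnableLog("rdApp.error")

    n_dropped = int((~valid_mask).sum())
    if n_dropped:
        dropped_ids = df.loc[~valid_mask, id_col].astype(str).tolist()
        logger.warning(
            "Excluded %d molecule(s) without valid SMILES: %s",
            n_dropped,
            ", ".join(dropped_ids[:10]),
        )
    df = df[valid_mask]
    if df.empty:
        raise MoleculeTableError(f"{path}: no rows with valid SMILES")

    responses = df[response_col].astype(float)
    if response_transform == "nloggi50":
        responses = responses.map(nloggi50)

    records = [
        MoleculeRecord(str(i), s, float(r))
        for i, s, r in zip(df[id_col], df[smiles_col], responses)
    ]
    return MoleculeTable(records, name=name or path.stem)


@dataclass
class Fingerprint:
    """Fixed-length molecular fingerprint.

    ECFP4: circular (Morgan) fingerprint of radius 2 folded to
    ``length`` bits, values in {0, 1}. MHFP6: min-hash fingerprint of
    radius 3, ``length`` unsigned hash values.
    """

    kind: FingerprintKind
    values: np.ndarray
    length: int = 2048

    def __post_init__(self) -> None:
        self.kind = FingerprintKind(self.kind)
        self.values = np.asarray(self.values)
        if self.length <= 0 or len(self.values) != self.length:
            raise FingerprintError(
                f"fingerprint length {len(self.values)} != declared {self.length}"
            )


_MHFP_ENCODERS: dict[int, object] = {}


def _mhfp_encoder(length: int):
    # MHFPEncoder seeds its permutations; a fixed seed keeps fingerprints
    # reproducible across processes.
    if length not in _MHFP_ENCODERS:
        from rdkit.Chem import rdMHFPFingerprint

        _MHFP_ENCODERS[length] = rdMHFPFingerprint.MHFPEncoder(length, 42)
    return _MHFP_ENCODERS[length]


def compute_fingerprint(
    smiles: str,
    kind: FingerprintKind | str = FingerprintKind.ECFP4,
    length: int = 2048,
) -> Fingerprint:
    """Compute an ECFP4 or MHFP6 fingerprint for one SMILES string."""
    from rdkit import Chem

    kind = FingerprintKind(kind)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FingerprintError(f"unparseable SMILES: {smiles!r}")

    if kind is FingerprintKind.ECFP4:
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=length)
        bv = gen.GetFingerprint(mol)
        values = np.zeros(length, dtype=np.uint8)
        values[list(bv.GetOnBits())] = 1
    else:
        enc = _mhfp_encoder(length)
        values = np.array(enc.EncodeMol(mol, radius=3), dtype=np.uint32)
    return Fingerprint(kind=kind, values=values, length=length)


def fingerprint_table(
    table: MoleculeTable,
    kind: FingerprintKind | str = FingerprintKind.ECFP4,
    length: int = 2048,
) -> np.ndarray:
    """Stack fingerprints for every molecule into an (N, length) array."""
    return np.vstack(
        [compute_fingerprint(s, kind=kind, length=length).values for s in table.smiles]
    )


def structure_distance(a: Fingerprint, b: Fingerprint) -> float:
    """Structure distance between two fingerprints, in [0, 1].

    ECFP4 uses the Jaccard (Tanimoto) distance 1 - |a∩b|/|a∪b|; two
    all-zero fingerprints have distance 0. MHFP6 uses the fraction of
    min-hash positions whose hash values differ, the standard unbiased
    estimator of the Jaccard distance of the underlying shingle sets.
    """
    if a.kind != b.kind or a.length != b.length:
        raise FingerprintError(
            f"incompatible fingerprints: {a.kind.value}/{a.length} vs "
            f"{b.kind.value}/{b.length}"
        )
    return float(
        _pairwise_structure_distances(
            a.values[None, :], b.values[None, :], a.kind
        )[0, 0]
    )


def _pairwise_structure_distances(
    A: np.ndarray, B: np.ndarray, kind: FingerprintKind
) -> np.ndarray:
    """(N, L) x (K, L) -> (N, K) distance matrix for one fingerprint kind."""
    kind = FingerprintKind(kind)
    if kind is FingerprintKind.ECFP4:
        A = A.astype(np.float64)
        B = B.astype(np.float64)
        inter = A @ B.T
        union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = 1.0 - inter / union
        dist[union == 0] = 0.0  # two empty bitsets: identical by convention
        return dist
    # MHFP: mismatch fraction over hash positions
    return (A[:, None, :] != B[None, :, :]).mean(axis=2)


@dataclass
class DistanceMatrix:
    """Sample-by-anchor distance matrix with id bookkeeping.

    ``space`` is "structure" (entries in [0, 1]) or "response"
    (absolute response differences, nonnegative).
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    space: DistanceSpace = DistanceSpace.STRUCTURE

    def __post_init__(self) -> None:
        self.space = DistanceSpace(self.space)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} != ({len(self.row_ids)}, {len(self.col_ids)})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def read(cls, path: str | Path, space: DistanceSpace | str) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            df.to_numpy(dtype=float),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            DistanceSpace(space),
        )


@dataclass
class FingerprintDataset:
    """Fingerprinted dataset: the in-memory unit the models consume.

    Pairs molecule ids and responses with a precomputed (N, L)
    fingerprint array, so model code never touches SMILES. Built from a
    :class:`MoleculeTable` via :meth:`from_molecule_table` or directly
    (e.g. by the synthetic generator).
    """

    ids: list[str]
    responses: np.ndarray
    fingerprints: np.ndarray
    kind: FingerprintKind = FingerprintKind.ECFP4
    name: str = ""

    def __post_init__(self) -> None:
        self.kind = FingerprintKind(self.kind)
        self.responses = np.asarray(self.responses, dtype=float)
        self.fingerprints = np.asarray(self.fingerprints)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise MoleculeTableError("duplicate molecule ids")
        if self.responses.shape != (n,) or self.fingerprints.shape[0] != n:
            raise ValueError("ids, responses and fingerprints disagree in length")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index_of(self) -> dict[str, int]:
        return {mid: i for i, mid in enumerate(self.ids)}

    def subset(self, ids: Sequence[str]) -> "FingerprintDataset":
        idx = self.index_of
        sel = [idx[i] for i in ids]
        return FingerprintDataset(
            list(ids),
            self.responses[sel],
            self.fingerprints[sel],
            self.kind,
            self.name,
        )

    @classmethod
    def from_molecule_table(
        cls,
        table: MoleculeTable,
        kind: FingerprintKind | str = FingerprintKind.ECFP4,
        length: int = 2048,
    ) -> "FingerprintDataset":
        return cls(
            ids=table.ids,
            responses=table.responses,
            fingerprints=fingerprint_table(table, kind=kind, length=length),
            kind=FingerprintKind(kind),
            name=table.name,
        )


def structure_distance_matrix(
    fingerprints: np.ndarray,
    row_ids: Sequence[str],
    anchor_index: Sequence[int],
    kind: FingerprintKind | str,
    row_index: Sequence[int] | None = None,
) -> DistanceMatrix:
    """Structure distances from selected rows to anchor fingerprints.

    ``fingerprints`` is the (N, L) array for the whole table;
    ``anchor_index``/``row_index`` are positional indices into it.
    """
    kind = FingerprintKind(kind)
    if len(anchor_index) == 0:
        raise ValueError("empty structure anchor set")
    row_index = np.arange(len(row_ids)) if row_index is None else np.asarray(row_index)
    anchor_index = np.asarray(anchor_index)
    vals = _pairwise_structure_distances(
        fingerprints[row_index], fingerprints[anchor_index], kind
    )
    return DistanceMatrix(
        vals,
        [row_ids[i] for i in row_index],
        [row_ids[i] for i in anchor_index],
        DistanceSpace.STRUCTURE,
    )


def response_distance_matrix(
    responses: np.ndarray,
    row_ids: Sequence[str],
    anchor_responses: np.ndarray,
    anchor_ids: Sequence[str],
) -> DistanceMatrix:
    """Response distances |t_i - t_k| from samples to response anchors."""
    responses = np.asarray(responses, dtype=float)
    anchor_responses = np.asarray(anchor_responses, dtype=float)
    if anchor_responses.size == 0:
        raise ValueError("empty response anchor set")
    vals = np.abs(responses[:, None] - anchor_responses[None, :])
    return DistanceMatrix(vals, list(row_ids), list(anchor_ids), DistanceSpace.RESPONSE)
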