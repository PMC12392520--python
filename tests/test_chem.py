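"""Chemistry I/O: molecule tables, fingerprints, distance matrices."""

import itertools

import numpy as np
import pytest

from adaptor import (
    DistanceMatrix,
    Fingerprint,
    FingerprintKind,
    MoleculeRecord,
    MoleculeTable,
    compute_fingerprint,
    nloggi50,
    read_molecule_table,
    response_distance_matrix,
    structure_distance,
    structure_distance_matrix,
)
from adaptor.chem import (
    FingerprintError,
    MoleculeTableError,
    _pairwise_structure_distances,
)


class TestNloggi50:
    @pytest.mark.parametrize(
        "gi50,expected", [(1e-4, 4.0), (1e-6, 6.0), (1e-8, 8.0), (10 ** (-7.86), 7.86)]
    )
    def test_negative_log10(self, gi50, expected):
        assert nloggi50(gi50) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1e-6])
    def test_nonpositive_concentration_rejected(self, bad):
        with pytest.raises(ValueError):
            nloggi50(bad)


class TestReadMoleculeTable:
    def test_invalid_smiles_rows_dropped_with_log(self, smiles_csv, caplog):
        with caplog.at_level("WARNING"):
            table = read_molecule_table(smiles_csv)
        assert len(table) == 12  # 13 rows, one unparseable
        assert "broken" not in table.ids
        assert "1 molecule" in caplog.text

    def test_nloggi50_transform_applied(self, tmp_path):
        path = tmp_path / "gi50.csv"
        path.write_text("id,smiles,response\na,CCO,1e-6\nb,CCN,1e-4\n")
        table = read_molecule_table(path, response_transform="nloggi50")
        assert table.responses == pytest.approx([6.0, 4.0])

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,structure,response\na,CCO,1\n")
        with pytest.raises(MoleculeTableError, match="smiles"):
            read_molecule_table(path)

    def test_all_rows_invalid_is_empty_table_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("id,smiles,response\na,xxxx,1\n")
        with pytest.raises(MoleculeTableError, match="no rows"):
            read_molecule_table(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(MoleculeTableError, match="duplicate"):
            MoleculeTable(
                [MoleculeRecord("a", "CCO", 1.0), MoleculeRecord("a", "CCN", 2.0)]
            )


class TestFingerprints:
    @pytest.mark.parametrize("kind", [FingerprintKind.ECFP4, FingerprintKind.MHFP6])
    def test_deterministic_and_correct_length(self, kind):
        fp1 = compute_fingerprint("CCO", kind=kind)
        fp2 = compute_fingerprint("CCO", kind=kind)
        assert fp1.length == 2048
        assert np.array_equal(fp1.values, fp2.values)

    @pytest.mark.parametrize("kind", [FingerprintKind.ECFP4, FingerprintKind.MHFP6])
    def test_equivalent_smiles_give_identical_fingerprints(self, kind):
        # kekulized and aromatic benzene parse to the same molecule
        a = compute_fingerprint("c1ccccc1", kind=kind)
        b = compute_fingerprint("C1=CC=CC=C1", kind=kind)
        assert np.array_equal(a.values, b.values)

    def test_ecfp4_is_binary(self):
        fp = compute_fingerprint("Cn1cnc2c1c(=O)n(C)c(=O)n2C")
        assert set(np.unique(fp.values)) <= {0, 1}
        assert fp.values.sum() > 0

    def test_unparseable_smiles_named_in_error(self):
        with pytest.raises(FingerprintError, match="not_a_molecule"):
            compute_fingerprint("not_a_molecule")


class TestStructureDistance:
    def test_identical_fingerprints_distance_zero(self):
        fp = compute_fingerprint("CCO")
        assert structure_distance(fp, fp) == 0.0

    def test_disjoint_bitsets_distance_one(self):
        a = Fingerprint(FingerprintKind.ECFP4, np.array([1, 1, 0, 0]), 4)
        b = Fingerprint(FingerprintKind.ECFP4, np.array([0, 0, 1, 1]), 4)
        assert structure_distance(a, b) == 1.0

    def test_mhfp_half_mismatch_is_half(self):
        a = Fingerprint(FingerprintKind.MHFP6, np.array([1, 2, 3, 4]), 4)
        b = Fingerprint(FingerprintKind.MHFP6, np.array([1, 2, 9, 9]), 4)
        assert structure_distance(a, b) == 0.5

    def test_kind_mismatch_rejected(self):
        a = Fingerprint(FingerprintKind.ECFP4, np.array([1, 0]), 2)
        b = Fingerprint(FingerprintKind.MHFP6, np.array([1, 0]), 2)
        with pytest.raises(FingerprintError, match="incompatible"):
            structure_distance(a, b)

    def test_jaccard_metric_axioms_on_all_4bit_sets(self):
        """d(a,a)=0, symmetry, triangle inequality, exhaustively at 4 bits."""
        vectors = [np.array(bits) for bits in itertools.product([0, 1], repeat=4)]

        def d(a, b):
            return float(
                _pairwise_structure_distances(
                    a[None, :], b[None, :], FingerprintKind.ECFP4
                )[0, 0]
            )

        for a in vectors:
            assert d(a, a) == 0.0
        for a, b in itertools.combinations(vectors, 2):
            assert d(a, b) == pytest.approx(d(b, a))
        for a, b, c in itertools.product(vectors, repeat=3):
            assert d(a, c) <= d(a, b) + d(b, c) + 1e-12

    def test_minhash_mismatch_estimates_shingle_jaccard(self, rng):
        """Min-hash disagreement fraction converges to the true Jaccard
        distance of the underlying sets as permutations grow."""
        universe = np.arange(60)
        set_a = universe[:40]
        set_b = universe[20:]  # |A∩B| = 20, |A∪B| = 60, Jaccard dist = 2/3
        n_perm = 4096
        # exact random permutations of the universe as min-hash
        perms = np.vstack([rng.permutation(60) for _ in range(n_perm)])
        ha = perms[:, set_a].min(axis=1)
        hb = perms[:, set_b].min(axis=1)
        assert (ha != hb).mean() == pytest.approx(2 / 3, abs=0.03)


class TestDistanceMatrices:
    def test_self_matrix_zero_diagonal_symmetric(self, synth300):
        idx = np.arange(20)
        dm = structure_distance_matrix(
            synth300.fingerprints, synth300.ids, idx, synth300.kind, row_index=idx
        )
        assert np.allclose(np.diag(dm.values), 0.0)
        assert np.allclose(dm.values, dm.values.T)

    def test_response_entries_are_absolute_differences(self):
        dm = response_distance_matrix(
            np.array([4.0, 7.0]), ["a", "b"], np.array([5.0]), ["c"]
        )
        assert np.allclose(dm.values, [[1.0], [2.0]])

    def test_structure_entries_bounded_in_unit_interval(self, synth300):
        dm = structure_distance_matrix(
            synth300.fingerprints,
            synth300.ids,
            np.arange(75),
            synth300.kind,
            row_index=np.arange(75, 300),
        )
        assert dm.values.min() >= 0.0 and dm.values.max() <= 1.0

    def test_empty_anchor_set_rejected(self, synth300):
        with pytest.raises(ValueError, match="empty"):
            structure_distance_matrix(
                synth300.fingerprints, synth300.ids, [], synth300.kind
            )

    def test_round_trip_through_csv(self, tmp_path, synth300):
        dm = structure_distance_matrix(
            synth300.fingerprints,
            synth300.ids,
            np.arange(5),
            synth300.kind,
            row_index=np.arange(10),
        )
        path = tmp_path / "dm.csv"
        dm.write(path)
        back = DistanceMatrix.read(path, "structure")
        assert back.row_ids == dm.row_ids and back.col_ids == dm.col_ids
        assert np.allclose(back.values, dm.values)
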