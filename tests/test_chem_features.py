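import numpy as np
import pytest

from toxqsar import (
    AlignmentError,
    CompoundSet,
    DescriptorMatrix,
    LabeledCompound,
    RegistryError,
    SchemaError,
    SmilesError,
    apply_normalizer,
    clean_matrix,
    compute_descriptors,
    fit_normalizer,
    read_compound_table,
    validate_smiles,
    write_compound_table,
)


class TestValidateSmiles:
    def test_alternate_spellings_canonicalize_identically(self):
        assert validate_smiles("OCC") == validate_smiles("CCO")

    def test_aromatic_input_is_valid(self):
        assert validate_smiles("c1ccccc1")  # benzene round-trips without error

    @pytest.mark.parametrize("bad", ["C1CC", "xyz", "C(", ""])
    def test_malformed_smiles_raise_with_offender(self, bad):
        with pytest.raises(SmilesError, match="invalid SMILES"):
            validate_smiles(bad)


class TestReadCompoundTable:
    def test_csv_parse_preserves_order_and_labels(self, tiny_csv):
        cs = read_compound_table(tiny_csv)
        assert cs.ids == ["m1", "m2", "m3"]
        assert cs.labels.tolist() == [1, 0, 1]
        assert cs.compounds[0].smiles == validate_smiles("CCO")

    def test_unparseable_label_names_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,smiles,label\nm1,CCO,1\nm2,CC,maybe\n")
        with pytest.raises(SchemaError, match="m2"):
            read_compound_table(path)

    def test_empty_table_errors(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("id,smiles,label\n")
        with pytest.raises(SchemaError, match="no compounds"):
            read_compound_table(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("name,structure\nm1,CCO\n")
        with pytest.raises(SchemaError, match="missing columns"):
            read_compound_table(path)

    def test_column_map_remaps_names(self, tmp_path):
        path = tmp_path / "mapped.csv"
        path.write_text("cid,structure,active\nm1,CCO,0\n")
        cs = read_compound_table(
            path, column_map={"id": "cid", "smiles": "structure", "label": "active"}
        )
        assert cs.ids == ["m1"]

    def test_csv_round_trip(self, tmp_path, smiles_set):
        path = tmp_path / "rt.csv"
        write_compound_table(smiles_set, path)
        back = read_compound_table(path)
        assert back.ids == smiles_set.ids
        assert back.smiles == smiles_set.smiles
        assert back.labels.tolist() == smiles_set.labels.tolist()

    def test_sdf_reading(self, tmp_path):
        from rdkit import Chem

        path = tmp_path / "mols.sdf"
        writer = Chem.SDWriter(str(path))
        for name, smi, label in [("m1", "CCO", "1"), ("m2", "c1ccccc1", "0")]:
            mol = Chem.MolFromSmiles(smi)
            mol.SetProp("_Name", name)
            mol.SetProp("activity", label)
            writer.write(mol)
        writer.close()
        cs = read_compound_table(path, format="sdf")
        assert cs.ids == ["m1", "m2"]
        assert cs.labels.tolist() == [1, 0]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(SchemaError, match="duplicate"):
            CompoundSet("x", [LabeledCompound("a", "CCO", 1), LabeledCompound("a", "CC", 0)])


class TestComputeDescriptors:
    def test_identical_molecules_give_identical_rows(self):
        cs = CompoundSet(
            "x",
            [
                LabeledCompound("a", validate_smiles("CCO"), 1),
                LabeledCompound("b", validate_smiles("OCC"), 0),
            ],
        )
        m = compute_descriptors(cs, "rdkit_2d")
        np.testing.assert_array_equal(m.values[0], m.values[1])

    def test_unknown_set_is_registry_error(self, smiles_set):
        with pytest.raises(RegistryError, match="nonexistent"):
            compute_descriptors(smiles_set, "nonexistent")

    @pytest.mark.parametrize("family", ["maccs", "estate", "morgan"])
    def test_fingerprint_families_produce_finite_matrices(self, smiles_set, family):
        m = compute_descriptors(smiles_set, family)
        assert m.n_compounds == len(smiles_set)
        assert np.isfinite(m.values).all()

    def test_combined_concatenates_families(self, smiles_set):
        combined = compute_descriptors(smiles_set, "combined")
        single = compute_descriptors(smiles_set, "rdkit_2d")
        assert combined.n_features > single.n_features
        assert len(set(combined.feature_names)) == combined.n_features

    def test_permutation_equivariance(self, smiles_set):
        reversed_set = CompoundSet("x", list(reversed(smiles_set.compounds)))
        m1 = compute_descriptors(smiles_set, "maccs")
        m2 = compute_descriptors(reversed_set, "maccs")
        np.testing.assert_array_equal(m1.values, m2.values[::-1])


class TestCleanMatrix:
    def test_nan_column_dropped_rows_kept(self):
        values = np.array([[1.0, np.nan, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        m = DescriptorMatrix(values, ["f1", "f2", "f3"], ["a", "b", "c"])
        cleaned = clean_matrix(m)
        assert cleaned.feature_names == ["f1", "f3"]
        assert cleaned.n_compounds == 3

    def test_clean_is_identity_on_finite_input(self, simple_matrix):
        cleaned = clean_matrix(simple_matrix)
        np.testing.assert_array_equal(cleaned.values, simple_matrix.values)
        assert cleaned.feature_names == simple_matrix.feature_names

    def test_all_columns_bad_errors(self):
        m = DescriptorMatrix(np.array([[np.nan], [1.0]]), ["f1"], ["a", "b"])
        with pytest.raises(SchemaError, match="no usable descriptors"):
            clean_matrix(m)

    def test_idempotent(self):
        values = np.array([[1.0, np.inf], [2.0, 3.0]])
        m = DescriptorMatrix(values, ["f1", "f2"], ["a", "b"])
        once = clean_matrix(m)
        twice = clean_matrix(once)
        assert once.feature_names == twice.feature_names
        np.testing.assert_array_equal(once.values, twice.values)


class TestNormalizer:
    def test_min_max_fit(self, simple_matrix):
        params = fit_normalizer(simple_matrix)
        np.testing.assert_array_equal(params.x_min, [2.0, 1.0, 0.0])
        np.testing.assert_array_equal(params.x_max, [6.0, 1.0, 10.0])

    def test_training_column_maps_to_unit_interval(self, simple_matrix):
        params = fit_normalizer(simple_matrix)
        scaled = apply_normalizer(params, simple_matrix)
        np.testing.assert_allclose(scaled.values[:, 0], [0.0, 0.5, 1.0])
        assert scaled.values.min() >= 0.0 and scaled.values.max() <= 1.0
        # non-constant columns attain both endpoints
        assert scaled.values[:, 2].min() == 0.0 and scaled.values[:, 2].max() == 1.0

    def test_query_outside_range_is_not_clamped(self, simple_matrix):
        params = fit_normalizer(simple_matrix)
        query = DescriptorMatrix(np.array([[8.0, 2.0, -5.0]]), ["a", "b", "c"], ["q"])
        scaled = apply_normalizer(params, query)
        assert scaled.values[0, 0] == pytest.approx(1.5)  # (8-2)/(6-2)
        assert scaled.values[0, 2] == pytest.approx(-0.5)

    def test_constant_column_maps_to_zero(self, simple_matrix):
        params = fit_normalizer(simple_matrix)
        query = DescriptorMatrix(np.array([[2.0, 99.0, 0.0]]), ["a", "b", "c"], ["q"])
        scaled = apply_normalizer(params, query)
        assert scaled.values[0, 1] == 0.0

    def test_single_row_matrix_fits(self):
        m = DescriptorMatrix(np.array([[3.0, 4.0]]), ["a", "b"], ["r"])
        params = fit_normalizer(m)
        np.testing.assert_array_equal(params.x_min, params.x_max)

    def test_feature_mismatch_raises(self, simple_matrix):
        params = fit_normalizer(simple_matrix)
        other = DescriptorMatrix(np.zeros((1, 2)), ["a", "x"], ["q"])
        with pytest.raises(AlignmentError):
            apply_normalizer(params, other)

    def test_json_round_trip(self, tmp_path, simple_matrix):
        from toxqsar import NormalizationParams

        params = fit_normalizer(simple_matrix)
        params.to_json(tmp_path / "norm.json")
        back = NormalizationParams.from_json(tmp_path / "norm.json")
        np.testing.assert_array_equal(back.x_min, params.x_min)
        assert back.feature_names == params.feature_names
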