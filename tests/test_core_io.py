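"""Core data model, FASTA I/O, matrix export and fixture generation."""

import numpy as np
import pytest

from omegafeat.fixtures import generate_fixtures, toy_structure_pdb
from omegafeat.io import (
    RunConfig,
    read_fasta,
    read_feature_matrix,
    write_fasta,
    write_feature_matrix,
)
from omegafeat.records import FeatureMatrix, SequenceRecord, SequenceSet
from omegafeat.registry import registry_counts, registry_list


class TestSequenceSet:
    def test_duplicate_id_rejected(self):
        recs = [
            SequenceRecord("s1", "dna", "AC"),
            SequenceRecord("s1", "dna", "GT"),
        ]
        with pytest.raises(ValueError, match="s1"):
            SequenceSet(recs, "dna")

    def test_alphabet_violation_reports_position(self):
        with pytest.raises(ValueError, match="position 3"):
            SequenceSet([SequenceRecord("s1", "dna", "ACXT")], "dna")

    def test_permissive_mode_drops_ambiguity_codes(self):
        s = SequenceSet(
            [SequenceRecord("s1", "dna", "ACNGT")], "dna", permissive=True
        )
        assert s[0].residues == "ACGT"

    def test_permissive_mode_still_rejects_unknown_characters(self):
        with pytest.raises(ValueError):
            SequenceSet(
                [SequenceRecord("s1", "dna", "AC9T")], "dna", permissive=True
            )


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACGT\n")
        s = read_fasta(str(p), "dna")
        assert len(s) == 1 and s[0].id == "s1" and s[0].residues == "ACGT"

    def test_label_dialect_round_trip(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1|1\nMKV\n>s2|0\nMRV\n")
        s = read_fasta(str(p), "protein")
        assert s.labels == ["1", "0"]
        q = tmp_path / "b.fasta"
        write_fasta(s, str(q))
        s2 = read_fasta(str(q), "protein")
        assert s2.ids == s.ids and s2.labels == s.labels
        assert [r.residues for r in s2] == [r.residues for r in s]

    def test_transliteration_u_to_t_and_back(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nacgu\n")
        assert read_fasta(str(p), "dna")[0].residues == "ACGT"
        assert read_fasta(str(p), "rna")[0].residues == "ACGU"

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        assert len(read_fasta(str(p), "dna")) == 0


class TestMatrixExport:
    def test_svm_light_omits_zeros_one_based(self, tmp_path):
        m = FeatureMatrix(np.array([[0.0, 3.5]]), ["a"], ["f1", "f2"], ["1"])
        p = tmp_path / "m.svm"
        write_feature_matrix(m, str(p), "svm_light")
        assert p.read_text().strip() == "1 2:3.5"

    @pytest.mark.parametrize("fmt", ["csv", "tsv"])
    def test_tabular_round_trip(self, tmp_path, fmt):
        rng = np.random.default_rng(0)
        m = FeatureMatrix(
            rng.normal(size=(4, 3)), ["a", "b", "c", "d"],
            ["x", "y", "z"], ["1", "0", "1", "0"],
        )
        p = tmp_path / f"m.{fmt}"
        write_feature_matrix(m, str(p), fmt)
        back = read_feature_matrix(str(p), fmt)
        assert back.sample_ids == m.sample_ids
        assert back.feature_names == m.feature_names
        assert back.labels == m.labels
        assert np.allclose(back.values, m.values, atol=1e-9)

    def test_arff_class_attribute_only_with_labels(self, tmp_path):
        m = FeatureMatrix(np.ones((2, 2)), ["a", "b"], ["x", "y"])
        p = tmp_path / "m.arff"
        write_feature_matrix(m, str(p), "arff")
        text = p.read_text()
        assert "@ATTRIBUTE class" not in text
        m2 = FeatureMatrix(np.ones((2, 2)), ["a", "b"], ["x", "y"], ["1", "0"])
        write_feature_matrix(m2, str(p), "arff")
        assert "@ATTRIBUTE class {0,1}" in p.read_text()

    def test_unknown_format_rejected(self, tmp_path):
        m = FeatureMatrix(np.ones((1, 1)))
        with pytest.raises(ValueError):
            write_feature_matrix(m, str(tmp_path / "x"), "xlsx")


class TestRegistry:
    def test_counts_match_manifest(self):
        counts = registry_counts()
        assert counts == {
            "protein": 71, "dna": 49, "rna": 37,
            "structure": 14, "ligand": 18, "total": 189,
        }

    def test_deterministic_order_and_filtering(self):
        a = [s.name for s in registry_list("structure")]
        b = [s.name for s in registry_list("structure")]
        assert a == b and len(a) == 14
        with pytest.raises(ValueError):
            registry_list("peptide")

    def test_names_unique_per_kind(self):
        for kind in ("protein", "dna", "rna", "structure", "ligand"):
            names = [s.name for s in registry_list(kind)]
            assert len(names) == len(set(names))


class TestFixtures:
    def test_deterministic_per_seed(self):
        a, b = generate_fixtures(1), generate_fixtures(1)
        for kind in ("protein", "dna", "rna"):
            assert [r.residues for r in a[kind]] == [r.residues for r in b[kind]]
        assert a["structure_pdb"] == b["structure_pdb"]

    def test_seed_sensitivity(self):
        a, b = generate_fixtures(1), generate_fixtures(2)
        assert [r.residues for r in a["dna"]] != [r.residues for r in b["dna"]]

    def test_toy_structure_complete_backbone(self):
        from omegafeat.structure import parse_structure

        model = parse_structure(toy_structure_pdb())
        assert len(model) >= 12
        assert all(r.has_backbone() for r in model.residues)
        assert all("CB" in r.atoms for r in model.residues)
        present = {r.name for r in model.residues}
        assert {"CYS", "HIS", "ASP", "GLU"} <= present

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_fixtures(1, n_seq=0)
        with pytest.raises(ValueError):
            generate_fixtures(1, seq_len=2)


class TestRunConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown configuration key"):
            RunConfig.from_dict({"scheme": "iDNA", "descriptors": ["Kmer"],
                                 "input": "x", "frobnicate": 1})

    def test_scheme_descriptor_mismatch_rejected(self):
        with pytest.raises(ValueError, match="not valid"):
            RunConfig.from_dict(
                {"scheme": "iDNA", "input": "x", "descriptors": ["AAC"]}
            )

    def test_valid_config_accepted(self):
        cfg = RunConfig.from_dict(
            {"scheme": "iRNA", "input": "x", "descriptors": ["Kmer", "MMI"],
             "seed": 7}
        )
        assert cfg.seed == 7 and cfg.format == "csv"
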