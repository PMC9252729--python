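"""Protein descriptors: worked examples, brute-force oracles, invariants."""

import math

import numpy as np
import pytest

from omegafeat import protein
from omegafeat.records import SequenceRecord, SequenceSet
from omegafeat.tables import (
    AA,
    HYDROPHILICITY_HW,
    HYDROPHOBICITY_PAAC,
    QSO_MATRICES,
    SIDE_CHAIN_MASS,
    standardize,
)
from conftest import make_set, random_protein

STD_H = standardize(HYDROPHOBICITY_PAAC)
ONE_PROP = {"h": STD_H}


class TestComposition:
    def test_aac_single_letter(self):
        names, v = protein.aac("AAAA")
        assert v[names.index("AAC.A")] == 1.0
        assert v.sum() == pytest.approx(1.0)
        assert np.count_nonzero(v) == 1

    def test_aac_uniform(self):
        _, v = protein.aac(AA)
        assert np.allclose(v, 0.05)

    def test_dpc_homopolymer(self):
        names, v = protein.dpc("AAAA")
        assert v[names.index("DPC.AA")] == 1.0
        assert v.sum() == pytest.approx(1.0)

    def test_cksaap_blocks_sum_to_one(self):
        rng = np.random.default_rng(3)
        seq = random_protein(rng, 30)
        names, v = protein.cksaap(seq, gap=2)
        for g in range(3):
            assert v[g * 400:(g + 1) * 400].sum() == pytest.approx(1.0)

    def test_cksaap_matches_pair_enumeration(self):
        # brute force: enumerate gapped pairs directly
        seq = "ACACA"
        names, v = protein.cksaap(seq, gap=1)
        for g in (0, 1):
            expect = np.zeros(400)
            pairs = [
                (seq[i], seq[i + g + 1]) for i in range(len(seq) - g - 1)
            ]
            for a, b in pairs:
                expect[20 * AA.index(a) + AA.index(b)] += 1 / len(pairs)
            assert np.allclose(v[g * 400:(g + 1) * 400], expect, atol=1e-12)

    def test_dde_zero_mean_under_background(self):
        # a dipeptide absent from the sequence has negative deviation
        names, v = protein.dde("AAAA")
        assert v[names.index("DDE.AA")] > 0
        assert v[names.index("DDE.WW")] < 0

    def test_asdc_counts_all_ordered_pairs(self):
        names, v = protein.asdc("AC")
        assert v[names.index("ASDC.AC")] == 1.0

    def test_sequence_reversal_symmetry(self):
        rng = np.random.default_rng(4)
        seq = random_protein(rng, 40)
        assert np.allclose(protein.aac(seq)[1], protein.aac(seq[::-1])[1])
        # DPC is direction-sensitive: find a witness
        assert not np.allclose(protein.dpc("ACD")[1], protein.dpc("DCA")[1])


class TestGroupedComposition:
    def test_gaac_homopolymer_aliphatic(self):
        names, v = protein.gaac("AAAA")
        assert v[names.index("GAAC.aliphatic")] == 1.0

    def test_gaac_sums_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            _, v = protein.gaac(random_protein(rng, 25))
            assert v.sum() == pytest.approx(1.0)

    def test_gdpc_matches_exhaustive_enumeration(self):
        from omegafeat.tables import AA_TO_FIVE_GROUP, FIVE_GROUP_NAMES

        seq = "AGWDE"
        names, v = protein.gdpc(seq)
        expect = np.zeros(25)
        for i in range(len(seq) - 1):
            a = FIVE_GROUP_NAMES.index(AA_TO_FIVE_GROUP[seq[i]])
            b = FIVE_GROUP_NAMES.index(AA_TO_FIVE_GROUP[seq[i + 1]])
            expect[5 * a + b] += 1 / (len(seq) - 1)
        assert np.allclose(v, expect)


class TestAutocorrelation:
    @pytest.mark.parametrize("variant", ["Moran", "Geary", "NMBroto"])
    def test_matches_double_loop_oracle(self, variant):
        rng = np.random.default_rng(11)
        for _ in range(50):
            seq = random_protein(rng, int(rng.integers(10, 40)))
            nlag = 3
            _, got = protein.autocorrelation(seq, variant, ONE_PROP, nlag)
            p = [STD_H[r] for r in seq]
            N = len(p)
            pbar = sum(p) / N
            for d in range(1, nlag + 1):
                if variant == "Moran":
                    num = sum(
                        (p[i] - pbar) * (p[i + d] - pbar) for i in range(N - d)
                    ) / (N - d)
                    den = sum((x - pbar) ** 2 for x in p) / N
                    expect = num / den
                elif variant == "Geary":
                    num = sum(
                        (p[i] - p[i + d]) ** 2 for i in range(N - d)
                    ) / (2 * (N - d))
                    den = sum((x - pbar) ** 2 for x in p) / (N - 1)
                    expect = num / den
                else:
                    expect = sum(
                        p[i] * p[i + d] for i in range(N - d)
                    ) / (N - d)
                assert got[d - 1] == pytest.approx(expect, abs=1e-9)

    def test_zero_variance_rule(self):
        _, v = protein.autocorrelation("AAAA", "Moran", ONE_PROP, 2)
        assert np.all(v == 0.0)
        _, v = protein.autocorrelation("AAAA", "Geary", ONE_PROP, 2)
        assert np.all(v == 0.0)

    def test_lag_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            protein.autocorrelation("AC", "Geary", ONE_PROP, 2)

    def test_covariance_matches_oracle(self):
        rng = np.random.default_rng(12)
        props = {"h": STD_H, "m": standardize(SIDE_CHAIN_MASS)}
        for _ in range(10):
            seq = random_protein(rng, 20)
            _, got = protein.auto_covariance(seq, "ACC", props, 2)
            series = {
                k: np.array([t[r] for r in seq]) for k, t in props.items()
            }
            expect = []
            N = len(seq)
            for k in props:
                s = series[k] - series[k].mean()
                for d in (1, 2):
                    expect.append(np.dot(s[:-d], s[d:]) / (N - d))
            for k1 in props:
                for k2 in props:
                    if k1 == k2:
                        continue
                    s1 = series[k1] - series[k1].mean()
                    s2 = series[k2] - series[k2].mean()
                    for d in (1, 2):
                        expect.append(np.dot(s1[:-d], s2[d:]) / (N - d))
            assert np.allclose(got, expect, atol=1e-9)


class TestQuasiSequenceOrder:
    def test_w_zero_degenerates_to_aac(self):
        seq = "MKVLAWFY"
        names, v = protein.qsorder(seq, nlag=3, w=0.0)
        _, a = protein.aac(seq)
        for m in QSO_MATRICES:
            block = v[names.index(f"QSOrder.{m}.A"):][:20]
            assert np.allclose(block, a, atol=1e-12)
            order = [v[names.index(f"QSOrder.{m}.d{d}")] for d in (1, 2, 3)]
            assert np.allclose(order, 0.0)

    def test_blocks_sum_to_one_per_matrix(self):
        rng = np.random.default_rng(13)
        seq = random_protein(rng, 30)
        names, v = protein.qsorder(seq, nlag=4, w=0.1)
        half = len(v) // 2
        assert v[:half].sum() == pytest.approx(1.0)
        assert v[half:].sum() == pytest.approx(1.0)

    def test_tau_of_identical_residues_is_zero(self):
        _, v = protein.socnumber("AA", nlag=1)
        assert np.allclose(v, 0.0)  # dist(A, A) = 0 in both matrices


class TestPseudoComposition:
    def test_lambda_zero_equals_aac(self):
        seq = "MKVLAWFY"
        _, v = protein.paac(seq, lam=0)
        _, a = protein.aac(seq)
        assert np.allclose(v, a, atol=1e-12)

    def test_theta_zero_for_homopolymer(self):
        names, v = protein.paac("AAAAA", lam=3)
        assert np.allclose(v[20:], 0.0)

    def test_paac_matches_direct_transcription(self):
        # independent two-pass evaluation of the formula
        seq, lam, w = "MKVL", 2, 0.05
        props = [
            standardize(HYDROPHOBICITY_PAAC),
            standardize(HYDROPHILICITY_HW),
            standardize(SIDE_CHAIN_MASS),
        ]
        N = len(seq)
        thetas = []
        for j in range(1, lam + 1):
            total = 0.0
            for i in range(N - j):
                total += sum(
                    (p[seq[i]] - p[seq[i + j]]) ** 2 for p in props
                ) / 3.0
            thetas.append(total / (N - j))
        freqs = [seq.count(a) / N for a in AA]
        denom = sum(freqs) + w * sum(thetas)
        expect = [f / denom for f in freqs] + [w * t / denom for t in thetas]
        _, got = protein.paac(seq, lam=lam, w=w)
        assert np.allclose(got, expect, atol=1e-9)

    def test_apaac_dimension_and_normalization(self):
        _, v = protein.apaac("MKVLAW", lam=3)
        assert len(v) == 20 + 6

    def test_lambda_too_large_rejected(self):
        with pytest.raises(ValueError):
            protein.paac("MKV", lam=3)


class TestPseKRAAC:
    def test_identity_reduction_equals_aac(self):
        seq = "MKVLAWFY"
        names, v = protein.psekraac(seq, "type1", cluster_count=20, k=1)
        _, a = protein.aac(seq)
        # identity mapping preserves the canonical residue order
        assert np.allclose(v, a, atol=1e-12)

    def test_ktuple_output_sums_to_one(self):
        rng = np.random.default_rng(14)
        for tag in ("type2", "type6B", "type16"):
            _, v = protein.psekraac(random_protein(rng, 25), tag,
                                    cluster_count=5, k=2)
            assert v.sum() == pytest.approx(1.0)

    def test_two_cluster_homopolymer_single_bin(self):
        _, v = protein.psekraac("AAAA", "type3A", cluster_count=2, k=2)
        assert np.count_nonzero(v) == 1

    def test_invalid_cluster_count_rejected(self):
        with pytest.raises(ValueError):
            protein.psekraac("AAAA", "type1", cluster_count=7)

    def test_sixteen_families(self):
        from omegafeat.reduced import SCHEME_FAMILIES, SCHEME_TAGS

        assert len(SCHEME_FAMILIES) == 16
        assert len(SCHEME_TAGS) == 19


class TestResidueEncoding:
    def test_binary_one_hot(self):
        s = make_set(["A"], "protein")
        fm = protein.residue_encoding(s, "binary")
        assert fm.values.sum() == 1.0
        assert fm.values[0][0] == 1.0  # alanine is first in canonical order

    def test_zscale_width_five(self):
        s = make_set(["MKV"], "protein")
        fm = protein.residue_encoding(s, "ZScale")
        assert fm.shape == (1, 15)

    def test_blosum62_row_matches_bundled_matrix(self):
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        s = make_set(["W"], "protein")
        fm = protein.residue_encoding(s, "BLOSUM62")
        assert np.allclose(fm.values[0], [float(m["W"][b]) for b in AA])

    def test_unequal_lengths_rejected(self):
        s = make_set(["MK", "MKV"], "protein")
        with pytest.raises(ValueError, match="equal-length"):
            protein.residue_encoding(s, "binary")

    @pytest.mark.parametrize("variant", protein.RESIDUE_ENCODINGS)
    def test_widths_match_manifest(self, variant):
        s = make_set(["MKVL"], "protein")
        fm = protein.residue_encoding(s, variant)
        assert fm.shape[1] == 4 * protein.encoding_width(variant)


class TestKnnDescriptor:
    def test_identical_query_gets_unit_proportion(self):
        train = make_set(["MKVLAW", "MRVIAW", "GGGGGG"], "protein",
                         labels=["1", "1", "0"])
        query = make_set(["MKVLAW"], "protein")
        fm = protein.knn_descriptor(query, train, k_fractions=[0.34])
        # k = ceil(0.34*3) = 2: the two class-1 sequences are nearest
        assert np.allclose(fm.values[0], [0.0, 1.0])

    def test_proportions_sum_to_one(self, protein_set):
        fm = protein.knn_descriptor(protein_set, protein_set,
                                    k_fractions=[0.2, 0.5])
        n_classes = len(set(protein_set.labels))
        for row in fm.values:
            for b in range(2):
                assert row[b * n_classes:(b + 1) * n_classes].sum() == (
                    pytest.approx(1.0)
                )

    def test_neighbour_ranking_matches_all_pairs_scores(self):
        from Bio import Align
        from Bio.Align import substitution_matrices

        train = make_set(["MKVLAW", "MKVIAW", "GGGGGG", "MKVLAF"], "protein",
                         labels=["1", "0", "0", "1"])
        query = make_set(["MKVLAW"], "protein")
        fm = protein.knn_descriptor(query, train, k_fractions=[0.25])
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score, al.extend_gap_score = -10.0, -1.0
        q = query[0].residues
        sims = [
            2 * al.score(q, t.residues) / (al.score(q, q) + al.score(t.residues, t.residues))
            for t in train
        ]
        best = int(np.argmax(sims))
        assert train.labels[best] == "1"
        assert np.allclose(fm.values[0], [0.0, 1.0])

    def test_unlabelled_training_rejected(self):
        train = make_set(["MKVLAW", "MRVIAW"], "protein")
        with pytest.raises(ValueError, match="label"):
            protein.knn_descriptor(train, train, k_fractions=[0.5])


class TestDispatcher:
    def test_composition_blocks_sum_to_one(self, protein_set):
        for name in ("AAC", "GAAC", "DPC_type1", "TPC_type1", "CTriad",
                     "ASDC", "GDPC_type1", "GTPC_type1"):
            fm = protein.compute(protein_set, name)
            assert np.allclose(fm.values.sum(axis=1), 1.0, atol=1e-9)
            assert (fm.values >= 0).all()

    def test_wrong_kind_rejected(self, dna_set):
        with pytest.raises(ValueError, match="protein"):
            protein.compute(dna_set, "AAC")

    def test_unknown_descriptor_rejected(self, protein_set):
        with pytest.raises(ValueError):
            protein.compute(protein_set, "NOPE")
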