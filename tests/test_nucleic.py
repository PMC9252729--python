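"""DNA/RNA descriptors: worked examples, entropy/covariance oracles."""

import itertools
import math

import numpy as np
import pytest

from omegafeat import nucleic
from omegafeat.tables import EIIP, dinuc_panel, reverse_complement
from conftest import make_set, random_dna


class TestKmerComposition:
    def test_mononucleotide_uniform(self):
        names, v = nucleic.kmer("ACGT", "dna", k=1)
        assert np.allclose(v, 0.25)

    def test_dinucleotide_three_windows(self):
        names, v = nucleic.kmer("ACGT", "dna", k=2)
        for m in ("AC", "CG", "GT"):
            assert v[names.index(f"Kmer2.{m}")] == pytest.approx(1 / 3)

    def test_rckmer_collapses_reverse_complements(self):
        names, v = nucleic.rckmer("AAAA", "dna", k=1)
        assert names == ["RCKmer1.A", "RCKmer1.C"]  # {A,T} and {C,G}
        assert v[0] == 1.0

    def test_rckmer_reverse_complement_invariant(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            seq = random_dna(rng, 30)
            rc = reverse_complement(seq, "dna")
            _, a = nucleic.rckmer(seq, "dna", k=3)
            _, b = nucleic.rckmer(rc, "dna", k=3)
            assert np.allclose(a, b, atol=1e-12)
        # plain Kmer has a witness where the invariance fails
        _, ka = nucleic.kmer("AAAC", "dna", k=2)
        _, kb = nucleic.kmer(reverse_complement("AAAC", "dna"), "dna", k=2)
        assert not np.allclose(ka, kb)

    def test_rna_uses_a_u_complementation(self):
        names, _ = nucleic.rckmer("ACGU", "rna", k=1)
        assert names == ["RCKmer1.A", "RCKmer1.C"]  # A~U, C~G

    def test_mismatch_profile_counts_within_m(self):
        # window AAA contributes to every k-mer within 1 substitution
        names, v = nucleic.mismatch_profile("AAA", "dna", k=3, m=1)
        hit = [n for n, x in zip(names, v) if x > 0]
        assert len(hit) == 1 + 3 * 3  # exact + single-substitution variants

    def test_subsequence_profile_plain_counts(self):
        names, v = nucleic.subsequence_profile("ACG", "dna", k=2)
        # subsequences: AC, AG, CG -> 1/3 each
        for m in ("AC", "AG", "CG"):
            assert v[names.index(f"Subsequence.{m}")] == pytest.approx(1 / 3)


class TestPositionEncoding:
    def test_anf_running_frequency(self):
        fm = nucleic.anf(make_set(["AAAA"], "dna"))
        assert np.allclose(fm.values[0], [1, 1, 1, 1])
        fm = nucleic.anf(make_set(["AC"], "dna"))
        assert np.allclose(fm.values[0], [1.0, 0.5])

    def test_binary_one_hot(self):
        fm = nucleic.binary(make_set(["A"], "dna"))
        assert np.allclose(fm.values[0], [1, 0, 0, 0])

    def test_ncp_codes(self):
        fm = nucleic.ncp(make_set(["ACGT"], "dna"))
        assert np.allclose(
            fm.values[0], [1, 1, 1, 0, 1, 0, 1, 0, 0, 0, 0, 1]
        )

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            nucleic.binary(make_set(["AC", "ACG"], "dna"))


class TestEiip:
    def test_per_position_constants(self):
        fm = nucleic.eiip(make_set(["AAAA"], "dna"))
        assert np.allclose(fm.values[0], [EIIP["A"]] * 4)

    def test_pse_eiip_homopolymer_single_entry(self):
        names, v = nucleic.pse_eiip("AAAA", "dna")
        nz = np.nonzero(v)[0]
        assert len(nz) == 1
        assert names[nz[0]] == "PseEIIP.AAA"
        assert v[nz[0]] == pytest.approx(3 * EIIP["A"])

    def test_pse_eiip_permutation_invariance_via_counts(self):
        # permutations preserving trinucleotide counts preserve PseEIIP
        seq = "ACGACG"
        rot = "CGACGA"  # same trinucleotide multiset? verify by counts
        _, a = nucleic.kmer(seq, "dna", k=3)
        _, b = nucleic.kmer(rot, "dna", k=3)
        if np.allclose(a, b):
            _, pa = nucleic.pse_eiip(seq, "dna")
            _, pb = nucleic.pse_eiip(rot, "dna")
            assert np.allclose(pa, pb)


class TestNucAutocorrelation:
    def test_homopolymer_gives_zero(self):
        _, v = nucleic.nuc_autocorrelation("AAAAAAAA", "dna", "Moran", nlag=2)
        assert np.allclose(v, 0.0)
        _, v = nucleic.nuc_covariance("AAAAAAAA", "dna", "AC", nlag=2)
        assert np.allclose(v, 0.0)

    @pytest.mark.parametrize("variant", ["Moran", "Geary", "NMBroto"])
    def test_matches_double_loop_oracle(self, variant):
        rng = np.random.default_rng(21)
        panel = dinuc_panel("dna")
        pname, table = next(iter(panel.items()))
        for _ in range(50):
            seq = random_dna(rng, int(rng.integers(10, 30)))
            _, got = nucleic.nuc_autocorrelation(
                seq, "dna", variant, properties={pname: table}, nlag=2
            )
            p = [table[seq[i:i + 2]] for i in range(len(seq) - 1)]
            N = len(p)
            pbar = sum(p) / N
            den0 = sum((x - pbar) ** 2 for x in p)
            for d in (1, 2):
                if variant == "Moran":
                    num = sum((p[i] - pbar) * (p[i + d] - pbar)
                              for i in range(N - d)) / (N - d)
                    expect = 0.0 if den0 == 0 else num / (den0 / N)
                elif variant == "Geary":
                    num = sum((p[i] - p[i + d]) ** 2
                              for i in range(N - d)) / (2 * (N - d))
                    expect = 0.0 if den0 == 0 else num / (den0 / (N - 1))
                else:
                    expect = sum(p[i] * p[i + d]
                                 for i in range(N - d)) / (N - d)
                assert got[d - 1] == pytest.approx(expect, abs=1e-9)

    def test_trinucleotide_length_precondition(self):
        with pytest.raises(ValueError):
            nucleic.nuc_covariance("ACGT", "dna", "AC", order=3, nlag=3)

    def test_trinucleotide_panel_rejected_for_rna(self):
        with pytest.raises(ValueError, match="DNA-only"):
            nucleic.nuc_covariance("ACGUACGU", "rna", "AC", order=3, nlag=1)


class TestMMI:
    def test_homopolymer_all_zero(self):
        _, v = nucleic.mmi("AAAAAA", "dna")
        assert np.allclose(v, 0.0)

    def test_matches_entropy_oracle(self):
        seq = "ACGTACGT"
        names, got = nucleic.mmi(seq, "dna")
        alpha = "ACGT"
        f1 = {a: seq.count(a) / len(seq) for a in alpha}
        f2, f3 = {}, {}
        for i in range(len(seq) - 1):
            k = "".join(sorted(seq[i:i + 2]))
            f2[k] = f2.get(k, 0) + 1 / (len(seq) - 1)
        for i in range(len(seq) - 2):
            k = "".join(sorted(seq[i:i + 3]))
            f3[k] = f3.get(k, 0) + 1 / (len(seq) - 2)

        def h(p):
            return -p * math.log(p) if p > 0 else 0.0

        expect = {}
        for a, b in itertools.combinations_with_replacement(alpha, 2):
            expect[f"MMI.{a}{b}"] = (
                h(f1[a]) + h(f1[b]) - h(f2.get("".join(sorted(a + b)), 0))
            )
        for a, b, c in itertools.combinations_with_replacement(alpha, 3):
            i_ab = expect[f"MMI.{a}{b}"]
            cond = (
                h(f2.get("".join(sorted(a + c)), 0))
                + h(f2.get("".join(sorted(b + c)), 0))
                - h(f1[c])
                - h(f3.get("".join(sorted(a + b + c)), 0))
            )
            expect[f"MMI.{a}{b}{c}"] = i_ab - cond
        for n, g in zip(names, got):
            assert g == pytest.approx(expect[n], abs=1e-9)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            seq = random_dna(rng, 25)
            _, a = nucleic.mmi(seq, "dna")
            _, b = nucleic.mmi(seq[::-1], "dna")
            assert np.allclose(a, b, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            nucleic.mmi("AC", "dna")


class TestPseudoKnc:
    def test_lambda_zero_equals_dinucleotide_composition(self):
        seq = "ACGTACGT"
        _, v = nucleic.pseudo_knc(seq, "dna", "PseDNC", lam=0)
        _, d = nucleic.kmer(seq, "dna", k=2)
        assert np.allclose(v, d, atol=1e-12)

    def test_parallel_variants_sum_to_one(self):
        rng = np.random.default_rng(23)
        for variant in ("PseDNC", "PseKNC", "PC-PseDNC", "PC-PseTNC"):
            seq = random_dna(rng, 30)
            _, v = nucleic.pseudo_knc(seq, "dna", variant, lam=2)
            assert v.sum() == pytest.approx(1.0)

    def test_psednc_matches_two_pass_transcription(self):
        seq, lam, w = "ACGTACGT", 2, 0.1
        panel = dinuc_panel("dna")
        tables = list(panel.values())
        N = len(seq) - 1
        thetas = []
        for j in (1, 2):
            s = 0.0
            for i in range(N - j):
                a, b = seq[i:i + 2], seq[i + j:i + j + 2]
                s += sum((t[a] - t[b]) ** 2 for t in tables) / len(tables)
            thetas.append(s / (N - j))
        _, freqs = nucleic.kmer(seq, "dna", k=2)
        denom = freqs.sum() + w * sum(thetas)
        expect = np.concatenate(
            [freqs / denom, np.array(thetas) * w / denom]
        )
        _, got = nucleic.pseudo_knc(seq, "dna", "PseDNC", lam=lam, w=w)
        assert np.allclose(got, expect, atol=1e-9)

    def test_lambda_too_large_rejected(self):
        with pytest.raises(ValueError):
            nucleic.pseudo_knc("ACGT", "dna", "PseDNC", lam=5)


class TestZcurve:
    def test_homopolymer_purine_axis(self):
        names, v = nucleic.zcurve("AAAA", "dna", "9bit")
        x = [v[i] for i, n in enumerate(names) if n.endswith(".x")]
        assert np.allclose(x, 1.0)  # A is a purine: x maximal

    @pytest.mark.parametrize(
        "variant,dim",
        [("9bit", 9), ("12bit", 12), ("36bit", 36), ("48bit", 48),
         ("144bit", 144)],
    )
    def test_dimensions(self, variant, dim):
        rng = np.random.default_rng(24)
        _, v = nucleic.zcurve(random_dna(rng, 40), "dna", variant)
        assert len(v) == dim

    def test_hand_evaluated_12bit(self):
        # "AC": only dinucleotide AC -> after A: x=-1 (C), y=+1, z=-1
        names, v = nucleic.zcurve("AC", "dna", "12bit")
        assert v[names.index("Zcurve12.A.x")] == -1.0
        assert v[names.index("Zcurve12.A.y")] == 1.0
        assert v[names.index("Zcurve12.A.z")] == -1.0


class TestPstnp:
    def test_propensity_signs_follow_classes(self):
        seqs = make_set(
            ["AAAA", "AAAA", "CCCC", "CCCC"], "dna",
            labels=["1", "1", "0", "0"],
        )
        fm = nucleic.pstnp(seqs)
        # AAA occurs only in class "1": positive propensity for those rows
        assert (fm.values[0] > 0).all() and (fm.values[2] < 0).all()

    def test_double_strand_merges_complements(self):
        # AAA and TTT share a canonical class in double-strand mode
        seqs = make_set(
            ["AAAA", "TTTT", "CCCC", "GGGG"], "dna",
            labels=["1", "1", "0", "0"],
        )
        fm = nucleic.pstnp(seqs, double_strand=True)
        assert np.allclose(fm.values[0], fm.values[1])


class TestRoster:
    def test_rna_excludes_dna_only_sets(self, rna_set):
        assert len(nucleic.DNA_DESCRIPTORS) == 49
        assert len(nucleic.RNA_DESCRIPTORS) == 37
        with pytest.raises(ValueError, match="not available"):
            nucleic.compute(rna_set, "EIIP")

    def test_composition_outputs_finite_and_normalized(self, dna_set):
        for name in ("NAC", "DNC", "TNC", "Kmer", "RCKmer", "ASDC"):
            fm = nucleic.compute(dna_set, name)
            assert np.isfinite(fm.values).all()
            assert np.allclose(fm.values.sum(axis=1), 1.0, atol=1e-9)

    def test_knn_identical_pair_unit_proportion(self):
        seqs = make_set(["ACGTACGT", "TTTTTTTT"], "dna", labels=["1", "0"])
        fm = nucleic.knn_descriptor(seqs, seqs, k_fractions=[0.5])
        assert np.allclose(fm.values[0], [0.0, 1.0])
        assert np.allclose(fm.values[1], [1.0, 0.0])
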