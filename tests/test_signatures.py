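"""96-class spectra, exposure attribution, psoralen vector, damage potential."""

import numpy as np
import pandas as pd
import pytest

from microclone.core import CLASSES_96, MutationCall, class_label
from microclone.signatures import (
    SignatureCatalog,
    cosine_similarity,
    damage_potential,
    default_catalog,
    fit_exposures,
    make_toy_genes,
    psoralen_reference,
    spectrum_96,
    _translate,
)


CAT = default_catalog()


class TestSpectrum96:
    def test_single_mutation_counted_once(self):
        m = MutationCall("chr1", 100, "C", "T", trinucleotide="A[C>T]A")
        spec, excluded = spectrum_96([m])
        assert spec.sum() == 1 and excluded == 0
        assert spec[CLASSES_96.index("A[C>T]A")] == 1

    def test_reverse_complement_pair_same_class(self):
        # G>A at TGT is the revcomp of C>T at ACA
        assert class_label("TGT", "A") == class_label("ACA", "T") == "A[C>T]A"

    def test_missing_context_excluded_with_count(self):
        calls = [
            MutationCall("chr1", 1, "C", "T", trinucleotide="A[C>T]A"),
            MutationCall("chr1", 2, "C", "T"),
        ]
        spec, excluded = spectrum_96(calls)
        assert spec.sum() == 1 and excluded == 1

    def test_sampled_spectrum_close_to_source(self):
        rng = np.random.default_rng(0)
        source = CAT["SBS7b-like"]
        counts = rng.multinomial(10_000, source)
        assert cosine_similarity(counts, source) >= 0.99


class TestPsoralenReference:
    def test_mass_confined_to_tpa_classes(self):
        vec = psoralen_reference()
        for i, lab in enumerate(CLASSES_96):
            if not (lab[2:4] == "T>" and lab.endswith("A")):
                assert vec[i] == 0.0
        assert vec.sum() == pytest.approx(1.0)

    def test_t_to_a_emphasized_by_default(self):
        vec = psoralen_reference()
        mass = {
            sub: sum(vec[i] for i, lab in enumerate(CLASSES_96) if sub in lab)
            for sub in ("T>A", "T>C", "T>G")
        }
        assert mass["T>A"] > mass["T>C"] > mass["T>G"]

    def test_matches_synthetic_puva_clone_spectra(self):
        # spectra of generator clones dominated by psoralen resemble the vector
        rng = np.random.default_rng(1)
        clone = rng.multinomial(10_000, psoralen_reference()) + rng.multinomial(
            600, CAT["SBS7b-like"]
        )
        assert cosine_similarity(clone, psoralen_reference()) >= 0.9


class TestFitExposures:
    def test_vertex_identifiability(self):
        spec = CAT["SBS1/5-like"] * 500
        ex = fit_exposures(spec, CAT)
        assert ex["SBS1/5-like"] == pytest.approx(500, abs=1.0)
        assert ex.drop(["SBS1/5-like", "unassigned"]).max() < 1.0

    def test_balanced_mixture_recovered(self):
        rng = np.random.default_rng(2)
        spec = rng.multinomial(1000, CAT["SBS7b-like"]) + rng.multinomial(
            1000, CAT["psoralen"]
        )
        ex = fit_exposures(spec, CAT)
        assert ex["SBS7b-like"] == pytest.approx(1000, rel=0.10)
        assert ex["psoralen"] == pytest.approx(1000, rel=0.10)

    def test_conservation_and_scale_equivariance(self):
        rng = np.random.default_rng(3)
        spec = rng.multinomial(800, CAT["SBS7b-like"]).astype(float)
        ex = fit_exposures(spec, CAT)
        assert ex.sum() == pytest.approx(spec.sum())
        ex2 = fit_exposures(2 * spec, CAT)
        assert np.allclose(ex2.to_numpy(), 2 * ex.to_numpy(), atol=1e-4)

    def test_all_zero_spectrum(self):
        ex = fit_exposures(np.zeros(96), CAT)
        assert (ex == 0).all()

    def test_matches_brute_force_ml_on_small_catalog(self):
        # grid search over the 2-simplex as an independent ML oracle
        small = SignatureCatalog(
            names=["SBS7b-like", "SBS1/5-like", "psoralen"],
            matrix=np.vstack(
                [CAT["SBS7b-like"], CAT["SBS1/5-like"], CAT["psoralen"]]
            ),
        )
        rng = np.random.default_rng(4)
        for _ in range(5):
            w_true = rng.dirichlet([1, 1, 1])
            spec = rng.multinomial(50, w_true @ small.matrix).astype(float)
            grid = np.linspace(0, 1, 101)
            best, best_ll = None, -np.inf
            for w1 in grid:
                for w2 in np.linspace(0, 1 - w1, int(101 * (1 - w1)) + 1):
                    w = np.array([w1, w2, 1 - w1 - w2])
                    mix = np.clip(w @ small.matrix, 1e-300, None)
                    ll = spec @ np.log(mix)
                    if ll > best_ll:
                        best_ll, best = ll, w
            ex = fit_exposures(spec, small, sparsity_threshold=0.0)
            got = ex.iloc[:3].to_numpy() / spec.sum()
            assert np.allclose(got, best, atol=0.02)


class TestCosineSimilarity:
    def test_identical_orthogonal_and_zero(self):
        a = np.zeros(96)
        a[0] = 1
        b = np.zeros(96)
        b[1] = 1
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert cosine_similarity(a, b) == 0.0
        with pytest.warns(UserWarning):
            assert cosine_similarity(a, np.zeros(96)) == 0.0

    def test_shared_indel_process_gives_high_similarity(self):
        # high- and low-psoralen clones draw indel spectra from one process
        rng = np.random.default_rng(5)
        process = rng.dirichlet(np.ones(20))
        high = rng.multinomial(3000, process)
        low = rng.multinomial(2500, process)
        assert cosine_similarity(high, low) > 0.99


class TestDamagePotential:
    def test_uniform_vs_uniform_is_identity(self):
        genes = make_toy_genes(n_genes=3, seed=11)
        out = damage_potential(np.full(96, 1 / 96), genes, baseline="uniform")
        assert np.allclose(out["ratio"], 1.0)

    def test_one_hot_signature_matches_hand_enumeration(self):
        # tiny intron-less gene: a one-hot signature's class fractions are
        # the annotation-class shares among that trinucleotide's mutations,
        # hand-counted here by direct enumeration
        from microclone.signatures import ToyGene

        seq = "TT" + "ATGGCTGCTGATGCTGCTGCTGCTTAA" + "TT"
        gene = ToyGene("toy", seq, exons=[(2, 29)])
        target = "G[C>T]T"
        sig = np.zeros(96)
        sig[CLASSES_96.index(target)] = 1.0
        out = damage_potential(sig, [gene], baseline="uniform")

        counts = {"synonymous": 0, "missense": 0, "nonsense": 0}
        cds = gene.cds()
        for i in range(len(cds)):
            tri = (seq[2:29])[max(i - 1, 0):i + 2] if 0 < i < len(cds) - 1 else None
            if tri is None:
                tri = seq[2 + i - 1:2 + i + 2]
            for alt in "ACGT":
                if alt == cds[i]:
                    continue
                if class_label(seq[2 + i - 1:2 + i + 2], alt) != target:
                    continue
                codon_i, off = divmod(i, 3)
                codon = cds[3 * codon_i:3 * codon_i + 3]
                new = codon[:off] + alt + codon[off + 1:]
                if _translate(new) == _translate(codon):
                    counts["synonymous"] += 1
                elif _translate(new) == "*":
                    counts["nonsense"] += 1
                else:
                    counts["missense"] += 1
        total = sum(counts.values())
        assert total > 0
        for ann, n in counts.items():
            got = out["fraction_signature"].get(ann, 0.0)
            if np.isnan(got):
                got = 0.0
            assert got == pytest.approx(n / total)

    def test_psoralen_less_synonymous_than_uv(self):
        genes = make_toy_genes(n_genes=8, n_codons=60, seed=13)
        out = damage_potential(
            psoralen_reference(), genes, baseline=CAT["SBS7b-like"]
        )
        assert out.loc["synonymous", "ratio"] < 1.0

    def test_invalid_orf_excluded_with_warning(self):
        from microclone.signatures import ToyGene

        bad = ToyGene("bad", "TTATGAATT", exons=[(2, 7)])  # length 5, not /3
        good = make_toy_genes(n_genes=1, seed=1)[0]
        with pytest.warns(UserWarning, match="no valid ORF"):
            out = damage_potential(np.full(96, 1 / 96), [bad, good])
        assert np.allclose(out["ratio"], 1.0)
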