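import math

import numpy as np
import pytest

import hlatag as ht
from hlatag.io import MISSING
from hlatag.model import hla_genotype_prior, marginalize_snp

from _oracles import grid_search_loglik
from conftest import make_typing


def _table(columns, sample_ids=None):
    snps = [
        ht.SnpRecord(name, "6", 100 * (j + 1), "A", "G")
        for j, name in enumerate(columns)
    ]
    calls = np.array(list(columns.values()), dtype=np.int8).T
    ids = sample_ids or [f"S{i}" for i in range(calls.shape[0])]
    return ht.GenotypeTable(snps, ids, calls)


class TestEnumerateCompatiblePairs:
    def test_degenerate_single_haplotype(self, one_snp, a01):
        m = ht.HaplotypeModel.from_freqs("A", "high", one_snp, {(a01, "a"): 1.0})
        pairs = ht.enumerate_compatible_pairs(m, np.array([0]))
        assert len(pairs) == 1
        h1, h2, w = pairs[0]
        assert (str(h1.hla), h1.snp_alleles, w) == ("A*01:01", "a", 1.0)

    def test_heterozygote_both_orders(self, two_hap_model):
        pairs = ht.enumerate_compatible_pairs(two_hap_model, np.array([1]))
        assert len(pairs) == 2
        assert sum(w for _, _, w in pairs) == pytest.approx(0.48)
        configs = {(h1.snp_alleles, h2.snp_alleles) for h1, h2, _ in pairs}
        assert configs == {("a", "b"), ("b", "a")}

    def test_missing_snp_marginalizes(self, two_hap_model):
        pairs = ht.enumerate_compatible_pairs(two_hap_model, np.array([MISSING]))
        assert sum(w for _, _, w in pairs) == pytest.approx(1.0)

    def test_hla_constraint_restricts_pairs(self, two_hap_model, a01, a02):
        pairs = ht.enumerate_compatible_pairs(
            two_hap_model,
            np.array([MISSING]),
            (ht.AlleleSet.of(a01), ht.AlleleSet.of(a01)),
        )
        assert sum(w for _, _, w in pairs) == pytest.approx(0.36)

    def test_incompatible_genotype_yields_empty_list(self, one_snp, a01):
        m = ht.HaplotypeModel.from_freqs("A", "high", one_snp, {(a01, "a"): 1.0})
        assert ht.enumerate_compatible_pairs(m, np.array([2])) == []


class TestFitEm:
    def test_single_haplotype_population(self):
        gt = _table({"rs1": [0, 0, 0, 0]})
        truth = make_typing([(f"S{i}", "A", "A*0101", "A*0101") for i in range(4)])
        model, diag = ht.fit_em(gt, truth, "A", "high", seed=0)
        assert model.n_haplotypes == 1
        assert model.freq_of(ht.parse_allele("A*01:01"), "a") == pytest.approx(1.0)
        assert diag.final_loglik == pytest.approx(0.0, abs=1e-9)

    def test_double_heterozygote_saddle_is_escaped(self):
        n = 6
        gt = _table({"rs1": [1] * n})
        truth = make_typing([(f"S{i}", "A", "A*0101", "A*0201") for i in range(n)])
        model, diag = ht.fit_em(gt, truth, "A", "high", seed=1)
        # optimum: the two repulsion-phase configurations, likelihood 0.5/sample
        assert diag.final_loglik == pytest.approx(n * math.log(0.5), abs=1e-6)

    def test_em_matches_simplex_grid_oracle(self):
        rng = np.random.default_rng(7)
        # truth model with 4 joint haplotypes over 2 SNPs, 2 alleles
        support = [("A*0101", "aa"), ("A*0101", "ab"), ("A*0201", "bb"), ("A*0201", "ba")]
        f = rng.dirichlet([2, 2, 2, 2])
        n = 18
        hap_idx = rng.choice(4, size=(n, 2), p=f)
        bits = {"a": 0, "b": 1}
        rows, truth_rows = [], []
        for i, (k1, k2) in enumerate(hap_idx):
            (al1, s1), (al2, s2) = support[k1], support[k2]
            geno = [bits[s1[j]] + bits[s2[j]] for j in range(2)]
            rows.append(geno)
            truth_rows.append((f"S{i}", "A", al1, al2))
        gt = _table(
            {"rs1": [r[0] for r in rows], "rs2": [r[1] for r in rows]}
        )
        truth = make_typing(truth_rows)
        model, diag = ht.fit_em(gt, truth, "A", "high", seed=2, prune_eps=1e-7)

        # oracle: enumerate compatible support-index pairs per sample
        pair_lists = []
        for i, (k1, k2) in enumerate(hap_idx):
            geno = rows[i]
            tr = {support[k1][0], support[k2][0]}
            pairs = []
            for a in range(4):
                for b in range(4):
                    ga = [bits[support[a][1][j]] + bits[support[b][1][j]] for j in range(2)]
                    alleles = {support[a][0], support[b][0]}
                    if ga == geno and alleles == tr:
                        pairs.append((a, b))
            pair_lists.append(pairs)
        grid_ll = grid_search_loglik(pair_lists, k=4, step=0.01)
        assert diag.final_loglik >= grid_ll - 1e-3

    def test_monotone_loglik_and_normalized_freqs(self):
        rng = np.random.default_rng(9)
        spec = ht.PopulationSpec(
            "p", n_hla_alleles=4, n_snps=5, tags_per_allele=2,
            haplotype_noise=0.05, recomb_rate=0.0,
        )
        coh = ht.sample_cohort(
            ht.CohortSpec(populations=((spec, 80),), seed=13, missing_rate=0.05)
        )
        model, diag = ht.fit_em(coh.genotypes, coh.hla, "A", "high", seed=4)
        diffs = np.diff(diag.loglik)
        assert (diffs >= -1e-10).all()
        assert model.freqs.sum() == pytest.approx(1.0, abs=1e-8)
        for i in range(coh.genotypes.n_samples):
            post, _ = ht.posterior_hla(model, coh.genotypes.calls[i])
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-8)

    def test_sample_permutation_invariance(self):
        spec = ht.PopulationSpec(
            "p", n_hla_alleles=3, n_snps=4, tags_per_allele=1,
            haplotype_noise=0.1, recomb_rate=0.0,
        )
        coh = ht.sample_cohort(ht.CohortSpec(populations=((spec, 50),), seed=21))
        gt = coh.genotypes
        rng = np.random.default_rng(0)
        perm = rng.permutation(gt.n_samples)
        gt2 = ht.GenotypeTable(
            gt.snps, [gt.sample_ids[i] for i in perm], gt.calls[perm]
        )
        m1, _ = ht.fit_em(gt, coh.hla, "A", "high", seed=5)
        m2, _ = ht.fit_em(gt2, coh.hla, "A", "high", seed=5)
        f1 = dict((str(j), v) for j, v in m1.freq_items())
        f2 = dict((str(j), v) for j, v in m2.freq_items())
        assert f1.keys() == f2.keys()
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-6)

    def test_missing_truth_is_a_precondition_error(self):
        gt = _table({"rs1": [0, 0]})
        truth = make_typing([("S0", "A", "A*0101", "A*0101")])
        with pytest.raises(ht.ValidationError):
            ht.fit_em(gt, truth, "A", "high")


class TestExtendAndDrop:
    def _training(self, n=40, seed=3):
        spec = ht.PopulationSpec(
            "p", n_hla_alleles=3, n_snps=3, tags_per_allele=1,
            haplotype_noise=0.0, recomb_rate=0.0,
        )
        coh = ht.sample_cohort(ht.CohortSpec(populations=((spec, n),), seed=seed))
        return coh

    def test_extend_zero_snp_model_equals_cold_start(self):
        coh = self._training()
        gt = coh.genotypes
        base, _ = ht.fit_em(gt, coh.hla, "A", "high", snp_ids=[], seed=0)
        ext, diag_ext = ht.extend_model(base, gt.snps[0], gt, coh.hla, seed=1)
        cold, diag_cold = ht.fit_em(
            gt, coh.hla, "A", "high", snp_ids=[gt.snps[0].snp_id], seed=2
        )
        assert diag_ext.final_loglik == pytest.approx(
            diag_cold.final_loglik, abs=1e-6
        )

    def test_extend_with_monomorphic_snp_changes_nothing(self):
        coh = self._training()
        gt = coh.genotypes
        mono = ht.SnpRecord("mono", "6", 999_000_000, "A", "G")
        gt2 = gt.merge_snps(
            ht.GenotypeTable([mono], gt.sample_ids, np.zeros((gt.n_samples, 1), np.int8))
        )
        base, diag0 = ht.fit_em(gt, coh.hla, "A", "high", seed=0)
        ext, diag1 = ht.extend_model(base, mono, gt2, coh.hla, seed=1)
        assert ext.n_haplotypes == base.n_haplotypes
        assert diag1.final_loglik == pytest.approx(diag0.final_loglik, abs=1e-6)

    def test_extend_then_drop_matches_marginalization(self):
        coh = self._training(n=60, seed=8)
        gt = coh.genotypes
        two, _ = ht.fit_em(
            gt, coh.hla, "A", "high", snp_ids=gt.snp_ids[:2], seed=0
        )
        ext, _ = ht.extend_model(two, gt.snps[2], gt, coh.hla, seed=1)
        dropped, _ = ht.drop_snp(ext, gt.snps[2].snp_id, gt, coh.hla, seed=2)
        marg = marginalize_snp(ext, gt.snps[2].snp_id)
        fa = dict((str(j), v) for j, v in dropped.freq_items())
        fb = dict((str(j), v) for j, v in marg.freq_items() if v > 1e-6)
        assert set(fa) == set(fb)
        for k in fa:
            assert fa[k] == pytest.approx(fb[k], abs=1e-4)


class TestPosterior:
    def test_single_compatible_configuration(self, two_hap_model, a01, a02):
        post, fb = ht.posterior_hla(two_hap_model, np.array([1]))
        assert not fb
        assert post[(a01, a02)] == pytest.approx(1.0)

    def test_worked_three_haplotype_example(self, three_hap_model, a01, a02):
        post, fb = ht.posterior_hla(three_hap_model, np.array([0]))
        assert not fb
        assert post[(a01, a02)] == pytest.approx(0.46875, abs=1e-12)
        assert post[(a01, a01)] == pytest.approx(0.390625, abs=1e-12)
        assert post[(a02, a02)] == pytest.approx(0.140625, abs=1e-12)

    def test_all_missing_gives_hwe_prior(self, three_hap_model):
        post, fb = ht.posterior_hla(three_hap_model, np.array([MISSING]))
        assert not fb  # compatible pairs exist; prior arises by marginalization
        prior = hla_genotype_prior(three_hap_model)
        for key, p in prior.items():
            assert post[key] == pytest.approx(p, abs=1e-12)

    def test_zero_likelihood_falls_back_to_prior_flagged(self, one_snp, a01):
        m = ht.HaplotypeModel.from_freqs("A", "high", one_snp, {(a01, "a"): 1.0})
        post, fb = ht.posterior_hla(m, np.array([2]))
        assert fb
        assert post[(a01, a01)] == pytest.approx(1.0)


class TestConditionalNll:
    def test_deterministic_model_correct_truth_is_zero(self, one_snp, a01, a02):
        m = ht.HaplotypeModel.from_freqs(
            "A", "high", one_snp, {(a01, "a"): 0.5, (a02, "b"): 0.5}
        )
        gt = _table({"rs1": [0, 2]})
        truth = make_typing(
            [("S0", "A", "A*0101", "A*0101"), ("S1", "A", "A*0201", "A*0201")]
        )
        assert ht.conditional_nll(m, gt, truth) == pytest.approx(0.0, abs=1e-9)

    def test_worked_example_value(self, three_hap_model):
        gt = _table({"rs1": [0]})
        truth = make_typing([("S0", "A", "A*0101", "A*0201")])
        nll = ht.conditional_nll(three_hap_model, gt, truth)
        assert nll == pytest.approx(-math.log(0.46875), abs=1e-9)

    def test_additivity_over_identical_samples(self, three_hap_model):
        gt1 = _table({"rs1": [0]})
        truth1 = make_typing([("S0", "A", "A*0101", "A*0201")])
        gt2 = _table({"rs1": [0, 0]})
        truth2 = make_typing(
            [("S0", "A", "A*0101", "A*0201"), ("S1", "A", "A*0101", "A*0201")]
        )
        one = ht.conditional_nll(three_hap_model, gt1, truth1)
        two = ht.conditional_nll(three_hap_model, gt2, truth2)
        assert two == pytest.approx(2 * one, abs=1e-12)

    def test_ambiguous_truth_sums_posterior_mass(self, three_hap_model):
        gt = _table({"rs1": [0]})
        truth = ht.HlaTypingTable()
        truth.add(
            "S0", "A",
            ht.AlleleSet.parse("A*0101/A*0201", "A"),
            ht.AlleleSet.parse("A*0101/A*0201", "A"),
        )
        # every genotype pair is consistent with the ambiguity set
        assert ht.conditional_nll(three_hap_model, gt, truth) == pytest.approx(
            0.0, abs=1e-9
        )
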