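import numpy as np
import pytest

import hlatag as ht
from hlatag.selection import SearchConfig, penalized_objective, select_snps

from conftest import make_typing


def _table(columns):
    snps = [
        ht.SnpRecord(name, "6", pos, "A", "G")
        for name, (pos, _) in columns.items()
    ]
    calls = np.array([vals for (_, vals) in columns.values()], dtype=np.int8).T
    return ht.GenotypeTable(snps, [f"S{i}" for i in range(calls.shape[0])], calls)


def _tag_noise_cohort(seed, n=500, n_tags=3, n_noise=3):
    """Cohort whose first SNPs deterministically tag the HLA allele and
    whose last SNPs are pure noise, all inside the search seed region."""
    noise = (0.0,) * n_tags + (0.5,) * n_noise
    spec = ht.PopulationSpec(
        "p",
        n_hla_alleles=4,
        n_snps=n_tags + n_noise,
        tags_per_allele=1,
        haplotype_noise=noise,
        recomb_rate=0.0,
        region_start=29_990_000,
        region_end=30_010_000,
        gene_start=29_989_000,
        gene_end=30_011_000,
    )
    coh = ht.sample_cohort(ht.CohortSpec(populations=((spec, n),), seed=seed))
    noise_ids = {f"snp{j:04d}" for j in range(n_tags, n_tags + n_noise)}
    cfg = SearchConfig(
        gene_start=spec.gene_start,
        gene_end=spec.gene_end,
        window_step=10_000,
        max_window=20_000,
        penalty_lambda=1.0,
        seed=seed,
    )
    return coh, noise_ids, cfg


class TestPenalizedObjective:
    def test_one_haplotype_has_zero_penalty(self, one_snp, a01):
        m = ht.HaplotypeModel.from_freqs("A", "high", one_snp, {(a01, "a"): 1.0})
        gt = ht.GenotypeTable(one_snp, ["S0"], np.array([[0]], dtype=np.int8))
        truth = make_typing([("S0", "A", "A*0101", "A*0101")])
        nll = ht.conditional_nll(m, gt, truth)
        assert penalized_objective(m, gt, truth, 5.0) == pytest.approx(nll)

    def test_penalty_linear_in_lambda(self, three_hap_model):
        gt = ht.GenotypeTable(
            three_hap_model.snps, ["S0"], np.array([[0]], dtype=np.int8)
        )
        truth = make_typing([("S0", "A", "A*0101", "A*0201")])
        nll = ht.conditional_nll(three_hap_model, gt, truth)
        o1 = penalized_objective(three_hap_model, gt, truth, 1.0)
        o2 = penalized_objective(three_hap_model, gt, truth, 2.0)
        assert o1 - nll == pytest.approx(2.0)  # K - 1 = 2
        assert o2 - nll == pytest.approx(4.0)

    def test_worked_value(self, three_hap_model):
        gt = ht.GenotypeTable(
            three_hap_model.snps, ["S0"], np.array([[0]], dtype=np.int8)
        )
        truth = make_typing([("S0", "A", "A*0101", "A*0201")])
        obj = penalized_objective(three_hap_model, gt, truth, 1.0)
        assert obj == pytest.approx(-np.log(0.46875) + 2.0, abs=1e-6)


class TestSelectSnps:
    def test_tagging_snp_beats_noise_snp(self):
        rng = np.random.default_rng(5)
        n = 120
        alleles = rng.choice([0, 1], size=(n, 2))  # two haplotypes per sample
        tag = alleles.sum(axis=1)  # perfectly tags the HLA genotype
        noise = rng.choice([0, 1, 2], size=n)
        gt = _table({"tag": (1000, list(tag)), "noise": (1100, list(noise))})
        names = {0: "A*0101", 1: "A*0201"}
        truth = make_typing(
            [
                (f"S{i}", "A", names[alleles[i, 0]], names[alleles[i, 1]])
                for i in range(n)
            ]
        )
        cfg = SearchConfig(gene_start=900, gene_end=1200, window_step=100,
                           max_window=100, penalty_lambda=1.0, seed=0)
        model, trace = select_snps(gt, truth, "A", "high", cfg)
        assert model.snp_ids == ["tag"]

    def test_duplicate_column_selected_once(self):
        rng = np.random.default_rng(6)
        n = 80
        alleles = rng.choice([0, 1], size=(n, 2))
        tag = list(alleles.sum(axis=1))
        gt = _table({"tagA": (1000, tag), "tagB": (1050, tag)})
        names = {0: "A*0101", 1: "A*0201"}
        truth = make_typing(
            [
                (f"S{i}", "A", names[alleles[i, 0]], names[alleles[i, 1]])
                for i in range(n)
            ]
        )
        cfg = SearchConfig(gene_start=900, gene_end=1100, window_step=100,
                           max_window=100, penalty_lambda=1.0, seed=0)
        model, _ = select_snps(gt, truth, "A", "high", cfg)
        assert model.n_snps == 1

    def test_lambda_extremes(self):
        # noisy-but-informative candidates: each addition splits
        # haplotypes, so the penalty has parameters to charge
        spec = ht.PopulationSpec(
            "p", n_hla_alleles=4, n_snps=2, tags_per_allele=1,
            haplotype_noise=0.05, recomb_rate=0.0,
            region_start=29_990_000, region_end=30_010_000,
            gene_start=29_989_000, gene_end=30_011_000,
        )
        coh = ht.sample_cohort(ht.CohortSpec(populations=((spec, 200),), seed=3))
        common = dict(
            gene_start=spec.gene_start, gene_end=spec.gene_end,
            window_step=10_000, max_window=20_000, seed=1,
        )
        # lambda = 0, cap 2: both informative SNPs enter
        m0, _ = select_snps(
            coh.genotypes, coh.hla, "A", "high",
            SearchConfig(penalty_lambda=0.0, max_snps=2, **common),
        )
        assert m0.n_snps == 2
        # huge lambda: nothing justifies its parameters
        m_inf, _ = select_snps(
            coh.genotypes, coh.hla, "A", "high",
            SearchConfig(penalty_lambda=1e6, **common),
        )
        assert m_inf.n_snps == 0

    def test_no_candidates_returns_hla_only_model_with_warning(self):
        truth = make_typing([("S0", "A", "A*0101", "A*0201")])
        gt = ht.GenotypeTable([], ["S0"], np.zeros((1, 0), np.int8))
        cfg = SearchConfig(gene_start=100, gene_end=200, seed=0)
        model, trace = select_snps(gt, truth, "A", "high", cfg)
        assert model.n_snps == 0
        assert any(e.action == "warn" for e in trace.entries)

    def test_objective_strictly_decreases_along_accepted_moves(self):
        coh, _, cfg = _tag_noise_cohort(seed=9, n=150)
        _, trace = select_snps(coh.genotypes, coh.hla, "A", "high", cfg)
        moves = trace.moves()
        assert moves, "expected at least one accepted move"
        for e in moves:
            assert e.obj_after < e.obj_before

    def test_backward_soundness_after_termination(self):
        coh, _, cfg = _tag_noise_cohort(seed=12, n=150)
        model, _ = select_snps(coh.genotypes, coh.hla, "A", "high", cfg)
        obj = penalized_objective(model, coh.genotypes, coh.hla, cfg.penalty_lambda)
        for sid in model.snp_ids:
            smaller, _ = ht.drop_snp(model, sid, coh.genotypes, coh.hla, seed=0)
            o = penalized_objective(smaller, coh.genotypes, coh.hla, cfg.penalty_lambda)
            assert o >= obj - 1e-6

    def test_deterministic_given_seed(self):
        coh, _, cfg = _tag_noise_cohort(seed=4, n=120)
        m1, t1 = select_snps(coh.genotypes, coh.hla, "A", "high", cfg)
        m2, t2 = select_snps(coh.genotypes, coh.hla, "A", "high", cfg)
        assert m1.snp_ids == m2.snp_ids
        assert [e.detail for e in t1.moves()] == [e.detail for e in t2.moves()]

    def test_noise_snps_rejected_single_replicate(self):
        coh, noise_ids, cfg = _tag_noise_cohort(seed=17)
        model, _ = select_snps(coh.genotypes, coh.hla, "A", "high", cfg)
        assert not (set(model.snp_ids) & noise_ids)
        assert len(model.snp_ids) >= 2
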