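import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hlatag as ht
from hlatag.calling import call_sample
from hlatag.evaluation import ConcordanceInput, kappa, platform_concordance
from hlatag.io import MISSING

from _oracles import kappa_bruteforce
from conftest import make_typing


def _result(sample_id, allele1, allele2, prob=1.0, ct=0.0):
    pair = tuple(
        sorted(
            (ht.parse_allele(allele1), ht.parse_allele(allele2)),
            key=lambda a: (a.locus, a.field1, a.field2 or ""),
        )
    )
    return call_sample(sample_id, {pair: prob}, ct=ct)


class TestAccuracy:
    def test_both_alleles_matched(self):
        truth = make_typing([("S1", "A", "A*0101", "A*0201")])
        rep = ht.accuracy([_result("S1", "A*0101", "A*0201")], truth, "A", "high")
        assert rep.per_allele_accuracy == 1.0
        assert rep.per_sample_accuracy == 1.0

    def test_homozygous_prediction_against_heterozygous_truth(self):
        truth = make_typing([("S1", "A", "A*0101", "A*0201")])
        rep = ht.accuracy([_result("S1", "A*0101", "A*0101")], truth, "A", "high")
        assert rep.per_allele_accuracy == 0.5
        assert rep.per_sample_accuracy == 0.0

    def test_optimal_pairing_handles_order(self):
        truth = make_typing([("S1", "A", "A*0201", "A*0101")])
        rep = ht.accuracy([_result("S1", "A*0101", "A*0201")], truth, "A", "high")
        assert rep.per_allele_accuracy == 1.0

    def test_ambiguity_credit(self):
        truth = ht.HlaTypingTable()
        truth.add(
            "S1", "A",
            ht.AlleleSet.parse("A*0201/A*0205", "A"),
            ht.AlleleSet.parse("A*0101", "A"),
        )
        rep = ht.accuracy([_result("S1", "A*0205", "A*0101")], truth, "A", "high")
        assert rep.per_allele_accuracy == 1.0

    def test_missing_truth_excluded_from_denominator(self):
        truth = make_typing([("S1", "A", "A*0101", "A*0201")])
        results = [
            _result("S1", "A*0101", "A*0201"),
            _result("S2", "A*0101", "A*0101"),  # no truth row
        ]
        rep = ht.accuracy(results, truth, "A", "high")
        assert rep.n_evaluated == 1
        assert rep.per_allele_accuracy == 1.0

    def test_intermediate_resolution_scoring(self):
        truth = make_typing([("S1", "A", "A*0101", "A*0201")])
        rep = ht.accuracy(
            [_result("S1", "A*0102", "A*0202")], truth, "A", "intermediate"
        )
        assert rep.per_allele_accuracy == 1.0  # matches at the 2-digit level

    def test_per_sample_never_exceeds_per_allele(self):
        rng = np.random.default_rng(0)
        names = ["A*0101", "A*0201", "A*0301"]
        rows, results = [], []
        for i in range(30):
            t = rng.choice(names, size=2)
            p = rng.choice(names, size=2)
            rows.append((f"S{i}", "A", t[0], t[1]))
            results.append(_result(f"S{i}", p[0], p[1]))
        rep = ht.accuracy(results, make_typing(rows), "A", "high")
        assert rep.per_sample_accuracy <= rep.per_allele_accuracy

    def test_frequency_threshold_restricts_denominator_only(self):
        truth = make_typing(
            [("S1", "A", "A*0101", "A*0201"), ("S2", "A", "A*0101", "A*0301")]
        )
        results = [
            _result("S1", "A*0101", "A*0201"),
            _result("S2", "A*0101", "A*0101"),  # misses the rare A*0301
        ]
        freqs = {
            ht.parse_allele("A*0101"): 0.6,
            ht.parse_allele("A*0201"): 0.35,
            ht.parse_allele("A*0301"): 0.01,
        }
        plain = ht.accuracy(results, truth, "A", "high")
        assert plain.per_allele_accuracy == pytest.approx(3 / 4)
        thresholded = ht.accuracy(
            results, truth, "A", "high", min_allele_freq=0.05, training_freqs=freqs
        )
        # the rare-allele slot leaves the denominator; matches are unchanged
        assert thresholded.n_allele_slots == 3
        assert thresholded.per_allele_accuracy == pytest.approx(1.0)

    def test_no_called_samples_is_flagged(self):
        truth = make_typing([("S1", "A", "A*0101", "A*0201")])
        r = _result("S1", "A*0101", "A*0201", prob=0.4, ct=0.5)
        rep = ht.accuracy([r], truth, "A", "high")
        assert rep.flagged
        assert rep.per_allele_accuracy is None


class TestKappa:
    def test_identical_vectors(self):
        assert kappa([0, 1, 2, 1], [0, 1, 2, 1]) == 1.0

    def test_total_disagreement(self):
        assert kappa([0, 1], [1, 0]) == pytest.approx(-1.0)

    def test_against_bruteforce_oracle(self):
        x = np.array([0, 0, 1, 1, 2, 2, 0, 1])
        y = np.array([0, 0, 1, 2, 2, 2, 0, 1])
        assert kappa(x, y) == pytest.approx(kappa_bruteforce(x, y), abs=1e-12)

    def test_against_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(11)
        x = rng.choice([0, 1, 2], size=200)
        y = np.where(rng.random(200) < 0.85, x, rng.choice([0, 1, 2], size=200))
        assert kappa(x, y) == pytest.approx(
            cohen_kappa_score(x, y, labels=[0, 1, 2]), abs=1e-12
        )

    def test_missing_pairs_dropped(self):
        x = [0, 1, MISSING, 2]
        y = [0, MISSING, 1, 2]
        assert kappa(x, y) == kappa([0, 2], [0, 2])

    def test_constant_conventions(self):
        assert kappa([1, 1, 1], [1, 1, 1]) == 1.0
        assert kappa([0, 0, 0], [2, 2, 2]) == 0.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_relabeling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.choice([0, 1, 2], size=50)
        y = rng.choice([0, 1, 2], size=50)
        assert kappa(x, y) == pytest.approx(kappa(y, x), abs=1e-12)
        relabel = {0: 2, 1: 0, 2: 1}
        xr = np.vectorize(relabel.get)(x)
        yr = np.vectorize(relabel.get)(y)
        assert kappa(x, y) == pytest.approx(kappa(xr, yr), abs=1e-12)


def _concordance_tables(seed=0, n=40, s=8, corrupt=0.0):
    rng = np.random.default_rng(seed)
    snps = [ht.SnpRecord(f"rs{j}", "6", 10 * (j + 1), "A", "G") for j in range(s)]
    ids = [f"S{i}" for i in range(n)]
    calls = rng.choice([0, 1, 2], size=(n, s)).astype(np.int8)
    other = calls.copy()
    if corrupt:
        mask = rng.random((n, s)) < corrupt
        other[mask] = rng.choice([0, 1, 2], size=int(mask.sum()))
    ta = ht.GenotypeTable(snps, ids, calls)
    tb = ht.GenotypeTable(snps, ids, other)
    tags_a = {f"rs{j}": "observed" if j % 2 == 0 else "imputed" for j in range(s)}
    tags_b = {f"rs{j}": "observed" if j < s // 2 else "imputed" for j in range(s)}
    return ConcordanceInput(ta, tb, tags_a, tags_b)


class TestPlatformConcordance:
    def test_identical_all_observed(self):
        ci = _concordance_tables(corrupt=0.0)
        ci = ConcordanceInput(
            ci.table_a, ci.table_b,
            {s: "observed" for s in ci.table_a.snp_ids},
            {s: "observed" for s in ci.table_a.snp_ids},
        )
        rep = platform_concordance(ci)
        assert rep.kappas["O-O"] == 1.0
        assert rep.kappas["O-I"] is None
        assert rep.kappas["I-O"] is None
        assert rep.kappas["I-I"] is None

    def test_pooled_kappas_match_bruteforce_oracle(self):
        for seed in range(5):
            ci = _concordance_tables(seed=seed, corrupt=0.05)
            rep = platform_concordance(ci)
            for cls in ("O-O", "O-I", "I-O", "I-I"):
                xa, xb = [], []
                for j, sid in enumerate(ci.table_a.snp_ids):
                    c = ("O" if ci.tags_a[sid] == "observed" else "I") + "-" + (
                        "O" if ci.tags_b[sid] == "observed" else "I"
                    )
                    if c == cls:
                        xa.extend(ci.table_a.calls[:, j])
                        xb.extend(ci.table_b.calls[:, j])
                if xa:
                    assert rep.kappas[cls] == pytest.approx(
                        kappa_bruteforce(np.array(xa), np.array(xb)), abs=1e-12
                    )

    def test_classes_partition_the_pool(self):
        ci = _concordance_tables(seed=3, corrupt=0.1)
        rep = platform_concordance(ci)
        assert (
            sum(rep.n_pairs[c] for c in ("O-O", "O-I", "I-O", "I-I"))
            == rep.n_pairs["overall"]
        )

    def test_mismatched_counted_allele_is_an_error(self):
        ci = _concordance_tables()
        flipped = [
            ht.SnpRecord(s.snp_id, s.chrom, s.position, s.allele_b, s.allele_a)
            for s in ci.table_b.snps
        ]
        tb = ht.GenotypeTable(flipped, ci.table_b.sample_ids, ci.table_b.calls)
        with pytest.raises(ht.ValidationError, match="counted allele"):
            ConcordanceInput(ci.table_a, tb, ci.tags_a, ci.tags_b)
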