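import numpy as np
import pytest

import hlatag as ht


@pytest.fixture
def a01():
    return ht.parse_allele("A*01:01")


@pytest.fixture
def a02():
    return ht.parse_allele("A*02:01")


@pytest.fixture
def one_snp():
    return [ht.SnpRecord("rs1", "6", 29_910_000, "A", "G")]


@pytest.fixture
def three_hap_model(one_snp, a01, a02):
    """The worked three-haplotype model: P{A01,A02 | genotype 0} = 0.46875."""
    return ht.HaplotypeModel.from_freqs(
        "A", "high", one_snp, {(a01, "a"): 0.5, (a02, "a"): 0.3, (a02, "b"): 0.2}
    )


@pytest.fixture
def two_hap_model(one_snp, a01, a02):
    return ht.HaplotypeModel.from_freqs(
        "A", "high", one_snp, {(a01, "a"): 0.6, (a02, "b"): 0.4}
    )


def make_typing(rows):
    """rows: (sample_id, locus, 'A*0101', 'A*0201' or sets 'x/y')."""
    t = ht.HlaTypingTable()
    for sid, locus, x, y in rows:
        t.add(sid, locus, ht.AlleleSet.parse(x, locus), ht.AlleleSet.parse(y, locus))
    return t


@pytest.fixture
def perfect_tagging_spec():
    """Zero-noise, one-core-per-allele population: SNPs determine HLA."""
    return ht.PopulationSpec(
        "ptag",
        n_hla_alleles=6,
        n_snps=12,
        tags_per_allele=1,
        haplotype_noise=0.0,
        recomb_rate=0.0,
    )
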