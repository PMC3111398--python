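"""Multi-ethnic versus single-population training sets.

Two populations carry disjoint HLA allele pools (an exaggerated
ethnicity contrast). A model trained only on the majority population
cannot predict minority alleles at all, while a model trained on a
150+150 mixture predicts both populations well — the rationale for
pooling multi-ethnic samples when no population-specific training set
exists.
"""

from hlatag import PopulationSpec
from hlatag.experiments import MultiEthnicConfig, run_design

config = MultiEthnicConfig(
    majority=PopulationSpec(
        "majority", n_hla_alleles=4, n_snps=8, tags_per_allele=1,
        haplotype_noise=0.01, recomb_rate=0.0,
        allele_names=("A*01:01", "A*01:02", "A*02:01", "A*02:02"),
        pool_seed=0,
    ),
    minority=PopulationSpec(
        "minority", n_hla_alleles=4, n_snps=8, tags_per_allele=1,
        haplotype_noise=0.01, recomb_rate=0.0,
        allele_names=("A*03:01", "A*03:02", "A*11:01", "A*11:02"),
        pool_seed=1,
    ),
    n_majority=300,
    n_minority=300,
    train_per_group=150,
    seed=4,
    resolutions=("high",),
)

table = run_design("multi-ethnic", config)
at_ct0 = table[table["ct"] == 0.0]
print(at_ct0[["cell", "per_allele_accuracy", "per_sample_accuracy"]].to_string(index=False))
print(
    "\nThe majority-only model collapses on minority validation (its "
    "posterior never contains minority alleles), while the mixture "
    "model stays accurate for both groups."
)
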