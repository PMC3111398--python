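# Methods

## Model and likelihood

For one HLA locus at one resolution (two-digit "intermediate" or
four-digit "high"), the model is a frequency table f over joint
haplotypes g = (h, s): an HLA allele h plus a string s over {a, b} of
alleles at the model's ordered SNP list. The counted allele of every
SNP (`allele_b`) is recorded explicitly so that genotype tables from
different sources can be orientation-harmonized before comparison.

Within the training population, haplotype pairs are assumed to pair at
random (Hardy–Weinberg). The observed-data likelihood of a sample with
unphased SNP genotypes G and typed HLA genotype H is the sum of
f_g · f_g' over all ordered pairs whose summed SNP alleles reproduce
every non-missing genotype and whose HLA pair matches H; ambiguous
typings (allele sets) allow any cross-combination of alternatives.
Missing SNP genotypes impose no constraint — they are marginalized,
not imputed, at both training and prediction time. HWE is stated as an
assumption deliberately: the admixture experiments construct cohorts
that violate it at the cohort level (Wahlund-type excess
homozygosity), which is exactly the regime the multi-ethnic design
probes.

## EM estimation

Frequencies are fitted by EM on the product of per-sample likelihoods.
Samples sharing a (genotype row, HLA constraint) configuration are
grouped, so the E-step cost scales with the number of distinct
configurations rather than n.

* **Initialization.** Frequencies proportional to
  compatible-configuration counts, mixed with 5% of a seeded symmetric
  Dirichlet draw. The jitter is what escapes the exactly symmetric
  saddle of all-double-heterozygote data; the count term avoids
  flat-start stagnation. Warm starts (from a parent model) receive a
  0.1% jitter only.
* **Convergence.** Stop when the per-sample log-likelihood gain falls
  below `tol` (default 1e-6) or after `max_iter` (default 500)
  iterations. The recorded log-likelihood sequence is non-decreasing
  (tests assert to 1e-10).
* **Haplotype space.** Small problems (alleles × 2^S ≤ 4096) enumerate
  every candidate haplotype. Larger ones grow incrementally: start
  from the HLA-only frequency model and add one SNP at a time, each
  retained haplotype splitting into its a/b children with frequencies
  split by the new SNP's allele frequency, followed by a warm-started
  EM refit. After every fit, haplotypes below `prune_eps` (default
  1e-5) are removed and frequencies renormalized. Incremental growth
  with pruning is what keeps many-SNP models tractable — full
  enumeration is impossible at the SNP counts real models reach.
* **Degenerate inputs.** If pruning would leave a sample with no
  compatible pair, its best pre-prune pair is re-admitted at the floor
  frequency; training never crashes on an explicable sample. At
  prediction time a zero-likelihood sample falls back to the HWE prior
  over HLA genotypes implied by the model's marginal allele
  frequencies, flagged as `fallback`, so every sample receives a
  posterior and CT = 0 always yields a 100% call rate.

## SNP selection

Forward-and-backward greedy search over an expanding window, scored by
conditional negative log-likelihood of HLA given SNPs plus λ·(K−1),
K the number of retained joint haplotypes. The search seeds among SNPs
inside the gene bounds, then alternates: add the in-window candidate
whose (iteration-capped, warm-started) refit most lowers the
objective; if no addition helps, try removals; if neither helps, widen
the window by `window_step` (default 50 kb) per side up to
`max_window` (default 500 kb, bracketing the spans real models
select). Candidate ranking uses a 20-iteration EM cap; an accepted
move is confirmed with a fully converged refit and logged only when it
strictly improves the objective, which makes the accepted-move
objective sequence strictly decreasing and guarantees termination.
Ties break by distance to the gene midpoint, then snp_id.

Design choices left open by the method's public description, decided
here: the penalty is λ·K with λ = 1 (AIC-like) by default and
log(n)/2 (BIC-like) selectable — validated by the noise-rejection
property (pure-noise decoys are never selected at λ = 1) rather than
by matching any reference implementation. The seed stage searches
among within-gene SNPs rather than force-including them;
`force_gene_snps=True` restores forced inclusion. Note that a
perfectly tagging SNP can add zero parameters (each haplotype keeps a
single surviving child), in which case even a very large λ accepts it:
the penalty charges parameters, not SNPs.

## Calling and evaluation

The maximum-posterior unordered allele pair is called when its
probability strictly exceeds CT; ties break lexicographically. CT = 0
calls everyone, including fallback samples. Headline accuracy is
per-allele: predicted alleles are paired with truth slots in the
pairing that maximizes matches (handling homozygote/heterozygote
asymmetry), a match meaning membership of the truth's alternative set
after reduction to its resolution. Per-sample (both-allele) accuracy
is always co-reported, since "comparing predicted with known
genotypes" admits either reading. Samples with missing truth leave the
denominator. With a frequency threshold, only truth slots whose
training-set allele frequency exceeds the threshold stay in the
denominator; match outcomes are never altered, only the evaluated
subset.

Cohen's kappa, κ = [Pr(a) − Pr(e)]/[1 − Pr(e)], is computed over
genotype categories {0,1,2} with pairs missing on either side dropped.
Platform concordance pools all SNP-sample pairs of a source class
(O-O, O-I, I-O, I-I by observed/imputed tags) into one 3×3 table and
reports one kappa per class — not an average of per-SNP kappas —
because a single coefficient per class per platform pair is the
comparable summary. Conventions: perfect agreement gives κ = 1 even
for constant vectors; two constant but different vectors give κ = 0;
empty classes are reported absent, not zero.

## QC

Genotyped SNPs are censored on MAF < 0.01, missingness > 0.05 and HWE
p < 1e-20. The HWE test is the asymptotic 1-df chi-square against
proportions from the observed allele frequency: at a 1e-20 threshold
only gross failures matter, where the asymptotic test suffices, so no
exact test is provided. All metrics are computed on the pre-filter
table and a SNP failing several filters reports every reason, making
reports independent of filter order; filtering is idempotent.
Imputed genotypes are hard-called when the maximum posterior strictly
exceeds 0.8 ("exceeds" read literally; an inclusive boundary is a
configuration flag), then censored on call rate < 0.95 and MAF < 0.01.

## Synthetic cohorts

The simulator models HLA–SNP linkage directly at the haplotype-pool
level rather than through coalescent machinery, because the quantity
the evaluation designs vary is tagging fidelity, and the pool gives it
a single seeded dial. Per population: each HLA allele carries
`tags_per_allele` core SNP haplotypes (drawn distinct on the
zero-noise positions, or supplied explicitly); per-SNP noise spreads
each core over neighbouring haplotypes (enumerated exactly up to 2^10
noisy positions, Monte Carlo with 256 draws/core beyond); allele
frequencies come from an explicit vector or a Dirichlet draw. The pool
is a property of the population (`pool_seed`), so two cohorts drawn
from the same spec share a pool — that is what makes the
cross-population transfer design meaningful.

Sampling draws two pool haplotypes per individual (HWE within
population), then applies recombination by walking outward from the
SNP nearest the gene and switching to a random partner haplotype with
the per-gap crossover probability — the HLA allele always rides the
primary haplotype, so linkage decays with distance from the gene.
Genotypes are summed counted alleles; missingness masks cells
uniformly at random; in posterior mode each genotype is also emitted
as a Dirichlet triple peaked at the truth with configurable
concentration (∞ = exact one-hot posteriors), standing in for an
imputation tool's output without modelling any particular imputer's
error structure.

Defaults, chosen once as a plausible single-locus regime: 6 HLA
alleles (Dirichlet 1.5 frequencies; allele names pair two four-digit
alleles per two-digit group so the intermediate resolution genuinely
coarsens), 12 SNPs evenly spaced over a 200 kb region around a 16 kb
gene, 2 cores per allele, 2% per-SNP core noise, 1% per-gap
recombination. What the generator does not emulate: real human MHC
haplotype maps and allele frequency spectra, platform-specific error
modes, relatedness, and imputation error correlated with LD — so
passing tests demonstrate correctness and the direction of design
effects, not field accuracy levels on real cohorts.

## Experiment designs and problem sizes

`run_design` re-enacts four evaluation designs on synthetic cohorts,
reporting per-allele and per-sample accuracy and call rate at
CT ∈ {0, 0.5, 0.9} in one tidy table: with/without imputed SNPs
(platform panel + hard-called posteriors for off-panel SNPs),
cross-platform training/validation (with pooled kappa classes via
`cross_platform_concordance`), cross-population transfer, and
multi-ethnic versus majority-only training. Comparative claims are
evaluated over 20 seeded replicates with a sign-count criterion, since
single-replicate differences of under a point are within simulation
noise.

Test-suite and acceptance problem sizes are the package's chosen
working points: EM-vs-grid checks use ≤2 SNPs, ≤3 alleles, n ≤ 20 with
a 0.01-step simplex grid over the truth support (the grid is
exhaustive only at that scale); perfect-tagging recovery uses n =
1,000 with a half/half split; frequency recovery uses n = 2,000 over
20 seeds (6 alleles, 2 cores/allele, 1% noise, no recombination, 10
SNPs — a well-identified regime where the RMSE criterion reflects
estimation rather than identifiability); selection soundness uses
3 deterministic tags plus 3 half-noise decoys at n = 500, λ = 1;
the multi-ethnic comparison uses two disjoint-pool populations, 150 +
150 mixture training versus 300 majority-only, validated on held-out
minority samples.

## Known limitations

* The EM is a local optimizer; the grid-oracle equivalence is
  demonstrated on small instances, not proven globally.
* Incremental haplotype growth explores children of retained parents
  only; a haplotype pruned early cannot reappear unless re-admitted by
  the compatibility floor.
* The greedy search can oscillate (add, later drop, re-add) while the
  objective still strictly decreases; it terminates but is not an
  exhaustive subset search.
* Strand-flip harmonization of A/T and C/G SNPs is out of scope:
  mismatched counted alleles between platforms are an error, never
  silently flipped.
* Binary PLINK, VCF and imputation-native formats are not read; the
  matrix-tsv and text ped/map dialects are the supported inputs.
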