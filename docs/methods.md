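# Methods

This note documents the models and conventions implemented in `bombuspop`,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not demonstrate about real surveys.

## Data model and validation filters

Alleles are integer fragment sizes in base pairs, exactly as scored against
a size standard; no binning is applied.  A missing genotype is an empty
multiset — never a size-0 allele — so a call's multiset size encodes its
interpretation: 1 = hemizygous/haploid, 2 = diploid, 3 = triple-peak
(triploid candidate).  GenePop files (2- and 3-digit codings,
auto-detected) round-trip bit-exactly; hemizygous calls are written in the
single-token haploid coding for that reason.

Specimens whose missing-locus fraction strictly exceeds 30% are discarded
(`>`: a specimen exactly on the threshold is kept).  Sibship reduction uses
a Queller–Goodnight moment estimator of pairwise relatedness (numerators
and denominators summed over loci before the ratio, the two directed
estimates averaged) and collapses each connected component of the
over-threshold graph (default threshold 0.25, between the full-sib
expectation and unrelated noise) to one member — the one with the fewest
missing loci, ties broken by a seeded draw.  This is a deliberate
simplification of full-likelihood sibship reconstruction and is not
equivalent to it: it cannot separate full from half sibs and its threshold
is a convention, not a posterior probability.

## Haplotyping and hybrid classification

In-silico PCR matches primers by Hamming distance only (no indels), IUPAC
degeneracy expanded, default budget 2 mismatches; both strands are
searched, the shortest candidate product wins, and distinct non-overlapping
products raise an ambiguity error.  Internally coordinates are 0-based
half-open.  Diagnostic content (SNP positions, restriction sites) ships as
an editable YAML scheme because published surveys define those sites in
external references; the packaged defaults are illustrative placeholders.
All diagnostic rules must agree or the call is `unknown`.

Hybrid classification is a pure function of morphotype, haplotype and a
location-context flag: morphological hybrids rank first, then
morphology/haplotype discrepancy; *terrestris* morphology outside that
subspecies' native range marks a naturalized foreign individual.  An
unknown haplotype on a non-hybrid morphotype is conservatively consistent.
A specimen that is both a morphological hybrid and discrepant counts once
in the per-location hybrid percentage.

## Diversity statistics

`He` is the uncorrected `1 − Σp²` (the convention of the spreadsheet tools
classically used for such tables); an unbiased small-sample variant exists
behind a flag but is off by default so bundled summaries stay comparable.
Multilocus values are unweighted means across loci.  Only female genotypes
enter `Ho`/`He`/`Fis` by default: haplodiploid males carry one gene copy
and would bias genotype-based statistics.

Rarefaction to `g` gene copies (default 10) makes unequal samples
comparable: `Ar_g = Σ_a [1 − C(N−N_a,g)/C(N,g)]`, and private allelic
richness multiplies each allele's presence probability in the focal
population by its absence probability in every other.  Loci with fewer
than `g` copies are dropped from that population's mean (with a warning)
rather than shrinking `g` globally, keeping the depth constant across
populations.  Both quantities are verified against exhaustive subset
enumeration in the tests.

`Fis` is Weir & Cockerham's *f*, variance components summed over alleles
and loci before the final ratio (the behaviour of the classic FSTAT
implementation; whether to sum or average is not universally fixed, so the
choice is recorded here).

Null-allele screening uses the two closed-form homozygote-excess
estimators — Chakraborty `(He−Ho)/(He+Ho)` and Brookfield-1
`(He−Ho)/(1+He)` — with a configurable flag threshold (default 0.05).  The
iterative van-Oosterhout estimator is not reproduced.

The Hardy–Weinberg test is the exact conditional test with the
probability-ordering criterion: all gene-copy pairings are enumerated when
the locus has at most 12 copies, otherwise the null is sampled by
Monte-Carlo shuffling of gene copies (default 10,000 replicates, `(hits+1)/
(reps+1)`).  Linkage disequilibrium uses the G statistic on the two-locus
genotype table with a permutation null (default 1,000 permutations)
preserving both single-locus distributions.

## Assignment

Three criteria, all invariant under allele relabeling and locus reordering:

* frequency log-likelihood with substitute frequency 0.01 for alleles
  absent from a pool (the convention of the standard assignment software);
* Nei's standard distance treating the individual as a population
  (frequencies 1 or 0.5), identities summed across loci before the ratio;
* the Bayesian criterion as the closed-form posterior-predictive
  likelihood of the two gene copies under a Dirichlet prior of weight 1/k
  per allele.  No Markov chain is needed for individual assignment; the
  closed form is exactly what the reference implementations evaluate, and
  it converges to the frequency likelihood as the pool grows (tested).

Leave-one-out is always applied when scoring a pool member against its own
pool.  Exclusion p-values come from simulating genotypes i.i.d. from pool
frequencies: `p = (1 + #{simulated ≤ observed}) / (n_sim + 1)`; the tests
verify the p-values are uniform for specimens truly from the pool.
Reference purification keeps candidates whose leave-one-out log10
likelihood ratio toward their own group is at least a margin (default 0).
The hybrid category uses a log10-ratio threshold (default 1.0); no
canonical threshold exists for this decision, so reports always carry the
raw scores for re-thresholding.

## Variants, Wilcoxon and regressions

`hOUT` removes morphological hybrids, discrepant hybrids and naturalized
foreign individuals; `rOUT` removes a seeded uniform random subset of the
same size.  The Wilcoxon signed-rank test reproduces the conventions of
the standard R implementation — zeros dropped before ranking, midranks on
ties, exact enumeration (dynamic programming over the rank-sum
distribution) when there are no ties and n ≤ 25, otherwise a normal
approximation with continuity correction and tie-corrected variance
`σ² = n(n+1)(2n+1)/24 − Σ(t³−t)/48`.  These conventions are validated by
recovering the bundled survey table's V = 52 / p = 0.014 (He) and V = 55 /
p = 0.006 (N) cells, and the exact path is checked against full 2ⁿ sign
enumeration.

ΔH<sub>E</sub> is defined as He(hIN) − He(hOUT): positive when hybrids add
diversity.  Regressions are ordinary least squares with the two-sided t
test on the slope (n − 2 df); hybrid percentage is on the 0–100 scale, so
slope units are "per percentage point".  Which locations enter a
regression is explicit input — published analyses of this design rarely
print the exact set, so no specific r² is asserted, only the sign and the
mechanism (tested on the simulator).

## Ploidy

Males heterozygous at ≥ 2 loci are diploid.  The triploid rule — ≥ 2 loci
with three distinct alleles — is a declared convention extending the
observed triple-peak phenomenon to a numeric cutoff.  Triploids are
excluded from the ϕ numerator and reported separately.  Males with < 2
typed loci stay in the denominator (ϕ divides by all sampled males) but
are flagged low-confidence.  Pooled ϕ is the ratio of sums, never the mean
of per-site ratios.  Reports round half-up to 2 decimals and always carry
the exact fraction, since published per-site figures mix rounding
conventions.

## Clustering

Genotypes are encoded as one dosage column per (locus, allele), missing
values imputed by column means, columns centred and scaled.  Cluster
number is scanned by k-means (10 seeded restarts) over principal
components with `BIC(K) = n·ln(W_K/n) + K·ln(n)`; other BIC definitions
exist, so specific best-K values on real data are treated as qualitative.
This BIC behaves sensibly only when enough principal components are
retained — in very low dimension any split of noise reduces within-cluster
variance enough to beat the `ln n` penalty — hence the scan defaults to
retaining many components.  DAPC is PCA followed by linear discriminant
analysis, with an overfitting guard (`n_pcs < n − #groups`) and α-score PC
selection: leave-one-out reassignment success minus its mean under label
permutation.

## The simulator

The generator emulates the sampling design of a two-subspecies hybrid-zone
survey.  Per locus a base frequency vector is drawn from a flat Dirichlet
and each subspecies pool from Dirichlet(base × concentration); the default
concentration 10 produces moderate, realistic microsatellite divergence,
and lowering it raises FST.  Default design: 9 loci × 8 alleles, 5
locations with introgression fractions q = 0, 0.1, 0.2, 0.3, 0.45
(spanning the 0–44% discrepant-hybrid range seen in field data), 10
colonies per location, 5 workers and 2 males sampled per colony, 10 csd
alleles, 2% missing calls, no null alleles and no morphotype
misclassification unless requested.

Queens mate once (the species is predominantly monandrous), so workers are
full sisters.  With probability q a colony descends from a commercial
matriline: an F1 queen (or, with probability 0.2 among those, a pure
foreign queen) mated to a local drone — its offspring are backcrosses with
native-looking morphology and the foreign mitochondrial haplotype, the
discrepant-hybrid mechanism.  Backcross depth is one generation by
default.  Mitochondria are strictly maternal.  Fertilized eggs homozygous
at the csd locus develop as diploid males (probability 1/k under random
mating with k csd alleles; recovered in tests within binomial error).
Null-allele dropout renders a heterozygote an apparent homozygote and a
double null missing, which is what produces the homozygote-excess signal
the screens look for.

What passing simulator tests show: the pipeline recovers planted structure
(introgression gradients, sib groups, ploidy, null loci) under the model's
assumptions.  What they do not show: robustness to allele-size homoplasy,
scoring error, polyandry, multi-generation introgression, population
substructure within locations, or non-random sampling — none of which the
generator emulates.

## Problem sizes and determinism

All randomness flows through seeded NumPy generators passed explicitly;
identical configurations reproduce byte-identical report bundles.  The
test suite runs its calibration checks at deliberately modest sizes (a few
hundred Monte-Carlo replicates, simulated surveys of ~350 specimens),
chosen as the smallest designs at which the binomial/KS tolerances are
meaningful.

## Known limitations

* The sibship filter is a moment-estimator substitute, not a likelihood
  pedigree model.
* Haplotype diagnostic rules are configuration; the shipped defaults are
  placeholders, not validated sites.
* The hybrid assignment category depends on a threshold convention;
  cross-survey comparability requires fixing that threshold.
* Exact best-K values from the BIC scan depend on the retained-PC count
  and the BIC definition and should be read qualitatively.
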