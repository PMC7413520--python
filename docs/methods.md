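# Methods and design notes

## The problem and the data the package carries

The package validates a forensic identification panel of diallelic SNPs for
two very closely related canid subspecies, grey wolf and domestic dog.  The
underlying study genotyped 97 Mongolian wolves and 108 Chinese dogs at 13
candidate ancestry-informative loci and published (a) per-locus one-time
genotyping success for both groups and (b) per-locus genotype-state and
allele frequencies for reference groups of 80 wolves and 90 dogs at the 12
loci surviving QC.  Individual genotypes were never deposited, so those two
tables are the package's only empirical inputs; they ship as plain-text
fixtures and everything downstream is computed from them.

Probability triples are always ordered (HOM_A, HET, HOM_B) relative to a
fixed per-locus reference allele: allele_a is the first allele of the
published genotype column (e.g. G for a G/T locus printed "GG GT TT").
Genotypes are stored as allele_a dosage {2, 1, 0} with −1 for missing.

One consistency caveat is inherited from the source: the published
per-locus between-population differential column was evidently computed
from unrounded frequencies, so recomputing it from the printed
three-decimal allele frequencies reproduces 11 of 12 values exactly and one
(rs23608542) one unit off in the third decimal.  Fixture-integrity tests
therefore assert agreement within 0.001 with at least 11 exact matches, and
internal genotype/allele consistency within ±0.002 (half-ulp of a
three-decimal table, times allowance for the het/2 term).

## Synthetic genotype generator

`simulate_population` draws each individual's call at each locus
independently from the population's genotype-state distribution
(`genotype_freq` mode, the default) or from Hardy–Weinberg proportions of
its allele frequency (`hwe` mode).  The default is the genotype-state
distribution because the source table shows clear HWE departures (e.g. the
wolf G allele at rs23882488 has frequency 0.013 yet HOM_G frequency 0.000),
and distances and assignment depend on genotype, not allele, distributions.
Loci are simulated independently, i.e. at linkage equilibrium, because no
pairwise-locus information was published.

What the generator does and does not emulate:

* It reproduces every per-locus marginal (χ² goodness-of-fit tests at
  n = 10⁴ in the suite) and hence all statistics that depend only on
  per-locus marginals — allele differentials, G<sub>ST</sub>, expected
  distance moments, classifier behaviour.
* It cannot reproduce inter-locus correlation.  The published wolf
  intra-population mean distance (1.197) is about 10% below what
  linkage-equilibrium simulation from the same marginals gives (≈1.35),
  which indicates structure/LD among the reference wolves (sampled across
  north/northeast China, Mongolia and the Russian Far East).  No LD model
  is attempted; the wolf intra mean is accordingly not treated as a
  reproduction target, while the moment identity E[d²] = 2·Σ_l(1−Σ_g p_g²)
  (≈2.53 for wolves) is.
* Missingness (`apply_missingness`) is independent per call with
  probability 1 − one-time success(locus, population); no genotyping-error
  or mutation model beyond that.  F1 hybrids receive one allele drawn from
  each parental population's allele frequencies per locus.

Reproducibility: each generator call consumes a single `numpy` Generator
stream seeded explicitly, in individuals-major, loci-minor order, so a
config's seed fully determines its output.

## Marker statistics

* Differentials are computed from the table's allele frequencies:
  within-population |p − (1−p)| = |2p−1|, between-population |p₁ − p₂|
  (identical for either allele by complement symmetry).  Published "±"
  values are treated as sample SDs (n−1), which matches the printed ranges.
* The differentiation statistic is Nei's G<sub>ST</sub> with equal
  population weights, from frequencies; the original analysis names only a
  software package, not an estimator.  Only the locus *ranking* feeds the
  cross-validation grids, and on this strongly diverged panel G<sub>ST</sub>
  and Weir–Cockerham θ rank the loci near-identically (asserted by a
  Spearman-correlation test against an in-test θ implementation).
* Locus-subset sizing uses round-half-up with a floor of one locus
  (10% of 12 loci must still select one training locus); ties in
  G<sub>ST</sub> break by locus id ascending.
* QC retains a locus iff one-time success ≥ threshold (default 0.90) in
  every population.  Mean success over a locus subset is the unweighted
  per-population mean, and "overall" the unweighted mean of those means,
  reported at three decimals.

## Distances and separation

The distance is Euclidean over per-locus genotype one-hot vectors,
d = √(2m) with m the number of mismatched-genotype loci.  The encoding was
fixed by a moment argument: for individuals drawn independently from
genotype tables, E[d²] = 2·Σ_l(1 − Σ_g p¹_g p²_g), and this closed form
reproduces all three published mean²+SD² values (wolf intra 2.53 vs 2.57,
dog intra 9.45 vs 9.48, inter 21.98 vs 22.03), whereas dosage or
allele-fraction encodings are off by factors of 1.6–1.8.  The encoding
remains selectable in `encode_matrix` for other uses.

Missing data: reference distances default to complete-case (the study
re-genotyped failed loci until complete); `missing='rescale'` computes each
pair over its jointly observed loci and rescales m by L/L_complete.

Separation statistics treat the pairwise distances themselves as
observations (the convention implied by the published degrees of freedom):
Welch's unequal-variance t of inter vs pooled-intra, and a "gap" =
inter 95% lower bound − intra 95% upper bound.  Bounds describe the
distance distribution, by default mean ± 1.96 SD (`normal`), with an
empirical-quantile (`percentile`) alternative.  Two published values are
documented as non-reproducible rather than chased: the gap 0.953 cannot be
derived from the published means/SDs under either bound method, and the
published inter maximum 4.959 exceeds √24 = 4.899, the hard ceiling of any
12-locus mismatch distance.

## Classifiers

Naive Bayes operates on the three genotype states per locus with Laplace
smoothing α (default 1): P(state|class) = (count + α)/(n + 3α).  Smoothing
reproduces the study's behaviour of multiplying per-locus likelihoods into
astronomically small wrong-class probabilities (~10⁻²⁸) without −∞; α = 0
is allowed when no class has zero counts.  Priors are equal (assignment is
between exactly two candidate subspecies).  A best-class posterior below
1 − 10⁻⁷ is annotated `possible_hybrid`, an advisory operationalization of
the observation that genuine wolf–dog hybrids should sit between the pure
classes.

LDA uses allele-fraction features (0/0.5/1 per locus) — one-hot features
would make the pooled covariance structurally singular — with class means,
pooled within-class covariance (denominator n − g), ridge ε = 10⁻⁶ on the
diagonal, and equal priors.  MISSING loci contribute nothing at prediction
time: naive Bayes simply skips them, LDA evaluates the marginal Gaussian
over the observed features.  Ties in the posterior break by population
label order; an individual missing at every model locus is flagged
`unassignable` with uniform membership.

## Cross-validation design

Both grids are stratified by population.  Monte-Carlo CV draws
round(p·n_pop) training individuals per population without replacement;
K-fold partitions each population into K shuffled folds with sizes
differing by at most one (80 wolves at K = 3 → 27/27/26).  F<sub>ST</sub>
ranking and locus-subset selection are recomputed inside every
resample/fold from training data only; the original description is silent
on this, but ranking on all data would leak test information into feature
selection, and a property test asserts that corrupting held-out genotypes
never changes the selected subset.  Model defaults follow the study's
stage-wise choices — LDA builds the Monte-Carlo predictive models, naive
Bayes produces K-fold membership probabilities and blind-test assignments —
and both are overridable.  The default grids give exactly 360 Monte-Carlo
and 48 K-fold assignment tests.

`run_full_validation` chains QC → marker stats → distances → Monte-Carlo →
K-fold → blind test from one YAML/JSON config, deriving per-stage child
seeds from a single master seed via `numpy.random.SeedSequence` and logging
them in the run manifest.

## Numerical conventions and problem sizes

* Fixture consistency tolerance 0.002 (three-decimal tables).
* Round-half-up for locus-subset sizes; three-decimal rounding only where
  the published tables print three decimals.
* The test suite and the acceptance script use the study's reference sizes
  (80 wolves, 90 dogs) throughout; distributional checks use n = 10⁴
  simulations, and replicate-averaged distance statistics use 50
  replicates, which puts Monte-Carlo error comfortably inside the asserted
  tolerances (SE of the replicate mean ≈ 0.003 for the inter mean).

## Known limitations

* No LD/structure model: statistics sensitive to inter-locus correlation
  (notably the wolf intra-distance mean and SD) are biased relative to the
  real reference panel; tests assert moment identities instead.
* Exact published blind-test membership values depend on the unpublished
  individual genotypes and are not reproduction targets; the blind-test
  stage asserts correctness counts and orders of magnitude instead.
* Two-population analyses only (no >2-way F<sub>ST</sub>, no
  admixture-proportion estimation); no VCF/PLINK I/O and no genomic
  coordinates — the panel is defined by locus ids and allele pairs alone.
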