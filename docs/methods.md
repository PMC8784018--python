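# Methods

## Model and rationale

A large polymorphic inversion suppresses recombination between the standard
and inverted orientations, so mutations accumulating inside the inverted
segment stay private to their orientation. Diploid samples then fall into
three genotype classes (standard/standard, standard/inverted,
inverted/inverted), and every SNP inside the segment is strongly correlated
with that class. `invscan` exploits this twice: PCA concentrates the
correlated block onto a leading component whose coordinates cluster by
inversion genotype, and per-SNP ANOVA against that component localizes the
block along the chromosome.

The memory problem is the feature matrix. The exact ("categorical")
encoding spends three indicator columns per site — *n × 3v* for *v* sites —
which for millions of SNPs exceeds workstation RAM. Feature hashing
replaces it with an *n × k* accumulator: allele keys
`chromosome_position_allele` are hashed to columns, and allele copy counts
(2 for a homozygote's allele, 1+1 for a heterozygote's two alleles, 0 for
unknown) are added into the hashed buckets, batch by batch, in one pass
over the file. Collisions add independent sites into shared columns; this
behaves like a sparse random projection, which preserves the between-cluster
geometry PCA needs as long as *k* is large enough. Row sums are conserved
(twice the called-genotype count per sample), which the tests use as a
mass-balance invariant, and an explicit projection oracle (exact allele-count
matrix followed by bucket summation) must agree entry-for-entry with the
streaming build.

The hash is MurmurHash3 x86_32 (via scikit-learn), interpreted as signed,
with `abs` taken in arbitrary-precision arithmetic so the INT32_MIN case is
defined, then reduced mod *k*. A seed parameter (default 0) makes bucket
structure reproducible across runs and platforms. Sign alternation — the
variance-correcting variant of the hashing trick — is deliberately omitted:
counts stay non-negative.

Both homozygous classes contribute two copies of their single allele's key;
this symmetric reading keeps row sums allele-copy-conserving. (The
alternative — counting only alternate-allele copies — would zero out
homozygous-reference genotypes; the symmetric rule mirrors the heterozygote
rule and is what the copy-count definition implies.)

## Choosing k (Johnson–Lindenstrauss heuristic)

For *n* points, a random projection to
k ≥ 4 ln(n) / (ε²/2 − ε³/3)
dimensions preserves pairwise squared distances within relative distortion
ε. If *l* SNPs are inversion-linked and *m* are background, samples of
different inversion genotypes differ in the *l* linked coordinates, so the
relative distance excess between unlike-genotype pairs is at least *l/m*;
any ε strictly below min(*l/m*, 1) keeps the clusters from collapsing.
`choose_epsilon` takes a 1% safety margin below that bound. Only the ratio
matters, so *l* and *m* may be SNP counts or genomic spans.

Numerical conventions: natural logarithm; the bound is truncated toward
zero (a strict "k ≥ bound" reading would round up; truncation matches the
reference dimensionality 4,532 for n = 198 at ε = 0.1, raw bound 4532.8,
and the one-dimension difference is immaterial in practice). The heuristic
overestimates on easy inversions — separability is typically already
perfect at k far below the bound — which is the safe direction.

## PCA and the separability check

PCA uses whitened scores (each retained component scaled to unit variance),
with the exact full-SVD solver up to 20,000 columns and the seeded
randomized solver beyond. Whitening would amplify numerically-zero variance
directions of a rank-deficient matrix into unit-variance noise, so
components with explained variance below 1e-12 of the leading component are
zeroed; an all-rows-identical matrix legally yields all-zero scores.

Separability is an evaluation device, not a genotype caller: a stratified
75/25 split, then a logistic-loss linear classifier on the first two PC
coordinates only, scored by held-out accuracy. The classifier is
stochastic-gradient logistic regression configured to actually converge on
2-D inputs: constant step 0.1 with iterate averaging (the conventional
decaying schedule stalls before reaching the separating solution),
L2 strength 1e-6 (two features need no shrinkage, and stronger shrinkage
biases the minority-class boundary), and balanced class weights, because
under Hardy–Weinberg the homozygous-inverted class has frequency q² and is
easily absorbed by an unweighted one-vs-rest scheme (at q = 0.3 and
n = 100 it holds only ~9 samples). With these settings the classifier
recovers linearly separable genotype clusters essentially always; under
permuted labels it scores at chance.

## Association scan

For each SNP the selected PC's coordinates are grouped by genotype class
(unknown genotypes excluded — the result is identical to removing the
sample) and tested by one-way ANOVA. The implementation accumulates group
counts, sums and sums of squares per batch with matrix products and
evaluates the F tail directly; it is algebraically the textbook F-test and
is cross-checked against `scipy.stats.f_oneway` per SNP in the tests.
Conventions for edge cases:

* fewer than two non-empty groups, or zero residual degrees of freedom →
  p = 1.0 (kept, not dropped, so the Bonferroni denominator equals the
  number of scanned SNPs);
* zero within-group variance with distinct means (perfect separation) →
  p = 0;
* p-values are clamped at 1e-300 before the −log10 transform.

One component per scan; the Manhattan table (chrom, pos, pvalue,
neglog10p, sorted by position) is the interface to localization.

## Boundary detection

SNPs are flagged at p < 0.01/num_snps (strict inequality at both Bonferroni
steps; "<" vs "≤" is a convention and is fixed here as strict). Windows of
10 kb (default) tile the chromosome from coordinate 0; the extent defaults
to the largest SNP position rounded up to a window multiple, or a known
chromosome length can be supplied. Each window's significant count is
tested with the exact binomial upper tail P[X ≥ x], X ~ Binomial(n_window,
p0), where p0 is the chromosome-wide flagged fraction; windows with no SNPs
or no flagged SNPs get p = 1.0 and still count toward num_windows (they
received a p-value, so they are members of the tested family). A window is
significant at p < 0.0001/num_windows, and the call is the interval between
the centers of the left-most and right-most significant windows — one
contiguous inversion per chromosome per scan.

A sparse-data caveat the tests quantify: with ~10 SNPs per window and
p0 = 0.2, a fully-flagged window of average occupancy has tail 0.2^10 =
1.024e-7, which narrowly misses a 1e-7 threshold; only windows with ≥ 11
SNPs can reach significance, so at this density the called edges sit a
window or two inside the true breakpoints on many replicates. At ≥ 50 SNPs
per window the caller pins the exact edge windows. Real chromosome arms
carry hundreds of SNPs per 10 kb window, comfortably in the dense regime.

## Interval scoring

Predicted and known intervals are compared by Sørensen–Dice coefficient
after rounding endpoints to the nearest 0.1 Mb; lengths are continuous
(not unit counts), and percentages are reported with one decimal, rounding
half up. Identical rounded intervals score 100.0; disjoint intervals 0.
A union helper merges breakpoint-region pairs reported by callers that
emit an inversion's two ends separately.

## Simulator

`simulate_inversion_vcf` emulates the defining features of a chromosome
carrying one polymorphic inversion, and nothing more:

* inversion genotypes drawn from Hardy–Weinberg at the inverted-orientation
  frequency (default 0.3, a moderately common inversion);
* *l* linked SNPs (default 2,000) at uniform distinct positions inside the
  inversion (default 2.0–4.0 Mb of a 10 Mb chromosome), copying each
  sample's inversion genotype, with per-site random ref/alt polarity so
  detection cannot exploit a fixed polarity, and optional per-site,
  per-sample "leakage" redraws emulating imperfect linkage (default 0);
* *m* background SNPs (default 8,000) at uniform distinct positions outside
  the interval, alt-allele frequency Uniform(0.05, 0.95), Hardy–Weinberg
  genotypes, resampled until each site is variable;
* optional missing genotypes ("./.") at a configurable rate (default 0).

Defaults give equal SNP density (~1/kb) inside and outside the inversion,
consistent with treating *l* and *m* as complementary spans in the JL
argument; no unlinked SNPs are placed inside the interval because
recombination suppression makes essentially every SNP inside a real
high-frequency inversion orientation-informative. Output is VCF 4.2 text
with a truth sidecar (interval, per-sample inversion genotypes, per-site
linkage flags), byte-reproducible from the seed.

What the simulator does **not** model — and therefore what passing tests do
not establish about real data: coalescent genealogy, LD decay outside the
inversion, population structure beyond the inversion itself, allele
frequency spectra, genotyping error correlated with depth, multiple or
overlapping inversions, and double crossovers / gene flux inside the
inversion. Tests on this generator validate the machinery (encoding, PCA
geometry, test calibration, change-point logic), not robustness to those
confounders.

## Problem sizes and determinism

Test-suite simulations use 10,000 SNPs × 50–100 samples per chromosome
(hashing at k ≤ 1,024, chosen via the JL helper where relevant), 20
replicates for recovery statistics, and 10,000 null SNPs for calibration
checks — sizes at which every stage's behavior is already asymptotic while
the whole suite stays fast. All randomness flows through explicit seeds
(simulator configs, PCA solver, classifier, train/test split); reruns are
bit-identical, manifest timestamps aside.

## Known limitations

* One inversion call per chromosome; overlapping inversion systems are out
  of scope.
* Window tiling is anchored at coordinate 0; the anchor is a convention and
  calls can shift by up to one window under a different anchor.
* At very low SNP density the binomial window test loses edge windows (see
  above); a smaller window or relaxed window-level alpha trades precision
  for sensitivity.
* The ANOVA is marginal per SNP: it does not model LD between SNPs, and a
  strong non-inversion structure on the tested PC would also produce
  associations — the windowed square-wave pattern, not any single p-value,
  is the inversion signature.
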