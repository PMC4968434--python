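# Methods

`balscan` implements a population-genetics workflow for detecting and
characterizing balanced polymorphism at candidate gene regions: a locus
where two deeply diverged haplotype clades segregate at intermediate
frequency in one population, producing an excess of intermediate-
frequency alleles (positive Tajima's D, Fu & Li's F), strong per-SNP
differentiation of the clade-diagnostic variants between populations,
a tight block of mutually high-LD SNPs, and a two-clade haplotype
network with a deep coalescence time.  Every statistic is exercisable
end-to-end on synthetic cohorts with known ground truth.

## Data model

Phased haplotypes live in a binary sites-by-chromosomes matrix; diploid
genotypes are its per-individual dosage collapse (0/1/2, with −1 for
missing, which the phased matrix does not admit).  Coordinates are
0-based half-open internally and converted exactly at the VCF boundary
(VCF is 1-based; BED is already 0-based half-open).  Variants are
polarized to ancestral/derived coding from a per-site ancestral-allele
TSV or an outgroup FASTA (TSV wins when both are supplied); sites whose
ancestral state is unknown or matches neither allele are dropped and
counted, and polarization fails loudly when fewer than 90 % (default)
of sites carry a usable ancestral call.  Multiallelic records and
indels are skipped on input: every downstream statistic is SNP-based.

## Neutrality battery

Per locus and group we report S, per-site π (monomorphic positions
enter through the sequenced locus length, reproducing the ×10⁻⁴ scale
of per-site diversity tables), Watterson's θ, Tajima's D, and Fu & Li's
D and F.  With polarized data the Fu & Li statistics use derived
singletons (external-branch mutations); unpolarized input falls back to
the starred variants based on minor-allele singletons.  The variance
constants are the corrected forms (the original report's typos are a
known hazard); they are validated in the test suite by a neutral
simulation calibration (null variance of D′ and F within ~15 % of 1).
Undefined statistics (S = 0, degenerate variance) propagate as explicit
`None`, never as 0.

Significance comes from one-tailed empirical p-values against neutral
coalescent replicates conditioned on the observed number of segregating
sites: a Kingman coalescent (waiting times Exponential(k(k−1)/2) in 2N
units) with exactly S infinite-sites mutations placed on branches with
probability proportional to branch length, no recombination.  The
estimator is (1 + k)/(R + 1), so p is never zero; the tail is the upper
tail for π excess and for positive observed D/F values, the lower tail
for negative ones, and is recorded per statistic.  One shared replicate
set per (n, S) serves the whole battery.

A property of this null worth knowing: conditioning on S and placing
mutations proportionally skews the simulated frequency spectrum
slightly toward singletons (short trees have relatively long external
branches), so the null mean of Tajima's D is ≈ −0.10 at n = 20, S = 20
rather than 0.  We verified the same mean with an independent tree
implementation (msprime) and under exact conditional sampling by
rejection; it is a real property of the fixed-S convention, not an
implementation artifact.  Test calibration of the *p-values* is
unaffected, because observed statistics are compared against the same
null that generated them.

Multiplicity across loci, groups and statistics is handled by the
adaptive Benjamini–Hochberg procedure: the number of true nulls m₀ is
estimated by the lowest-slope recipe on the ordered p-values, then the
BH step-up runs with m replaced by m₀; adjusted values are clipped to
[raw, 1] and monotone in rank.  FDR control at α = 0.01 on all-null
p-vectors is checked empirically in the acceptance suite.

## Differentiation scan

Per-SNP pairwise F_st between population clusters with three selectable
estimators: `wright` (the default; Nei's G_ST form (H_T − H_S)/H_T with
sample-size-weighted frequencies), `hudson` (sample-size corrected) and
`wc` (Weir & Cockerham θ for two haploid allele samples).  The
estimators are *not* interchangeable in expectation: under the
Balding–Nichols model with per-population parameter F, Hudson and WC
are approximately unbiased for F while the two-population G_ST
expectation is (F/2)/(1 − F/2); each is tested against its own
closed-form expectation, and the pipeline uses one consistent estimator
for gene SNPs and background so outlier calling is scale-free.  Sites
monomorphic in the pooled pair are undefined (NaN) and excluded.
Outliers are flagged at the nearest-rank (ceiling, no interpolation)
percentile of an empirical genome background, 99th by default, and the
percentile rank of every gene SNP is reported.

## LD analysis

Genotypic r² is the squared Pearson correlation of dosage vectors over
pairwise-complete individuals; haplotypic r² is D²/(p(1−p)q(1−q)) from
phased haplotype counts (algebraically the squared correlation of the
binary site indicators).  Pruning follows the 50-SNP window / 10-SNP
step / r² > 0.1 sliding-window recipe over the currently kept SNPs;
of a violating pair the lower-MAF SNP is removed, ties broken toward
the larger coordinate (the historical tool's rule is under-documented,
so the rule here is explicit); undefined r² counts as 0 for pruning.
The high-LD set around anchor SNPs collects every SNP with r² above
the threshold (0.95 default) with at least one anchor and reports the
member-by-member r² matrix, the genomic span of the member set (the
operationalization of an "LD block" here — no Gabriel-style block
algorithm is implemented), and the count of excluded SNPs.

## DAPC

Discriminant analysis of principal components as a scikit-learn
estimator: center (optionally variance-scale; default off, the usual
convention for allele dosages) → PCA by SVD → retain k PCs → linear
discriminant analysis on the scores, solved as the generalized
eigenproblem S_B v = λ S_W v with all g − 1 discriminant functions
retained and axes normalized so the pooled within-group covariance is
the identity in discriminant space.  Posteriors are therefore spherical
Gaussian likelihoods around the group centroids with equal priors (no
priors are published for this use; a cross-check against sklearn's LDA
posteriors on the same scores is part of the suite).  k = "auto"
maximizes the mean α-score — observed correct-reassignment proportion
minus its mean over label permutations (30 by default, seeded) — which
penalizes retaining so many PCs that the model memorizes groups.
Held-out cohorts are projected as supplementary individuals using the
reference centering, loadings and coefficients only; projecting the
training data reproduces fit-time scores to 1e−8.  Missing dosages are
mean-imputed per site.

## Haplotype inference (EM)

For the tight-LD block (≤ 32 SNPs, around ten distinct haplotypes) an
EM algorithm under Hardy–Weinberg estimates haplotype frequencies from
unphased genotypes: the E-step distributes each ambiguous genotype over
its compatible haplotype pairs proportionally to current pair
probabilities, the M-step re-estimates frequencies; the log-likelihood
is non-decreasing and convergence is a frequency fixed point (|Δ| <
1e−8).  Ten random restarts guard against local optima, and restarts
reaching the best likelihood with different frequency vectors are
reported as ties (e.g. the classic lone double-heterozygote).  Full
pair enumeration is used up to 12 heterozygous sites; beyond that the
2^(h−1) enumeration is replaced by partial enumeration over the
candidate haplotype pool established by less ambiguous individuals
(each candidate determines its partner uniquely), the standard trick
for blocks in strong LD.  This EM deliberately replaces coalescent-
prior MCMC phasing: it is deterministic given a seed and fully
testable; equivalence with any particular phasing program is not
claimed, only frequency-recovery accuracy against synthetic truth
(total-variation distance < 0.05 at 200 individuals × 10 SNPs).
Maximum-posterior phase pairs are assigned per individual, ties broken
lexicographically and flagged; individuals incompatible with every
positive-frequency pair get a uniform-augmentation assignment and are
flagged.

## Median-joining network and TMRCA

Distinct haplotypes (with per-group chromosome counts) are connected by
the ε-relaxed minimum-spanning network: a pair is linked when its
Hamming distance is within ε (default 0) of its connection level (the
minimax path distance; ε = 0 keeps exactly the union of all minimum
spanning trees).  Majority-consensus median vectors of connectable
triples are added greedily while they reduce the minimum-spanning cost,
and obsolete unsampled nodes of degree ≤ 2 are deleted when removal
does not raise the cost; with homoplasy-free data the result is the
unique most-parsimonious tree (checked exhaustively at small sizes).
Edges carry the list of mutated site ids; uniform site weights.

Rooting picks the node nearest the outgroup haplotype (ties: highest
sampled count, then lexicographic).  The rho statistic is the
count-weighted mean shortest mutational path from the root to each
sampled chromosome; its standard error is computed as
√(Σ counts·d²)/n — the stated frequency-weighted form rather than the
tree-decomposition estimator, because a median-joining network need not
be a tree.  Calibration is generation-free: the per-locus per-lineage
rate per year is fixed_differences/(2 × divergence_time), 120 and 6 My
by default, i.e. 1e−5 per locus per year.  Note that a dated TMRCA of
this kind depends strongly on where the root lands: in the default
synthetic scenario all inter-clade differences are derived in clade A,
so the all-ancestral outgroup roots inside clade B and rho averages
clade-A frequency × split depth plus within-clade depth.  Whole-network
and per-clade dating are both possible from the same object.

## Synthetic cohorts (what they emulate, and what they do not)

The generator produces four ingredients with known truth:

* **Neutral nulls** — fixed-S or θ-mode Kingman coalescent, no
  recombination (the conservative convention for conditioned nulls;
  recombination is refused explicitly rather than approximated).
* **Structured cohorts** — n-island coalescent with per-lineage
  migration rate M/2 (time in 2N units), plus unlinked Balding–Nichols
  genotypes for ancestry-assignment experiments.
* **The balanced locus** — two clades built by construction: each
  clade's internal variation is an independent coalescent; a fixed
  number of inter-clade differences is planted at distinct sites with
  the derived state on clade A; chromosomes are drawn per group at
  configured clade frequencies, with truth labels returned.  This is a
  deliberate stand-in for a balancing-selection coalescent (no NFDS or
  overdominance dynamics): it reproduces the downstream statistical
  signatures — SFS skew, diagnostic-SNP differentiation, two-clade
  network — without modeling the selective process itself.
* **The genome background** — per-SNP Balding–Nichols F_st values:
  ancestral frequency Uniform(0.05, 0.95), cluster frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F), binomial allele counts.

Default scenario conditions mirror a 1000-Genomes-style reference
panel: 492/758/572 chromosomes in the African/European/East-Asian
clusters, clade-A frequencies 0.21/0.50/0.06, an 18-person disease
cohort resampled from the European cluster with clade-A frequency
boosted 0.50 → 0.53 under Hardy–Weinberg pairing, a 4-kb locus with 30
clade-diagnostic sites and 8 within-clade segregating sites per clade.
The background F per cluster pair defaults to 0.05, chosen so the
synthetic genome null reproduces the documented operating point of
continental human comparisons: a derived-allele-frequency contrast of
~0.45 between clusters ranks beyond the genome-wide 99th percentile,
while a ~0.3 contrast does not.  Real data differ from all of this in
ways the tests cannot probe: recombination within the locus, mutation-
rate heterogeneity, ascertainment of the genome background, genotype
error, and admixture; passing the suite shows the *methods* are
correct and calibrated, not that any particular biological claim is.

All generators are pure functions of (config, seed); the pipeline
derives every stage seed from one global seed by fixed offsets, and a
rerun of the same configuration is byte-identical.

## Problem sizes

The shipped studies use 5000 replicates for null calibration (n = 20,
S = 20), 10,000 replicates for positive-control p-values (n = 100 per
group), 20,000 background SNPs, 300 BN SNPs × 390 individuals for
ancestry assignment, and 200 individuals × 10 SNPs for phasing
recovery — sizes at which every Monte-Carlo band in the tests is stable
across seeds while the whole suite runs in minutes on one core.

## Known limitations

* No recombination in any simulator (fixed-S nulls are conservative
  for the positive statistics tested here; LD decay is not emulated).
* The fixed-S null's mean-D bias (above) is inherent to the
  convention, not removable by implementation.
* The EM phaser is not a general-purpose phasing tool: no phasing
  across recombination breakpoints, no imputation, ≤ 32 sites.
* The median-joining search is exact only in the sense of its greedy
  cost criterion; like the original algorithm it does not guarantee a
  minimal Steiner network for arbitrary homoplasy.
* rho-based dating ignores rate variation across sites and lineages;
  its confidence interval reflects sampling error only, not
  calibration uncertainty.
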