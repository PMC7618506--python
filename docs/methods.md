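# Methods

This note documents the statistical procedures, the synthetic-data
generator that stands in for a real two-site tablet study, the numerical
choices made where the design was genuinely open, and the limits of what
the test suite demonstrates.

## Study design encoded by the package

Two production sites, labelled country **A** and country **B**, process
identical excipient lots into placebo tablets under three scenarios of
increasing environmental contamination: direct compression with laboratory
windows closed (groups E-1/T-1), direct compression with windows open
(E-2/T-2), and wet granulation with local tap water, windows open
(E-3/T-3). Two control formulations exist at site A only: the
wet-granulation formulation without water (E-4) and the cross-over group
E-5, made at site A with site-B water. E-5 is excluded from differential
abundance and model training and used purely for held-out prediction: its
assignment probes whether the water or the ambient manufacturing
environment dominates a tablet's biological signature.

## Count-table analysis

**Exclusion rules.** An ASV is removed if any single negative control
carries strictly more than 10 of its reads (per-control, not summed — the
conservative forensic reading), if it is present with at least one read in
any pure-excipient sample, or if its BLAST hits match a named
excipient-derived taxon (default *Zea* at ≥ 90 % identity). The rules are
idempotent and order-stable; a `FilterReport` records every removal.

**Rarefaction.** Each sample is subsampled without replacement to a fixed
depth (default 5 000 reads) `n_iter` = 100 times; the per-ASV mean is
rounded half-up. Iteration reduces the variance of any single subsample
while preserving the expectation (a hypergeometric mean), at the cost of
slightly non-integral sampling properties; column sums are conserved up to
half a count per ASV. Samples below depth are dropped with a warning.

**Diversity and group tests.** Richness counts ASVs with nonzero rarefied
counts; Shannon entropy uses natural logarithms (ecology convention; a
base-2 variant is a one-line change at the call site). Group differences
in alpha diversity use Kruskal–Wallis with tie correction and Dunn's
pooled-rank z post-hoc tests, Holm-adjusted. Beta diversity uses
Bray–Curtis dissimilarities, classical-scaling PCoA (negative eigenvalues
reported, axes restricted to positive ones), and PERMANOVA with
sequential (Type-I) sums of squares of the Gower-centered matrix in the
user-given term order — the convention of `vegan::adonis` — with p-values
from whole-row permutations that include the observed statistic in
numerator and denominator. Dispersion homogeneity follows
`vegan::betadisper`: distances to group spatial medians in the full PCoA
embedding, with imaginary-axis contributions subtracted in the squared
distance, tested by a permutation F on the distances. Both procedures are
validated against vegan's own output on fixed fixtures in the test suite.

## Differential abundance

Counts are normalized with **poscounts** size factors: the per-ASV
reference is the n-th root of the product of its positive counts (zeros
contribute a factor of one), a sample's factor is the median ratio of its
positive counts to positive references, and factors are rescaled to unit
geometric mean. This is the estimator of choice for zero-inflated
amplicon tables and agrees with pydeseq2's implementation to < 0.5 % on
shared fixtures.

The country contrast is the log₂ ratio of method-adjusted country means of
normalized counts: cell means are computed per (country, manufacturing)
cell and averaged within country, so a method imbalance between countries
cannot masquerade as a country effect (the ~ country + country:method
design). When either country mean is zero, a pseudo-mean of 0.5 normalized
counts is added to both numerator and denominator, keeping the fold change
finite and antisymmetric.

The Wald standard error follows from the negative-binomial variance
μ + αμ² by the delta method. The dispersion α is estimated per ASV by
method of moments from within-cell variability — and then **stabilized
against a fitted mean-dispersion trend** α(μ) = a₀ + a₁/μ (iteratively
trimmed least squares across ASVs), with the working dispersion taken as
the larger of the per-ASV estimate and the trend value. Raw per-ASV
moment estimates carry so few degrees of freedom at this design size
(12 + 9 tablets) that they underestimate α for a large fraction of ASVs
and visibly inflate the Wald statistics; the trend floor is a
deliberately conservative stand-in for the shrinkage a full DESeq2 fit
would perform, which is out of scope here. For the same reason the
two-sided reference distribution is Student's t at the residual degrees
of freedom of the cell-means model rather than a normal. With both
choices the null z-scores are calibrated (sd ≈ 0.96 in the calibration
layout) and the procedure attains, at q = 0.05 over 20 simulated studies
with |lfc| = 3 planted in 50 of 500 ASVs, a mean sensitivity of ~0.97 at
a mean empirical FDR of ~0.01. Adjustment is Benjamini–Hochberg; ASVs
with adjusted p < q are flagged overabundant in the country with the
larger mean.

## Classification

**DAPC.** Features (rarefied counts of the flagged ASVs) are centered
(unscaled by default; scaling is a flag) and projected onto the smallest
number of principal components whose cumulative variance reaches the
target (default 0.90), capped at n − #classes so the within-class scatter
of the subsequent LDA stays nonsingular. Linear discriminant analysis
with equal class priors supplies the discriminant axes and Gaussian
posteriors. Equal priors reflect the near-balanced design (12 vs 9) and
avoid prejudging a questioned sample's origin.

**KDA.** Kernel Fisher discriminant analysis with a radial-basis kernel;
the bandwidth defaults to the median pairwise training distance, and the
within-class kernel scatter is regularized (1e-6, scaled by the kernel
trace) before solving the generalized eigenproblem. Posteriors come from
a Gaussian model on distances to class means along the discriminant axes
with pooled within-class variance. The kernel and bandwidth are
implementation choices — the vendor software behind such analyses does
not publish its algorithm — and both are exposed as parameters.

**Validation.** Leave-one-out cross-validation refits the entire fitter
inside every fold, including any feature selection the fitter performs, so
the held-out sample can never influence its own prediction; a leakage
test asserts this directly. Note the difference from selecting
discriminant features once on the full two-class data and then
cross-validating only the classifier: that variant (the common practice
in vendor workflows) is optimistic, and callers who want it must select
features before constructing the fitter.

## Chemometrics

Blank-strip background peaks are clustered to consensus masses and their
mean intensity subtracted from matching sample peaks (nearest match
within the tolerance); surviving peaks are normalized per measurement to
base peak = 100 %, aggregated along the mass axis by single linkage with
gap < 1 m/z (intensity-weighted mean mass, summed intensity — total
intensity is conserved), and aligned across measurements by greedy
centroid clustering at 15 mmu after sorting by mass, which is
deterministic and order-independent. ANOVA pre-selection keeps abundant
features (max group mean > 10 %) whose extreme-mean tablet groups differ
at p < 0.05; two-class Fisher-ratio selection ranks features by
(μ_A − μ_B)²/(σ²_A + σ²_B) with a 1e-12 variance floor and keeps the top
95 with fold change > 1, where fold change is the max/min ratio of class
means offset by one intensity unit (so empty classes are well defined —
"any difference" qualifies, as intended by a fold-change-greater-than-one
rule on percent-scale intensities).

## Reference-free geolocation

Overabundant ASV selection is the conjunction of three conditions per
country: flagged overabundant there, nonzero in at least two of that
country's tablets, and zero in every tablet of the other country
("exclusive occurrence" — the strictest reading). Taxon resolution keeps
only BLAST hits at the largest percent identity (LPI) among species-rank
hits: one distinct species → single species; several → a set of equally
possible species; none — only when *no* ASV of the country's set resolves
to species rank — triggers a genus-rank fallback for the whole set.
Unified point maps pool all occurrence records of all the group's species
onto a fixed global lattice anchored at (−180°, −90°) — pointy-top
hexagons of 5° width by default, squares available for oracle testing —
and count observations per bin without deduplicating repeated
coordinates. Unified region maps sum per-species 0/1 region presences, so
a region's value is the number of co-occurring group species. Bin counts
always sum to the number of mapped records.

## Synthetic-data generator

`simulate_counts` draws each sample from a Dirichlet-multinomial whose
mean composition mixes a shared excipient pool with site-specific dust
and water pools: windows-closed tablets get 2 % dust, windows-open 8 %,
wet granulation 24 % dust + 8 % water (dust dominating), the no-water
formulation 15 % dust, and the cross-over group site-A dust with site-B
water at the same 3:1 ratio — strong enough that the environment-dominates
finding is recoverable but not trivially so. Pool profiles are lognormal;
negative controls carry a sparse contamination pool (which also seeps into
tablets at 0.3 %) with some counts above the 10-read exclusion threshold.
Per-sample depths are uniform over 5 264–329 354 reads, the observed
bacterial-marker range of this kind of experiment. The total Dirichlet
concentration defaults to 5 000, i.e. a replicate-to-replicate CV of
roughly 30 % for a mid-abundance ASV — plausible for replicate tablets of
a controlled formulation; the earlier, much looser choice implied ~160 %
replicate CV, which no controlled manufacturing process shows. A
calibration layout (`da_calibration_config`) replaces the pool structure
with one shared pool carrying planted log₂-fold changes (split evenly
between countries so compositional renormalization stays symmetric and
unplanted ASVs are true nulls).

`simulate_spectra` plants site-specific peaks with a +50 intensity shift
over a base of 10 (additive noise sd 5), shared and background peaks with
random masses at ≥ 2.5 Da mutual spacing (so 1-m/z aggregation never
merges distinct true features), per-measurement mass jitter of 4 mmu
(within the 15-mmu alignment tolerance), three technical replicates per
tablet and blank strips containing only background. The cross-over group
carries the full site-A signature plus a 25 % echo of site B.

`simulate_biogeography` places site-pool species ranges around the two
production laboratories' coordinates (radius 10°, records from a
truncated Gaussian), cosmopolitan species worldwide, derives a synthetic
30°-cell region grid by circle–rectangle intersection, and emits BLAST
hits with configurable tied-top-hit (LPI ambiguity) rates plus genus-rank
rows.

**What the generator does not emulate:** real taxonomic structure and
database error, chimeras and PCR/primer bias, spatial sampling bias in
occurrence databases, land masks, batch effects between sequencing runs,
and matrix effects in DART-MS ionization. Passing tests therefore
demonstrate the correctness and calibration of the *procedures* under the
declared noise model, not field performance on real seizures.

## Numerical choices and degenerate inputs

Thresholds written as QIIME parameters (coverage, identity) are
inclusive; the control-read rule is strict (> 10). Bray–Curtis between
two all-zero samples is an error, as is alpha diversity of an all-zero
sample. PCoA eigenvalues within 1e-10 (relative) of zero are treated as
zero. Permutation p-values are never zero by construction. Posterior
ties are broken to the lexicographically first class and flagged. Missing
query features at prediction time are imputed as zero with a warning; a
query sharing no features with the model is an error. Problem sizes in
the test suite (500-simulation PERMANOVA calibration at n = 20 with 199
permutations; 20-seed error-rate studies; 50-replicate geolocation
recovery) were chosen as the smallest sizes at which the binomial noise
of the measured rates is well inside the asserted bands.

## Known limitations

* The Wald test's trend-stabilized moment dispersion is conservative by
  construction; with very few ASVs (< 10 testable) the trend degenerates
  to a median floor.
* The hexagonal lattice is planar in lon/lat: bins shrink physically
  toward the poles and the lattice does not wrap at ±180°. For the
  mid-latitude use cases modelled here this is immaterial; global-scale
  quantitative comparisons should use equal-area bins.
* PERMANOVA assumes exchangeability under the null; with strongly
  heterogeneous dispersions its rejections conflate location and spread —
  which is exactly why `betadisper` is part of the workflow.
* LPI resolution trusts the hit table's rank annotations; it does not
  parse taxonomy strings.
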