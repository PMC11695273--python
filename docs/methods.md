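# Methods

`introscan` analyses biallelic SNP genotypes from a two-species hybrid
system: two parental populations and a swarm of admixed individuals
produced by hybridisation and repeated backcrossing, sampled in two
years. This note documents the models and estimators, the tunable
parameters, the synthetic-data generator, and the numerical and design
choices that were genuinely open.

## Data model

Genotypes are alt-allele dosages in {0, 1, 2} with missing calls stored
as NaN (`GenotypeMatrix`); per-SNP metadata (`LocusTable`) carries a RAD
locus id, chromosome, 1-based position and ref/alt alleles; the
population map assigns each sample a group label (parvulus, pauper,
hybrid, unknown) and a sampling year. Missing genotypes are excluded
from every frequency denominator throughout.

## SNP filtering

A SNP is retained iff its overall minor-allele frequency over
non-missing genotypes is at least `maf_min` (default 0.03) and its call
rate is at least `call_rate_min` (default 0.75) within *every*
population defined by the current group labels. MAF is computed on the
pooled sample while the call rate is per population, mirroring the
semantics of Stacks' `populations` (`--min-maf` global, `-r` per
population). Because the call-rate rule depends on the grouping, the
pipeline runs the filter twice: once under the prior labels and again
after SNP-based reclassification. One-SNP-per-RAD-locus thinning keeps
the first SNP by position (positions are unique within a chromosome, so
no tie-break is needed).

## Relatedness

Pairwise kinship uses the KING-robust estimator: over the SNPs
co-genotyped in a pair, (N_het,het − 2·N_opposite-homozygote) divided by
the summed heterozygote counts of the two samples. Self-kinship is 0.5;
a zero denominator (no heterozygous calls) yields NaN. No automated
sibling exclusion is performed — pairs above the standard second-degree
cut-off (0.177) are reported and removal is left to the caller.

## Ancestry estimation and classification

Ancestry coefficients come from a sparse nonnegative matrix
factorisation of the dosage matrix: minimise over non-missing entries

    sum_(i,l) ( g_il/2 − sum_k q_ik f_kl )²  +  (alpha·n/L)·||F||²

subject to row-stochastic Q ≥ 0 and 0 ≤ F ≤ 1, by alternating projected
least squares (closed-form ridge solves for F clipped to [0, 1]; per-sample
least squares projected onto the probability simplex for Q). The fit
keeps the best objective over `repeats` random restarts (default 100;
10 in the pipeline default for runtime) and is deterministic under a
seed.

The ridge on F is normalised by panel size: the effective per-SNP ridge
is `alpha·n/L`, not `alpha`. An unnormalised ridge of 100 would exceed
the per-SNP data weight (at most n/2) at any realistic panel size,
forcing all ancestral frequencies toward 0 and collapsing Q to binary
labels; normalising makes the default `alpha = 100` a mild shrinkage
whose strength does not depend on how many SNPs were genotyped.

K is selected by masked cross-entropy: `mask_fraction` (default 5%) of
the observed entries is hidden, the model refit, and the held-out
dosages scored by the negative mean log-probability under
Binomial(2, q_i·f_l), probabilities clamped to [1e−9, 1−1e−9]. A larger
K must improve the score by more than 1e−3 to be preferred, so
structureless data settle on K = 1.

Classification uses the two-cluster rule: a sample is assigned to the
cluster of its largest ancestry coefficient when that coefficient
reaches `q_threshold` (default 0.80, boundary inclusive — q = 0.80 is
parental), and is labelled hybrid otherwise. Cluster-to-species identity
is resolved by majority vote of the prior popmap labels.

PCA for visual structure mean-imputes missing dosages per SNP, centres,
scales each SNP by sqrt(2p(1−p)) and drops monomorphic sites.

## Divergence and diversity

Multi-locus F_ST is the Weir–Cockerham (1984) estimator: per-SNP
variance components a (among populations), b (among individuals within
populations) and c (within individuals) computed from sample sizes,
allele frequencies and observed heterozygote fractions, combined as the
ratio of sums θ = Σa / Σ(a+b+c). Negative per-SNP components are kept
untruncated — the ratio-of-sums requires raw components. Confidence
intervals resample loci with replacement (default 100 iterations,
percentile 2.5/97.5).

Per-SNP θ is the single-locus ratio a/(a+b+c) (NaN when undefined).
Φ_ST per RAD locus is an AMOVA on haplotype pairwise-difference counts:
each individual's genotypes within a locus are expanded to two
haplotypes with heterozygous sites phased at random under a fixed seed
(RADseq genotypes are unphased; sensitivity to the phase draw can be
assessed by varying the seed), and Φ_ST = σ²_among / (σ²_among +
σ²_within) from the standard sums-of-squares decomposition.

Per-group diversity: Ho is the mean heterozygote fraction, He the
unbiased expected heterozygosity 2p(1−p)·2n/(2n−1), both averaged over
polymorphic SNPs, and F_is = 1 − mean(Ho)/mean(He) (NaN when He = 0).

## Private alleles

An allele (ref or alt) is private to a parental species when its
observed frequency is > 0 in that species' samples and exactly 0 in the
other species' samples. Privacy is defined on parental samples only and
requires exact absence — no minimum-count smoothing — so sample-size
sensitivity is measured by the subsampling procedure rather than masked
by the definition. Hybrid frequencies are computed overall and per year;
records with fewer than 3 genotyped hybrids in a year are flagged
low-support. Flags:

* `high_freq`: hybrid frequency ≥ 0.30 (boundary inclusive);
* `exceeds_origin`: hybrid frequency strictly greater than the origin
  frequency (ties do not count);
* `present_both_years`: frequency > 0 among hybrids in both sampling
  years ("occurred in both years" is read as *observed*, not merely
  genotyped).

Cross-year shifts (later minus earlier year) are classified as
increase/decrease/unchanged with counts of |Δ| ≥ 0.3 and mean |Δ| ± s.e.
per class per origin. Reported percentages are rounded half-up to the
nearest integer (percent declines to one decimal), matching hand
reporting conventions.

The subsampling sensitivity procedure draws `n_target` hybrids of one
year without replacement (default 3 replicates), recomputes the whole
private-allele chain on the reduced data and averages the numeric
summaries. Dropping hybrids cannot create newly observed private
alleles, so hybrid-observed counts are monotone non-increasing; the
count and fraction of apparent cross-year decreases rises in
expectation because conditioning on presence in the small subsample
biases that year's frequencies upward.

## Outlier scans

**PC-regression scan.** The scaled genotype matrix is decomposed by SVD;
each SNP is regressed on the top-K PC scores (default K = 2, matching
the two genetic clusters; scree fractions are emitted for override),
giving K z-statistics per SNP. Their Mahalanobis distance D² uses a
minimum-covariance-determinant estimate of the z covariance so a few
aberrant SNPs cannot distort the null. D² is rescaled by the genomic
inflation factor λ = median(D²)/median(χ²_K) and converted to an upper
tail χ²_K p-value. Bonferroni at family-wise α = 0.05 is the primary
correction; Benjamini–Hochberg flags are emitted alongside.

**Trimmed chi-square F_ST scan.** Per-SNP uncorrected
F_ST = Σ nᵢ(pᵢ−p̄)² / ((r−1)·n̄) / (p̄(1−p̄)) is computed; SNPs with
expected heterozygosity below 10% are excluded; the lowest and highest
5% of the remaining values are trimmed; and the scaled chi-square null
F_ST ~ (F̄/df)·χ²_df is fitted to the core by maximum likelihood with
explicit truncation at the realised trim bounds (Nelder–Mead on
log-parameters). Right-tail p-values from the fitted null are corrected
by Benjamini–Hochberg at FDR 5%. The fit is refused below 50 core loci.

## Local PCA

The genome is cut into consecutive windows of `window_snps` SNPs per
chromosome (default 25; a trailing remainder shorter than half a window
merges into the previous one). Each window is summarised by the top-k
(default 2) eigenpairs of its mean-imputed, centred sample covariance,
eigenvalues normalised by the window's total variance. Window
dissimilarity is the Frobenius norm between eigenvalue-weighted rank-k
projection matrices; the dissimilarity matrix is embedded by classical
(Torgerson) MDS, clamping any negative eigenvalues with a warning.

Three extreme corners are extracted deterministically: seed 1 is the
window farthest from the centroid, seed 2 the window farthest from seed
1, seed 3 the window maximising summed distance to both; each corner
takes the ⌈proportion·n_windows⌉ nearest windows (default 5%), with
contested windows going to the nearest seed. The source method leaves
corner choice to the analyst's eye; the farthest-point rule is a
reproducible approximation of that visual choice. An aggregated PCA over
each corner's concatenated SNPs is available for inspection.

## Combined evidence

Candidates are the high-frequency private alleles; each gains one tier
for a position flagged by the PC scan and one for falling inside a
corner window's bp span (tier ∈ {1, 2, 3}), sorted by tier then |Δ|.
Matching is by SNP position, with RAD-locus-level joins possible via the
locus id column. Reclassification tables cross-tabulate prior versus
SNP-based labels with half-up integer percentages per prior group.

## Synthetic data generator

The generator emulates the study design with known truth:

* **Divergence.** Ancestral frequencies uniform on [0.05, 0.95]; each
  parental population's frequency drawn from the Balding–Nichols
  distribution Beta(p(1−F)/F, (1−p)(1−F)/F) with F = `target_fst`
  (default 0.035, the observed parental divergence scale). F = 0
  degenerates to identical frequencies. A chosen number of loci can be
  planted as fixed differences (frequency 1 vs 0) to serve as known
  selection targets.
* **Pedigree.** Parental individuals draw both haplotypes from their own
  population; F1s one from each (true ancestry 0.5); a generation-g
  backcross toward parvulus carries one parvulus haplotype and a second
  that is parvulus with probability 1−2⁻ᵍ, giving expected ancestry
  1−2⁻ᵍ⁻¹ (0.75, 0.875, …). Backcrossing is modelled allele-wise by
  expected ancestry, not by recombination maps: all downstream
  statistics are site-wise, and linkage matters only at RAD-locus scale,
  which is preserved by drawing all SNPs of a RAD locus from the same
  parental haplotype origin per individual.
* **Years and drift.** Samples are organised in per-year cohorts; later
  years draw from frequencies passed through one Wright–Fisher binomial
  round of size 2·`drift_ne` (default 500; the real system's effective
  sizes are unknown, and this default produces small cross-year shifts
  of the observed order).
* **Missingness.** Uniform at random at `missing_rate` (default 0 in the
  API, 0.16 in study-condition runs — only mean missingness is known, no
  structure).

The truth set records per-sample expected ancestry, the parental-
exclusive alleles realised in the parental samples, and planted
divergent loci. What passing tests on this generator do *not* show: the
generator has no linkage beyond RAD loci, no structured missingness, no
selection dynamics, and drift is a single idealised round — conclusions
about power on real RADseq data (where missingness is locus-structured
and backcrossing is sex-biased) need the real data.

## Numerical choices and degenerate inputs

* WC84 components are NaN for SNPs where any population has fewer than
  two genotyped individuals; monomorphic SNPs contribute 0/0 and are
  skipped from ratio sums.
* Monomorphic SNPs are dropped before any PCA scaling; monomorphic
  windows are excluded from the local-PCA distance computation.
* Binomial likelihoods clamp probabilities to [1e−9, 1−1e−9].
* The NMF stops when the relative objective decrease falls below 1e−7 or
  at `max_iterations` (default 1000), returning the best iterate with a
  convergence flag.
* All stochastic steps (NMF restarts, cross-entropy masks, bootstrap,
  Φ_ST phasing, subsampling) consume explicit seeds; the pipeline
  refuses a config without one.

## Problem sizes used in verification

The test-suite and the acceptance script exercise the method at the
study's design scale or modest multiples below it: 10,000 SNPs on 30
chromosomes with 50 + 30 + 15 samples for F_ST recovery; 5,000 SNPs and
30 + 30 + 10 samples across three seeds for classification recovery;
5,000-SNP panmictic panels for scan calibration; 1,000-SNP single-
chromosome panels (40 windows) for the local-PCA planting check; and
2,000-SNP two-year swarms (11 vs 4 hybrids) with 20 subsample draws for
the sensitivity properties. These sizes were chosen as the smallest at
which the corresponding statistics are stable.

## Known limitations

* Φ_ST depends (weakly) on the random phase draw; only one draw is
  reported per run.
* The trimmed chi-square null assumes an equilibrium island-model
  F_ST distribution; strong hierarchical structure would miscalibrate
  it (the PC scan is the primary instrument here).
* The masked cross-entropy compares K values on one mask draw per K;
  very close scores (< 1e−3) resolve toward the smaller K.
* Corner extraction is deterministic but not rotation-invariant in
  degenerate embeddings where many windows tie at equal distances.
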