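# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `germdecon`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Genotype model

The central object is an accessions × SNPs grid of genotype calls. A call
is the alternate-allele dosage d ∈ {0, …, ploidy} plus reference and
alternate read depths; missing calls are stored explicitly (never imputed
at this layer — mean imputation happens only inside PCA). The dosage
fraction f = d/ploidy is the coordinate shared by all downstream
computations, which is what lets diploid, tetraploid, and hexaploid
accessions live in one matrix. Heterozygote means 0 < d < ploidy.

VCF input takes dosage as the count of non-reference alleles in GT at any
ploidy and depths from AD. Multi-allelic records are rejected in strict
mode; otherwise they are reduced to the most-supported alternate allele
(calls involving other alternates become missing) — the upstream GBS
genotypers this package consumes emit bi-allelic SNPs only, so this path
is a safety valve, not a modeling choice. The TSV "genotype table" dialect
(fixed SNP columns, then `dosage:ref:alt` cells) is this package's own;
it carries a `snps_in_centroid` column so markers from multi-SNP GBS
fragments can be excluded (`simplex_only`), but it does not claim
bit-compatibility with any particular upstream tool's matrix layout.

## Gower dissimilarity

Both codings reduce to GD = mean |state_a − state_b| over co-genotyped
SNPs, with states {0, 0.5, 1} (collapsed) or dosage fractions (dosage
coding). Consequences worth knowing:

* Collapsed and dosage codings coincide exactly on diploids.
* The dosage-coding score for mismatched tetraploid heterozygote classes
  is the linear dosage distance (3:1 vs 1:3 → s = 0.5); the published
  formulation does not define these cross-class scores, and the linear
  rule is the one consistent completion that preserves the diploid scores.
* Mixed-ploidy pairs are only comparable under collapsed coding; dosage
  coding across ploidies raises an error rather than guessing.
* A pair with no shared typed SNP is NaN in the matrix. Redundancy
  grouping treats NaN conservatively as "distinct"; clustering refuses
  NaN outright, since a tree over undefined distances is meaningless.

The matrix computation factors the state alphabet into indicator matrices
so the whole N×N computation is a handful of matrix products; an
independent per-SNP loop oracle in the test suite agrees to 1e-12.

Diploidized-marker selection keeps SNPs whose heterozygous depth ratios
across tetraploid accessions average within 0.05 of 0.25 (or 0.75) with
SD ≤ 0.05 and at least 3 supporting accessions. On simulated tetraploid
collections the redundancy partition from this subset equals the
all-marker partition (tested), mirroring the robustness argument for
using the simple GD on polyploids.

## Ploidy inference

Heterozygous depth ratios alt/(ref+alt) at sites with total depth ≥ 10
are smoothed with a Gaussian KDE of fixed bandwidth 0.025 on [0, 1].
Rule-of-thumb bandwidths (Silverman/Scott) assume unimodality and merge
the five hexaploid modes, so a fixed kernel below half the 1/6 class
spacing is used instead. Local maxima with prominence ≥ 2% of the global
maximum inside [0.05, 0.95] count as peaks (dosage classes are very
unevenly populated, so interior modes can sit on shallow valleys); maxima
closer than 0.09 are merged. The peak list is matched bijectively against
{0.5}, {0.25, 0.5, 0.75}, {1/6 … 5/6} with per-peak tolerance ±0.06;
exactly one consistent template yields a call, anything else is
"unclear". A lone central peak is additionally demoted to unclear when
the density at 0.25/0.75 reaches half the central density (possible
suppressed tetraploid shoulders) — conservative by design. Accessions
with fewer than 100 usable ratios return "insufficient_data". Unclear
accessions may inherit the consensus ploidy of an "ok" redundancy partner
in a post-partition annotation pass that never overwrites a direct call.

Resolving five hexaploid modes needs real depth: at 60× the adjacent-mode
separation is ~3.5 binomial standard deviations, at 30× it is not.
Expect hexaploids to come back unclear in low-coverage collections —
which is also why the redundancy-inheritance pass exists.

## Redundancy thresholds

Replicate GDs are pooled per category: pairs sharing a replicate tag and
also library and lane are biological; pairs split across libraries or
lanes are technical. The cutoff is the one-sided 99th percentile of the
fitted normal, mean + 2.3263·sd, used only when a Shapiro–Wilk test does
not reject normality (p ≥ 0.05); otherwise the empirical 99th percentile.
The percentile — not a confidence interval of the mean — is deliberate: a
mean-CI shrinks with replicate count and would eventually declare true
replicates non-identical. Zero-spread inputs return the mean with a
degenerate-distribution warning; fewer than 3 values is an error.

Read sub-sampling is approximated by binomial thinning of each allele's
depth at the configured fraction (default 0.5, 10 sub-samples, 45 pairwise
GDs) followed by re-calling through the depth-ratio caller (dosage =
round(ploidy·ratio), minimum call depth 6, heterozygotes need ≥ 3 reads of
each allele). True read-level resampling with replacement cannot be
reproduced post-alignment; thinning matches its first two moments per
site.

Cross-species extrapolation divides a species' subsampling GD_99% by the
mean subsampling:technical ratio estimated from species that have both.
Recomputing that ratio from the published per-species thresholds gives
0.31; the published rounded 0.30 remains available as a
`paper_compat_ratio` config constant.

## Synthetic collections

The generator is the package's test bed and defines its study conditions:

* Ancestral allele frequencies ~ Uniform(0.05, 0.95); sub-population
  frequencies by a Balding–Nichols Beta draw with divergence parameter
  `fst` (default 0.15; recovery tests use 0.2–0.3). A Hudson-style FST
  estimator recovers the parameter within ±0.1 at 2000 SNPs (tested).
* Founder dosages ~ Binomial(ploidy, p_subpop); default ploidy 4 (the
  dominant class in cold-hardy clonal fruit collections), with per-founder
  overrides. A configurable fraction of markers (default 0.13) is
  "diploidized" in polyploids: drawn Binomial(2, p), at most two variable
  copies, heterozygous depth ratio ~ 1/ploidy.
* Replicate error is a post-call channel: with probability p a call moves
  one dosage step (reflecting at the bounds). Copies in a within-library
  replicate set use the intra-library rate (default 5e-4), copies in a
  cross-library set the inter-library rate (default 3.2e-3, i.e. 6.4×).
  Each member of a technical set carries the inter-library rate, so the
  expected technical:biological mean-GD ratio equals the rate ratio; the
  observed ratio on the standard fixture is ~6–7 (tested to lie in
  [4, 10]). The channel is calibrated to put biological replicate GDs at
  a few 1e-4 and technical at a few 1e-3, the magnitudes observed for GBS
  replicates. Clones perturb the founder's profile directly; re-calling
  every copy independently from fresh depth draws would put tetraploid
  replicate GDs near 1e-2 — an order above what replicated GBS data
  show — because depth-ratio calls near class boundaries flip
  independently. The published error rates are not recoverable from
  summary dissimilarities alone, so these channel constants are this
  package's calibration, documented as such.
* Per-cell depth ~ negative binomial (mean 40, dispersion 5 — GBS
  coverage is over-dispersed), floored at the minimum call depth so that
  missingness comes only from the explicit missing-call channel (default
  rate 0.065, matched by the realized fraction within 2 SE; tested).
  Allele depths ~ Binomial(depth, f(1−e)+(1−f)e) with sequencing error
  e = 0.005, which concentrates heterozygous ratios at the dosage
  fractions.

What the simulator does **not** model: linkage disequilibrium, allele
dropout/null alleles, library-specific fragment representation bias
beyond the scalar error channel, batch effects on depth, or genotype-call
uncertainty correlated across loci. Passing recovery tests therefore
show the estimators are correct under the stated error model, not that
real collections behave this benignly; on real data thresholds should
always come from that collection's own replicates.

## Clustering

The eight hclust agglomeration rules run through scipy's linkage;
ward_d uses the identity ward.D(d) = ward.D2(√d) with squared heights.
An independent naive Lance–Williams implementation in the tests agrees to
1e-10. Tie-breaking follows scipy's deterministic nearest-neighbor-chain
order. Method selection bootstraps SNP columns (the feature-resampling
convention of cladogram-stability tools; the resampling unit is a
documented choice, not unique), recomputes the GD matrix, and scores each
method by the cophenetic correlation coefficient; clade stability is the
plain bootstrap proportion of SNP-resampled trees containing the same
leaf clade — approximately-unbiased multiscale p-values are deliberately
out of scope. Newick export writes heights as branch lengths and support
percentages as internal labels.

## Population genetics

PCA runs on mean-imputed, centered dosage fractions (optional unit
scaling). K selection fits K-means (10 restarts, seeded) on the leading
PCs holding ≥ 90% of variance and scores BIC(K) = n·ln(WSS/n) + K·ln(n)
(the find.clusters convention — K-means BIC has no single canonical form,
so one is fixed and stated); the chosen K is the smallest K attaining the
minimum, so a monotone curve returns the smallest K evaluated.

AMOVA is an allele-level nested ANOVA: each accession contributes
`ploidy` binary allele copies per locus, sums of squares decompose among
groups / among genotypes within groups / within genotypes, and variance
components come from the standard expected-mean-square coefficients for
unbalanced nested designs. Per-locus sums use that locus's typed
accessions; degrees of freedom and coefficients use the full design
(at ~6.5% missingness the coefficient error is negligible). Negative
components truncate to zero with a flag and percentages renormalize.
F_ST is the among-group share of total variance. P-values are
permutational: genotypes among groups for the among-group stratum;
allele copies redistributed among genotypes within groups (sequential
hypergeometric sampling, vectorized over loci) for the other two, with
p = (count+1)/(n_perm+1). The default is 999 permutations — 0.001
resolution, the conventional choice — with the count exposed in config.
Under no structure the among-group p-values are uniform (tested by a
Kolmogorov bound over 400 replicates).

Diversity per population: allele frequency p from dosage sums over
ploidy-weighted copies (the natural polyploid generalization; the
reference desktop programs' internal polyploid conventions are not
restated anywhere authoritative, so numerical parity is claimed only
with these definitions), N_E = 1/(p²+q²), unbiased H_E with the
n_c/(n_c−1) correction, H_O = fraction of heterozygous accessions, F_IS =
mean over polymorphic loci of 1 − H_O/H_E. Note that for autopolyploids
H_O routinely exceeds the allele-frequency H_E, giving strongly negative
F_IS — an artifact of comparing a ploidy-dependent observed rate with a
two-allele expectation, visible in published polyploid tables as well.
The |F_IS| < 0.05 random-mating check in the tests is therefore run on
diploid simulations.

## Pipeline

`run_deconvolution` runs per species: load → ploidy → GD → thresholds
(technical replicates preferred, biological fallback, read-subsampling
when no replicates exist) → partition + conflicts + representative
culling → linkage selection → bootstrapped tree → PCA → K selection →
AMOVA → diversity. Structure analyses run on the culled set only. All
randomness derives from the single config seed; rerunning a config
byte-reproduces the summary JSON (tested). Stage failures abort with the
species and stage named; partial outputs are kept.

## Problem sizes

Tests and the acceptance script run on deliberately modest instances:
2000–4000 SNPs, 20–60 genotypes, clone triplets for 12 founders, 10–200
bootstrap/permutation replicates in unit tests (the pipeline defaults are
higher). These sizes were chosen so each statistical check has adequate
power (e.g. ≥ 18 replicate pairs behind a threshold estimate, 20 seeds
behind the K-recovery rate) while the whole suite stays interactive.
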