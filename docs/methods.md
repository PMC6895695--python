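# Methods

`cardiofate` models a directed cardiac differentiation experiment: a
collection of induced pluripotent stem cell (iPSC) lines is differentiated
toward cardiovascular progenitors, each harvested sample is a mixture of
cardiomyocytes (CM), epicardium-derived cells (EPDC) and a residual
stem-like population (SC), and the question is which features of the
*undifferentiated* lines — signature-gene expression, sex, X-chromosome
activation state, genotype — predict the CM/EPDC outcome. This note
documents the statistical procedures, the synthetic data they are
validated on, and the design choices made where the design was open.

## Deconvolution

The signature matrix is built by one-vs-rest marker selection: for each
population, genes are tested for overexpression with a Welch t-test on
log2(TPM+1) over reference replicates, ranked by p, and the top N (default
50) passing the p cutoff (default 1e-13) are retained. A gene ranking in
two populations is kept once, assigned to the population where its p is
smallest, so the matrix never contains duplicate rows. Fractions are then
estimated per bulk sample by nonnegative least squares of the marker-gene
expression on the signature columns (linear TPM space — mixing is linear
in linear space), with coefficients renormalized to sum to one. NNLS is
deterministic and dependency-light; it is validated by mixture-recovery
tests (mean absolute CM-fraction error < 0.05 at multiplicative log-normal
noise sd 0.1 over 50-sample cohorts) rather than by comparison to the
support-vector formulation some reference tools use.

## Fate assignment and the threshold sweep

A line is CM-fated at ratio threshold k when its estimated CM fraction is
>= k; differentiations terminated before harvest (no beating syncytium)
are assigned CM fraction 0. Candidate thresholds run from 0.0 to 0.9 in
steps of 0.1. At each threshold a per-gene Welch t-test on log2(TPM+1)
compares CM-fated to EPDC-fated lines; genes at Storey q < 0.1 are
counted; the threshold maximizing the count wins, with ties broken toward
the smaller threshold (deterministic, favors the inclusive CM class).
Thresholds leaving fewer than three lines in either class are skipped and
reported. Bookkeeping over the union of genes significant at any threshold
records how many attain their strongest p at the winner. Calibration: the
observed count is compared against a permutation null that reshuffles the
fate labels (class sizes preserved exactly) 100 times.

The final signature adds borderline genes: not q-significant at the best
threshold, but nominally p < 0.0015 (two-sided) *and* annotated to a
relevant pathway class (WNT/beta-catenin, muscle/cardiac, EMT). Direction
is the sign of the CM-minus-EPDC mean difference.

## Multiple testing

Storey q-values use the smoothed lambda-grid pi0 estimator (grid
0.05-0.95, step 0.05, cubic least-squares smoother evaluated at the
largest lambda, clamped to (0,1]) and the step-up rule
q_i = pi0 * min_{p_j >= p_i} m p_j / rank(p_j), ties taking the largest
rank. With pi0 fixed at 1 the procedure reduces exactly to
Benjamini-Hochberg, which the tests verify against an independent
implementation.

## Per-gene and joint signature models

Each signature gene's association with the outcome fraction is fit two
ways: ordinary least squares of the fraction on log2(TPM+1) (identity
link), and a quasi-binomial GLM with logit link (fractional outcome;
Pearson-chi2 dispersion), since a binomial likelihood is not literally
available for a continuous fraction. Variance explained is reported as a
pseudo-R2, by default the squared Pearson correlation between fitted and
observed (a deviance ratio is offered as an alternative; the choice is
recorded in output metadata).

The joint model is LASSO regression of the outcome fraction on all
signature genes (standardized log2(TPM+1)), with the penalty chosen at the
minimum mean held-out squared error over a shared alpha path under
10-fold cross-validation. Folds are stratified by outcome rank to
stabilize small cohorts. The reported R2 comes from held-out folds only
(SST against the training-fold mean), so pure-noise inputs score near or
below zero and the estimate carries no optimism; tests verify it never
exceeds the in-sample OLS R2.

## X-chromosome allelic imbalance

The allelic imbalance fraction (AIF) of a gene in a sample is
max(ref, alt)/(ref+alt) over allele-specific read counts; 0.5 is balanced
biallelic expression (both X active), 1.0 monoallelic (one X inactive).
Rows under the coverage floor (default 20 reads; folded-binomial bias
< 0.06 there) are dropped and tallied. Genes overlapping the
pseudoautosomal regions PAR1 (chrX:60,001-2,699,520) and PAR2
(chrX:154,931,044-155,260,560), 1-based inclusive, by any base are masked
from chrX statistics. Group comparisons pool gene-sample AIF values and
use a two-sided Mann-Whitney U (normal approximation, tie-corrected).
Regional analysis computes per-gene delta AIF = mean(group A) − mean(group
B) — the sign convention is explicit in the output — and tests each named
chrX interval's member deltas against zero with a one-sample Wilcoxon,
stratified by escape/non-escape annotation when provided. Escape-gene
annotation is a user input; no list is bundled.

## Enrichment

The per-gene input statistic is the normalized mean expression difference
(mean difference over pooled standard error on log2(TPM+1)); positive
means higher in CM-fated lines. Each gene set is tested member-vs-rest
with a Welch t-test, both one-sided directions evaluated; the direction
with the smaller p is reported alongside the two-sided p (doubled
one-sided minimum), which is uniform under the null. FDR correction runs
independently within each collection. Sets below 10 scored genes are
dropped (stabilizes the t approximation). chrX runs are restricted to
female lines via a sample filter.

## Association

Covariates (sex, age, ethnicity, passage) enter a logistic GLM on the
binary fate with Wald Z tests; categorical covariates are one-hot encoded
against the most frequent level; complete cases only, with dropped counts
reported. Perfect separation — likely in small cohorts — triggers a
Firth-penalized refit (Jeffreys-prior score correction), flagged in the
output. The variant scan is per-variant OLS of the outcome fraction on
dosage with covariates projected out of both sides (Frisch-Waugh), folded
allele frequency > 5% required, monomorphic variants skipped, and a
genome-wide flag at p < 5e-8; calibration is checked by the genomic
inflation factor on null scans. Clone/twin concordance compares
within-pair |outcome difference| to all unrelated cross-pairs with a
Mann-Whitney U.

## Replication

Batch diagnostics compare Spearman sample-sample correlations within each
cohort and across cohorts on the shared gene universe. The replication
test correlates the two cohorts' per-gene fate contrasts over all shared
genes, then counts signature genes with nominal p < alpha and matching
direction in the second cohort. The "random expectation" is constructed
empirically: the rate of the same criterion (direction taken from the
discovery contrast) among non-signature shared genes; Fisher's exact test
is applied to the 2x2 table of signature membership against criterion
status. Under an independent null second cohort the expected replication
rate is alpha/2 per gene (the sign agreement halves the nominal rate),
which the tests verify to within sampling error.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes, so
every stage is testable without restricted-access data.

* **Reference profiles.** Gene baselines are log-normal TPM; each
  population receives a disjoint block of marker genes whose mean exceeds
  every other population's by a configured fold change (default 8).
  Pseudo-replicates (default 20, log-normal sd 0.2) stand in for the
  per-cell replicates a reference atlas would provide; 20 is the depth at
  which fold-8 markers clear a p < 1e-13 selection cutoff under a t-test.
* **Bulk mixtures.** Linear combinations of the reference columns with
  multiplicative log-normal noise; expression noise is multiplicative on
  TPM to preserve nonnegativity and heteroskedasticity. noise_sd = 0
  reproduces the exact mixture.
* **iPSC cohort.** Each line draws a latent CM fraction. The default
  (`fate_dist="bimodal"`) mixes a high component Beta(9, 1.5) (weight
  0.82) with a low component Beta(1.2, 5), giving a cohort where roughly
  two-thirds of lines are CM-fated at the 0.3 threshold and the spread of
  outcomes is wide, as in large differentiation panels. Terminated lines
  (default 37 of 184) draw their latent from a low tail and report outcome
  0. A planted signature gene g is shifted in log2 space by
  sign(g) x effect x noise_sd x (c − 0.5), where c is the latent fraction
  (`coupling="linear"`) or the indicator of reaching a step threshold
  (`coupling="step"`). `effect_profile="fixed"` gives all genes one
  magnitude; `"exponential"` draws per-gene magnitudes with that mean,
  reflecting the orders-of-magnitude spread of per-gene contributions real
  signatures show. The sign split defaults to 36 positive / 55 negative
  out of 91.
* **Threshold-identifiability design.** When the object under test is
  *where* the optimal threshold lies, the latent distribution must place
  mass on both sides of the boundary; otherwise several thresholds induce
  identical labelings and the optimum is undefined. `fate_dist="boundary"`
  (truncated normal, mean 0.32, sd 0.12) is the design used for those
  recovery experiments; it was fixed by a pilot analysis of
  label-dilution factors before the tests were written.
* **Sex effect.** Female lines get lower termination odds and a higher
  high-fate mixture weight; the default magnitude (0.35) was set by an
  oracle power calculation targeting ~85% power for a p < 0.01 logistic
  sex effect at n = 180.
* **X-inactivation.** Female lines are XaXa, XaXi, or mosaic (default mix
  0.25/0.55/0.20). Allele counts are Poisson totals (mean = depth) split
  binomially: non-escape chrX genes of XaXi lines at skew 0.99, everything
  else at 0.5; mosaic lines reactivate each gene independently with their
  per-line probability (per-gene Bernoulli erosion — real partial erosion
  is region-wise, which this does not model). Counts are generated for
  female lines only, matching the scope of the chrX analyses.
* **Genotypes.** Hardy-Weinberg dosages at uniform MAF; an optional causal
  variant adds beta x dosage to the latent fate, with a helper computing
  beta for a target variance-explained.

Planted truth (signature genes and signs, X states, true fractions) is
emitted alongside the data and never consumed by analysis code.

**What the generator does not emulate:** read-level noise, GC/length
biases, batch structure within a cohort, correlated co-expression modules,
linkage disequilibrium, region-wise X erosion, or clone lineage beyond a
single correlation knob. Passing recovery tests therefore demonstrates
that the procedures are correct and calibrated under their stated
assumptions, not that those assumptions hold in any particular real
dataset.

## Numerical choices and degenerate inputs

Expression tests operate on log2(TPM+1). Welch (unequal-variance) t-tests
are used throughout where a "t test" is called for. Genes with zero pooled
variance get contrast statistic 0 with a flag. NNLS fits that return an
all-zero coefficient vector (possible only for pathological inputs) fall
back to uniform fractions with a warning. Storey pi0 falls back to the raw
estimate at the largest lambda when the grid has fewer than four points.
Argmax ties in the sweep go to the smaller threshold; p-value ties in the
step-up rule take the larger rank; LASSO alpha ties resolve to the larger
(sparser) penalty. The fate boundary is inclusive (>= threshold is
CM-fated). All generators draw from substreams derived deterministically
from one integer seed.

## Problem sizes used in the shipped checks

The acceptance script and test suite run at desk scale: 3,000-gene
references, 184-line cohorts (37 terminated), 80-91 signature genes,
ASE depth 200 over ~120 genes, 10,000-variant null scans, 2,000-variant
causal-recovery scans, 20-seed recovery sweeps, 50-100 replicate
calibration loops, and 500-replicate replication nulls. These sizes were
chosen so the full suite characterizes every stage's behavior while
remaining quick to run end to end.

## Known limitations

* The deconvolution reference and the bulk mixtures share the same
  generative family in the synthetic cohort; cross-platform reference
  mismatch is not modeled.
* The quasi-binomial "logit link" per-gene model treats the fraction as
  the mean of a binomial of unknown size; its R2 is a pseudo-R2, not a
  likelihood-ratio quantity.
* The enrichment test is parametric (t on member vs rest); no
  running-sum/Kolmogorov-Smirnov enrichment or leading-edge extraction.
* The variant scan has no mixed-model relatedness correction; related
  lines inflate the effective sample size slightly.
* Replication's "random expectation" is an empirical background rate among
  non-signature genes; other constructions (e.g. label permutation) would
  give slightly different expected counts.
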