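# Methods

## Generative model

The simulator produces gene-level RNA-seq counts for a *Drosophila*-like
genome of six chromosome arms (X, 2L, 2R, 3L, 3R, 4; defaults 900 genes
per major arm, 60 on the dot chromosome — real arms scaled down ~3×,
proportions kept). Each gene carries truth labels assigned by exact
quota: `responsive` (participates in the trans inverse-dosage response;
default fraction 0.8), `sex_bias_truth` (default 15%, split evenly
female/male, up-multiplied 4× in the biased sex), and `is_tf` (5%,
available for enrichment exercises). The responsive fraction is a
simulator free parameter, not an empirical claim: real ratio
distributions have a ratio-1 shoulder, and 0.8 keeps the modal bins at
the theoretical peaks while producing that shoulder.

Counts are negative binomial, `Var = μ + α μ²`. Expected expression is a
product of multiplicative factors (cis dosage `c/c0`; trans inverse
`c0/c` per varied arm for responsive genes; MSL2 repression 2/3 for
responsive genes in transgene females, 1 in males; sex-bias multiplier;
per-batch per-gene log2 offsets). `c0` is the sex-matched euploid copy
number — male X counts as 1, so the male X is treated as baseline-
compensated by the endogenous MSL complex and cross-sex contrasts are not
distorted by an artificial 2× X shift.

Baselines are log-normal (meanlog 3, sdlog 1.5 on the CPM scale);
dispersions are gamma (shape 2, scale 0.005, mean 0.01), a level
appropriate for biological replicates that each pool ~20 larvae. Batch
offsets are drawn per gene, N(loc, scale) in log2 units, with the first
batch as reference; a batch shift uniform across genes would be removed
by CPM renormalization before any batch correction ran, so per-gene
offsets are what make batch adjustment a testable operation.

### The stable (mass-anchor) compartment

CPM divides by the library total, so it measures relative composition: a
genome-wide 2/3 down-regulation mostly cancels itself through the
denominator, and per-gene CPM ratios equal the generative ratios only if
total library mass is approximately invariant across karyotypes.
Observed aneuploid CPM distributions nonetheless peak at the uninflated
theoretical values (2/3, 1, 4/9), which is only arithmetically coherent
if the bulk of library mass is carried by dosage-insensitive RNA. The
default model therefore promotes 150 unresponsive, non-sex-biased genes
to a high-abundance "stable" compartment holding 96% of expected library
mass, with low dispersion (0.005): a stand-in for perdurant maternal,
structural, and strongly buffered housekeeping transcripts whose
steady-state abundance does not track zygotic copy number. These genes
take factor 1 under every karyotype. Consequences: the CPM denominator is
anchored (residual ratio inflation ≤ ~2%, which keeps every theoretical
peak inside its 0.05-wide bin), while the 150 stable genes contribute
only negligibly to any binned frequency. Without this compartment the
simulated trisomy peaks appear at ≈0.83/1.22 instead of 0.67/1.0 — an
artifact of normalizing a globally shifted transcriptome, not of the
dosage model.

What the generator does **not** emulate: transcript isoforms (gene level
only), length effects (CPM, not TPM), GC/mappability bias, outlier
samples, and correlated noise beyond the block structure induced by the
effect factors themselves. Passing parameter-recovery tests therefore
demonstrates the correctness of the pipeline's statistics, not robustness
to every artifact of real libraries.

## Preprocessing

Fixed order: prefilter genes with < 10 total reads → CPM → temporary
log2(CPM + 0.5) → batch adjustment (only when the design spans ≥ 2
sequencing batches, genotype as covariate) → back-transform → drop genes
with any nonpositive value (they would generate extreme ratios) →
arithmetic replicate averaging per genotype. The log offset 0.5 is a
package choice; results are de-logged before ratios so the offset never
enters a ratio. Averaging after batch adjustment is deliberate —
permuting the two changes results.

The batch step is parametric empirical-Bayes location/scale adjustment
(ComBat): per gene, standardize under a batch + group model; estimate
per-batch location γ and scale δ²; shrink toward a normal / inverse-gamma
prior moment-matched across genes, iterating the coupled posterior-mean
equations to 1e-4; remove, rescale, restore. Only the parametric branch
is implemented. A final per-gene re-centering enforces exact preservation
of each gene's grand mean (the adjustment itself preserves it only
approximately); the test suite checks agreement with Bioconductor
`sva::ComBat` up to that centering. Batches of one sample and batches
perfectly confounded with a covariate group are rejected.

## Ratio distributions

Per-gene ratios are experimental over control group means, tagged by
chromosome class relative to the dosage-varied arm (`varied_arm`, `X`,
`other_autosome`). Binning is half-open at constant width (0.05 default;
0.1 with percentage frequencies), range [0, 3) — the displayed peaks all
lie in 0.4–1.5 — with ratios ≥ 3 counted as overflow rather than binned.
The modal peak is the center of the maximal bin; ties resolve toward the
bin nearest ratio 1.0 (peaks are interpreted relative to the no-change
line), then to the lower bin. No kernel smoothing is used: the peak is a
property of the binned frequencies.

Note one structural consequence of half-open bins: the theoretical values
1.0 and 1.5 sit exactly on bin edges, so with symmetric sampling noise
the modal bin alternates between the two adjacent bins, both of whose
centers are exactly 0.025 (one half-width) from the theoretical value.
Recovery checks therefore compare |modal center − expected| against the
half-width rather than asking which side of the edge the mode fell on.

The two-sample Kolmogorov–Smirnov statistic is the exact supremum of the
empirical-CDF difference over the pooled points; the p-value is the
asymptotic series Q(λ) = 2 Σ (−1)^{k−1} exp(−2k²λ²) with the standard
small-sample correction λ = (√n_e + 0.12 + 0.11/√n_e)·D,
n_e = n_a n_b/(n_a+n_b), clamped to (0, 1].

## Chromosome profiles

Genes are ordered at equidistance (ordinal rank, not base pairs — the
analysis only needs order) by arm in the fixed sequence X, 2L, 2R, 3L,
3R, 4, position within arm, gene id for ties. log2 fold changes are
smoothed per arm independently (no bleed across the plotted separators)
by LOWESS with tricube weights, span 0.05 of the arm and 3 robustifying
iterations (statsmodels backend); arms with < 3 genes pass through with a
warning. The span and iteration count are package defaults, exposed as
parameters. Signed regions are maximal runs of one sign per arm; zeros
attach to the preceding run, leading zeros join the first signed run, and
an all-zero arm is a single "none" region. Segmentation is descriptive —
no changepoint statistics.

## Differential expression

Median-of-ratios size factors over genes positive in every sample. The
two-group NB test fits each group's log-mean exactly (the design is
saturated, so the GLM reduces to a per-group 1-D Newton solve of the NB
score equation), giving a Wald statistic log2fc/se with
se² = 1/I_A + 1/I_B from the Fisher information Σ μ/(1+αμ). Reversing the
contrast negates log2fc bitwise. P-values are two-sided normal,
BH-adjusted.

Dispersion estimation controls the test's calibration at n = 3 + 3 and is
the one place the package goes beyond a textbook recipe:

1. gene-wise Cox–Reid-adjusted profile-likelihood estimates on a log-α
   grid with parabolic refinement (grid search is robust to the flat
   small-sample likelihoods);
2. a running-median trend over mean-expression order (window 5% of
   genes, ≥ 25);
3. a one-replicate parametric bootstrap: counts are resimulated at the
   trend dispersion and re-estimated, giving (a) a multiplicative bias
   correction for the running median of a skewed estimator and (b) the
   sampling variance of the log estimates — the χ²-based trigamma formula
   underestimates it for NB data at 4 residual df;
4. empirical-Bayes shrinkage with posterior weight
   prior/(prior + sampling noise), the prior variance being the excess of
   the observed robust spread of log dispersions over the bootstrap
   sampling variance, floored at 0.25². When true dispersions follow the
   trend tightly the weight collapses toward the trend and the Wald test
   behaves as if dispersion were known — this adaptivity, not a fixed
   shrinkage weight, is what keeps the null type-I error at ~0.05 with
   three replicates per group.

No Cook's-distance outlier handling and no independent filtering; the
contracts are calibration and fold-change recovery (checked against a
brute-force null simulation and against pydeseq2 on a fixture), not
numerical identity with any release of the reference tool. Sexes and
batches are analyzed in separate tests, since dispersions differ
systematically between them.

Sex-bias classes come from the diploid female-vs-male contrast (log2fc
oriented female over male): padj < 0.05 and positive → female-biased,
negative → male-biased, else non-biased; no fold-change cutoff beyond
significance. Set overlaps use the one-sided hypergeometric tail
(enrichment direction); PPI neighborhoods are breadth-first subgraphs
within a hop limit (2 edges in females, 3 in males around *msl-2* in the
original use), with STRING-dialect 0–1000 scores normalized to [0, 1].

## Coexpression

The top-n genes by mean log expression (default 10,000) enter a signed
adjacency a_ij = ((1+r_ij)/2)^β, Pearson r, β = 11 for the autosomal
design and 17 for the sex-chromosomal design (fixed, no scale-free fit
search), then the topological overlap matrix
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij), TOM_ii = 1,
computed in one block. Modules are average-linkage clusters of 1 − TOM
under a static height cut (default 0.995) with clusters < 30 genes set to
"grey"; the static cut replaces the dynamic hybrid tree-cut heuristic
because planted-block recovery is the testable contract and the full
heuristic is out of proportion to its use here. Labels follow the
conventional color order by decreasing size. Note the cut height
interacts with the correlation structure: for strongly blocked designs a
lower cut (e.g. 0.95) is appropriate, since between-block TOM
dissimilarity fluctuates just below 1 while within-block dissimilarity is
far smaller.

Module eigengenes are PC1 of the per-gene z-scored module submatrix
(SVD), sign-oriented to correlate positively with the module's mean
profile; variance explained is the PC1 share of squared singular values.
Per-genotype summaries are means with t-based 95% confidence intervals;
single replicates get a mean and a flagged-absent CI.

## Problem sizes and determinism

Default study simulations are 4,560 genes × 3 replicates per genotype
with a library parameter of 5×10⁶ — sizes at which the full test suite
runs in well under a minute while every chromosome class keeps ≥ 500
responsive genes, the scale at which modal-bin recovery is
sampling-robust. All randomness flows from explicit integer seeds through
`numpy.random.Generator`; a fixed seed reproduces counts bit for bit.
The acceptance script derives independent sub-seeds for genome, model,
and the two count draws from the single `--seed` via `SeedSequence`.

## Known limitations

* The NB test supports exactly two groups (the study's contrasts are all
  pairwise); no continuous covariates in the DE model.
* ComBat is parametric-prior only.
* Coexpression has no module merging by eigengene correlation and no
  block-wise TOM approximation; it is meant for ≤ ~10⁴ genes.
* Gene-level only throughout; isoform-level sex-bias analysis is out of
  scope.
* The stable-compartment mass fraction is a modeling device calibrated to
  the compositional-invariance requirement, not an estimate of any real
  larval RNA fraction.
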