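# Methods

This note documents the models, algorithms and numerical choices behind
`causal-gwas`, and what the synthetic experiments do and do not establish.

## The discovery model

A Markov boundary of the phenotype *T* is a minimal variable set **M** such
that every other variable is statistically independent of *T* given **M**.
Under the standard causal-discovery assumptions (causal Markov condition,
adjacency faithfulness relaxed to admit information-equivalent variable
sets, causal sufficiency, correct statistical decisions), the Markov
boundary coincides with the local causal pathway of the phenotype. In a
GWAS design the phenotype has no spouse variables — no measured variable is
a co-parent of a child of *T* — so the parents-and-children set already
equals the Markov boundary and no spouse-recovery phase is needed.

### Conditional-independence testing

All decisions rest on the G² likelihood-ratio test for discrete variables:

G² = 2 Σ_s Σ_{t,x} O·ln(O/E),

summed over the strata *s* of the conditioning configuration, with E the
product-margin expectation inside each stratum. Degrees of freedom sum,
over non-empty strata, (r−1)(c−1) counting only levels with non-zero
stratum margins; a test with zero total df returns p = 1 (no evidence of
dependence — this is exactly what happens when conditioning on an exact
duplicate of the tested SNP). Rows with a missing value in any tested
column are dropped for that test only.

A test is **reliable** when n ≥ 5 cells' worth of data on average:
n ≥ min_avg_cell · L(T) · L(X) · Π L(Z). The same arithmetic yields the
conditioning-size cap max-k = ⌊log₃(n / (5·2·3))⌋ for a binary phenotype
and ternary SNPs — 3 at n = 1366. An unreliable test yields *no decision*:
the caller may never conclude independence from it. This conservatism
prevents false eliminations in the boundary search. The average-count form
(rather than a per-cell minimum) is the only reading consistent with the
⌊log₃⌋ derivation.

### GLL-style induction

`gll_mb` is a semi-interleaved inclusion/elimination scheme:
candidates are the SNPs with a reliable, significant marginal G²
association (α = 0.05), admitted in ascending p-value order (ties broken
by chromosome, position); after each admission, every current member *x*
is tested against all subsets S of the other members with |S| ≤ max-k, in
increasing size and lexicographic order; the first reliable test declaring
x ⊥ T | S removes *x* permanently. The sweep repeats until stable before
the next admission. Elimination is single-pass (removed SNPs are not
readmitted), which bounds runtime; the false-positive control comes from
the many overlapping conditional tests each irrelevant SNP must survive.

Two asymmetric error modes follow from this design and are visible in the
tests. Under a global null with few candidates, a lone marginal false
positive has no companions to condition on and survives (the null test
asserts the empty boundary on a seed where no candidate passes). With deep
conditioning (|S| = 3 splits the sample into 27 strata), a genuinely causal
SNP occasionally meets one borderline test above α among the ~100 subsets
tried and is falsely eliminated; at n = 2000 and per-allele log-odds in
[0.5, 1.2] this costs about 5 % recall (the measured mean over 50 seeded
runs is ≈ 0.94 with ≈ 0 false positives).

### TIE* enumeration

`tie_star` finds every information-equivalent boundary: starting from the
reference boundary M₀ on the full SNP set, it withholds each non-empty
subset G of the union of discovered boundaries (|G| ≤
`max_equivalence_subset`, default 2; subsets in increasing size then
lexicographic order), re-runs the inducer, and accepts the result M_G iff
it is new and **subsumes** M₀: every x ∈ M₀ \ M_G must be rendered
conditionally independent of T by some subset of M_G (|S| ≤ max-k,
reliable). Accepted boundaries extend the union and hence the withheld
subset queue; the capped lattice is finite, so enumeration terminates.
The subset-size cap reflects that observed multiplicity arises from
single-SNP substitutions (e.g. one perfectly linked pair); the full lattice
is exponential. All orderings are specified, so the output is
deterministic for a fixed dataset and configuration.

Marginal tests are computed once per dataset and shared across all TIE*
re-runs through a memoized cache, which is what keeps enumeration at
hundreds of SNPs interactive.

## Prediction

Genotypes of the selected SNPs are encoded as minor-allele dosages 0/1/2,
missing calls imputed with the training-set per-SNP mode, and each column
centered and scaled by training statistics (sample standard deviation,
ddof = 1; constant columns get scale 1 to avoid division by zero). Test
data always reuse the stored training parameters.

Kernel ridge regression treats the 0/1 labels as reals and solves the dual
system (K + λI)c = y with K the RBF Gram matrix; a subject z scores
Σᵢ cᵢ K(z, xᵢ), and the continuous score is used for ranking/ROC. At λ = 0
with distinct rows the fit interpolates exactly; a singular system at λ = 0
raises an error advising λ > 0, while at λ > 0 an ill-conditioned solve
falls back to the least-squares (min-norm) solution. λ and γ are selected
by stratified 10-fold cross-validation maximizing mean fold AUC; ties
prefer the smaller γ then the larger λ, i.e. the smoother, more regularized
model. The λ grid spans {10⁻¹⁰, 10⁻⁸, …, 1}; the γ grid is
{2⁻³, …, 2³}/n with n the number of SNPs in the model, preserving the
scale-dependence of the kernel width on signature size.

## Evaluation

Stratified hold-out splits keep the case:control proportion, with the
per-stratum training count rounded half-up from the 2:1 fraction. AUC is
the Mann-Whitney statistic with ties counted ½. The DeLong interval is
AUC ± z·√(S₁₀/m + S₀₁/n) from the placement-value variances, truncated to
[0, 1]; its empirical coverage on binormal scores is verified at ~95 % in
the test suite. The robustness protocol repeats split → TIE* → fit →
held-out AUC over many random splits and reports the AUC distribution and
each SNP's selection frequency (membership in any boundary of the split);
failing splits are recorded with their index, never silently dropped.

## Audits

The missingness audit binarizes every call (1 = missing), G²-tests each
SNP's missingness indicator against the phenotype, controls the set at a
BH false-discovery rate, tests hypergeometric enrichment of significant
missingness inside a coordinate window, and trains the kernel-ridge
classifier on the binarized matrix over a stratified split. Random
missingness gives AUC ≈ 0.5; phenotype-dependent missingness is both
individually detectable and highly predictive. The locus window is a
configurable coordinate triple because locus membership rules are
dataset-specific; in synthetic runs it defaults to the planted NMAR
cluster's span.

The conditional-independence audit takes an externally supplied marker
list and, for each marker, searches subsets of a discovered boundary in
increasing size (≤ max_subset, default 4) for the first reliable test
declaring the marker independent of the phenotype. Markers absent from the
panel or already inside the boundary are reported with a note rather than
errored. Reported sets are genuinely minimal by construction (smaller
subsets were tested first); the test suite re-verifies minimality
exhaustively.

## The synthetic generator

The generator is the study-conditions stand-in for access-controlled cohort
data. Defaults: 1000 cases + 1000 controls, 500 SNPs, MAFs uniform on
[0.1, 0.5], LD blocks of 10 SNPs with copying probability 0.4, five causal
SNPs spread evenly with per-allele log-odds 1.2/0.9/0.8/0.65/0.5, intercept
−1, no missingness. These sizes mirror a mid-size candidate-region study
and give the conditional tests realistic power at max-k = 3.

Haplotypes are drawn by first-order copying within blocks: the first SNP
of a block is Bernoulli(MAF); each subsequent allele copies its left
neighbour with probability ρ, else is drawn fresh. This is the smallest
mechanism with tunable r² decay; it produces block-diagonal LD with
geometric decline, not the long-range or admixture-driven structure of
real populations. Two haplotypes sum to the dosage. The phenotype is
Bernoulli(logistic(β₀ + Σ βⱼgⱼ)); subjects are drawn in batches until the
case and control quotas fill (rejection sampling = case-control
ascertainment), with a bounded draw budget guarding degenerate
specifications. Duplicate columns are copied exactly (r² = 1), mirroring
deterministic complete LD; missingness is applied last, MCAR uniformly and
NMAR as extra missing probability in cases at listed SNPs.

Not emulated: population stratification and admixture, genotyping batch
effects beyond missingness, sex chromosomes, rare variants, and realistic
coalescent LD. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to
confounding in real cohorts.

## Problem sizes in the test and acceptance runs

The repeated-simulation checks run at sizes chosen to keep the whole suite
interactive while leaving the statistics well-powered: 50 seeded
discovery runs at 2000 × 500 for recall/false-positive rates; 100
robustness splits at 600 × 40; DeLong coverage over 500 replicates of
100 + 100 binormal scores; missingness audits at 800 × 150 with a 50-SNP
NMAR cluster at 15 % extra missingness. The acceptance script's synthetic
study uses 2000 × 100 with one duplicated causal SNP, which recovers the
two-boundary multiplicity structure reliably across seeds.

## Known limitations

- Interleaved elimination trades a few points of recall for near-zero
  false positives; a backtracking or symmetry-corrected variant would
  recover borderline members at higher cost.
- TIE* verification requires the substitute boundary to subsume the
  reference in a single shot; a borderline elimination inside a re-run can
  reject a genuinely equivalent boundary.
- The G² asymptotics degrade in sparse strata despite the reliability
  heuristic; no exact or permutation test is provided.
- The HWE filter uses the 1-df χ² goodness-of-fit, not the exact test, and
  defaults to controls only (standard practice; configurable to the pooled
  cohort).
- The dosage-table dialect carries no allele letters or coordinates;
  round-trips preserve calls, ids and phenotype but not allele metadata.
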