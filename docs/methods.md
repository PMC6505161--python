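# Methods

This document describes the statistical model, the simulation pipeline, the
default parameters and the numerical choices made in `bulkblup`. All
quantitative statements here are either exact mathematical consequences of
the model or values computed by the test suite / `scripts/acceptance.py`;
no claims about real data are made anywhere in this package.

## 1. Two-locus theory (`bulkblup.theory`)

### Population model

Two panels of fully homozygous lines ("male" and "female" heterotic groups)
are crossed at random. Attention is restricted to a single pair of biallelic
loci, A and B, with *gene-orthogonal* allele frequencies: the reference
allele frequency of locus A in the male group (`pA_m`), locus A in the
female group (`pA_f`), and likewise `pB_m`, `pB_f`, are free parameters, and
the four parental alleles of an F1 are drawn independently. Each F1 is
labelled by the origin state `(i, j, k, l)` where `i, j ∈ {1, 2}` are the
male- and female-derived alleles at locus A and `k, l` those at locus B
(1 = reference, 2 = alternate). The probability of a state is the product of
the four allele-frequency terms, giving 16 origin classes.

### Gene-action matrices

Genetic values are encoded as a 3×3 matrix `U` with `U[g_A, g_B]` the value
of genotype `(g_A, g_B)`, where `g = i + j − 2 ∈ {0, 1, 2}` counts alternate
alleles. Built-in patterns:

- **additive / dominance**: `U = b ⊕ c` (outer sum of per-locus vectors);
  per-locus vectors are `(0, a + d, 2a)` with `d = 0` for pure additivity.
- **additive × additive**: `z · [[2,1,0],[1,1,1],[0,1,2]]`.
- **duplicate factor**: all entries `z` except `U[2,2] = 0`.
- **complementary**: `z` in the top-left 2×2 block, 0 elsewhere.

Arbitrary matrices are accepted everywhere a pattern label is.

### F1 and F1:2 bulk values

The F1 value of origin class `(i, j, k, l)` is `U[i+j−2, k+l−2]`. The F1:2
bulk value is the expected genetic value of the selfed progeny of that F1,
obtained by exact enumeration of the 4×4 gamete table: the F1 produces the
two parental gametes `(i, k)` and `(j, l)` with probability `(1 − r)/2` each
and the two recombinant gametes with probability `r/2` each, where `r` is
the recombination rate between the loci (`r = 1/2` for unlinked loci). The
16 gamete pairs are accumulated into the nine genotypes and weighted by `U`.

Consequences that the test suite verifies exactly:

- A singly heterozygous F1 yields the Mendelian 1/4 : 1/2 : 1/4 mixture at
  the segregating locus.
- An unlinked doubly heterozygous F1 under duplicate-factor action has bulk
  value `15/16 · z` (only the 1/16 double-alternate-homozygote class drops
  out), whereas its own F1 value is `z`.
- Linkage (`r ≠ 1/2`) changes the bulk value only for doubly heterozygous
  F1s; additive and additive×additive matrices give bulk ≡ F1 value.

`f2_origin_genotype_frequencies` returns the full origin-labelled F2
distribution. For a doubly heterozygous, unlinked F1 all 16 origin classes
have probability 1/16; when the F1 is homozygous at a locus, classes that
collapse to the same origin state are merged, so only the total probability
(always 1) is comparable across F1 classes.

### Variance decomposition and summary statistics

Over the 16-class distribution, `population_summary` computes for both the
F1 values and the bulk values: the mean, the total variance, and the
orthogonal decomposition into male GCA variance (variance of the
male-gamete conditional means), female GCA variance, and SCA variance
(remainder). Derived quantities:

- `psca = var_SCA / var_total`, the SCA share;
- `cor_hybrids`: correlation between F1 and bulk values across the 16
  classes (the ceiling on cross-generation predictive accuracy at the QTL
  level);
- `cor_gca_m`, `cor_gca_f`, `cor_gca_avg`: correlations between F1-based
  and bulk-based GCA effects per group, and their average.

Correlations are reported as NaN whenever either variance is zero (e.g.
fixed loci, pure-additive SCA, degenerate frequencies); downstream grid
summaries use NaN-aware minima.

`frequencies_from_divergence(dA, dB)` places the two groups symmetrically
around 1/2: `p_m = (1 + d)/2`, `p_f = (1 − d)/2` at each locus. Grid scans
sweep divergence over `0, 0.02, …, 0.98` (endpoints below 1 to avoid fixed
loci) and, for the dominance model, the degree of dominance `d/a` over
`0.05, …, 3.0`.

Key exact/derived results recomputed by `scripts/acceptance.py`:

- Under pure dominance, the minimum of the average GCA correlation between
  generations over the divergence × degree-of-dominance grid is 0 at double
  precision (F1 and bulk GCA effects can be completely uncorrelated).
- Under duplicate-factor action with equal divergence in both groups, the
  minimum F1/bulk correlation over the divergence grid is ≈ 0.32.

## 2. Simulated breeding program

### Founders (`bulkblup.founders`)

A genetic map of `n_chrom` chromosomes (default 10 × 160 cM) carries
`n_loci` marker/QTL positions placed uniformly at random. Each locus is
assigned a pair of group allele frequencies from a divergence profile:
by default 35 % of loci "divergent" (frequencies pushed toward opposite
fixation in the two groups), 35 % "convergent" (similar, intermediate
frequencies), and the rest intermediate. Founder lines are fully homozygous;
genotypes are coded 0/2 copies of the reference allele. Panels are written
and read as plain TSV (lines × markers, plus a map table).

### Meiosis and DH families (`bulkblup.meiosis`)

Gametes are simulated under the Haldane model: per chromosome, the number
of crossovers is Poisson with mean = map length in Morgans, positions are
uniform, and the recombination rate between two positions `d` Morgans apart
is `r = (1 − e^(−2d))/2` (verified against simulation at 10–120 cM).
Doubled-haploid (DH) lines are single gametes doubled to homozygosity.

Within each group, founder lines receive importance weights mimicking an
elite breeding pool: 5 lines share weight 0.1 each, 20 share 0.0125 each,
and the remaining lines split 0.25 equally. Biparental families are drawn
with probability proportional to the product of parental weights (no selfs,
no duplicate pairs); each family contributes `n_dh_per_family` DH lines.

### Trait architecture (`bulkblup.architecture`)

The trait is the sum of `n_qtl_pairs` two-locus blocks (default 100). QTL
are selected from the simulated loci subject to a minor-allele-frequency
floor and, per population-structure scenario, a divergence constraint
("convergent" scenario: both-group divergence ≤ 0.05; "divergent":
≥ 0.60). Pairs are assigned gene action with probabilities: additive 0.05,
additive×additive 0.05, dominance 0.10, duplicate 0.40, complementary 0.40.

Effect sizes are sampled so that (verified at the stated sample sizes by
acceptance tests):

- homozygous effects `a ~ N(0, (0.25 √(π/2))²)`, giving `E|a| = 0.25`;
- dominance deviations `d ~ N(|a|, (0.78 |a|)²)`, giving ≈ 90 % positive
  (directional) dominance and mean degree of dominance 1;
- epistatic scales `z` with `E|z| = 0.25` (additive×additive) or `E|z| = 1`
  (duplicate, complementary).

Each 3×3 block additionally receives i.i.d. normal "pattern noise" with
standard deviation equal to 1/10 of the mean absolute entry, so no block is
a perfectly textbook pattern. True F1 values are computed from the QTL
genotypes; true bulk values either by exact per-pair enumeration using the
Haldane `r` between the two QTL (mode `"exact"`), or by simulating `n_f2`
selfed progeny per hybrid through the meiosis engine (mode `"simulate"`,
which matches the exact mode within Monte-Carlo error in tests).

### Training sets (`bulkblup.training`)

`n_training_families` male families are paired one-to-one with as many
female families; every DH line of a tested family pair is crossed to every
line of its partner family, giving the tested hybrids. Phenotypes are true
genetic values plus i.i.d. normal noise under two scenarios:

- **calibrated** (constant heritability): the residual variance is set from
  the realized genetic variance of the training generation so that
  `h² = 0.5` for both F1 and bulk training;
- **constant_residual**: the residual variance calibrated on the F1s is
  reused unchanged for the bulks, so bulk heritability is lower whenever
  bulks have less genetic variance — the agronomically realistic comparison.

### Genomic model (`bulkblup.model`)

Group-wise additive relationship matrices use centred, frequency-scaled
marker codes `w = (x − 2p)/√(4 p (1 − p))` and `A = W W′ / M`; with
homozygous 0/2 codes and sample frequencies the mean diagonal is exactly 1.
Monomorphic markers are excluded with a logged warning. A random subset of
`n_kernel_markers` loci (QTL not excluded, mimicking an anonymous SNP chip)
feeds the kernels.

Hybrid covariance is modelled with eight kernels built from the parental
matrices `A_m`, `A_f` by Hadamard products: male GCA (`alpha_m`) and male
additive×additive (`aa_m = A_m ∘ A_m`), the female analogues, and four
SCA-type kernels (`delta = A_m ∘ A_f`, `ad_m = aa_m ∘ A_f`,
`ad_f = A_m ∘ aa_f`, `dd = aa_m ∘ aa_f`). Each kernel is rescaled by its
mean diagonal so variance components are on a common per-hybrid scale.

Variance components are estimated by Gibbs sampling. Each kernel is
eigendecomposed once (`K = U D U′`), the corresponding random effect is
parameterized in the whitened basis `Φ = U √D`, and scalar effects are
updated singly with two matrix–vector products per kernel sweep. Variances
have scaled-inverse-χ² priors with 5 degrees of freedom and scale chosen to
split half the phenotypic variance equally across the genetic terms
(prior `R² = 0.5`). The default desk chain is 10 000 iterations (5 000
burn-in, thinning 10); the full-scale preset is 100 000 / 50 000 / 50. The
sampler is validated against (i) analytic recovery of known variances
within posterior uncertainty and (ii) a direct REML oracle (profiled
restricted likelihood optimized over the variance ratio) on single-kernel
problems.

Prediction uses the posterior-mean variance components in the standard
mixed-model BLUP `ĝ_P = C_PT V_TT⁻¹ (y − μ)`, where `C_PT` sums the
selected cross-kernels — all eight for total hybrid performance, the
male/female GCA pairs (`alpha + aa`) for GCA, and the four SCA-type terms
for SCA. Component BLUPs sum exactly to the total BLUP.

### Accuracy reporting (`bulkblup.runner`)

Predicted hybrids are classed by parental testing status: T3 (both parents
tested, combination tested), T2 (both tested, new combination), T1 (one
parent tested), T0 (neither). Hybrid and SCA accuracies are correlations
between predictions and true F1 values within class. GCA accuracy is
reported for tested and untested lines, both "within-family" (correlation
computed inside each family and averaged over families, removing the
family-mean signal) and "across" (plain correlation over all lines of the
category).

Each replicate runs: founder sampling → DH families → QTL architecture →
truth tables → three training sets (F1; bulks at constant residual; bulks
at constant heritability) → model fit and prediction per training set.
Replicates are summarized into three tables: genetic parameters
(`table1`), GCA accuracy (`table2`), and hybrid/SCA accuracy by T-class
(`table3`).

## 3. Default parameters

| Parameter | desk preset | full-scale preset |
|---|---|---|
| loci | 2 000 | 15 000 |
| kernel markers | 1 000 | 5 000 |
| QTL (forming two-locus pairs) | 200 | 200 |
| DH families × lines (per group) | 20 × 10 | 40 × 25 |
| tested family pairs | 10 | 20 |
| F2 progeny per bulk (simulate mode) | 100 | 100 |
| Gibbs chain (length/burn-in/thin) | 10 000 / 5 000 / 10 | 100 000 / 50 000 / 50 |

The desk preset keeps a full replicate near 25 s on one CPU so that
replicated experiments fit in a test run; the full-scale preset reproduces
the dimensions of a realistic maize-style study but is not executed by the
test suite.

## 4. Numerical choices

- **Seeding.** All stochastic stages derive independent streams from
  `numpy.random.SeedSequence` with stage-indexed spawn keys; replicate
  seeds are masked to 31 bits. Replicates and whole experiments are exactly
  reproducible from a single master seed (covered by tests).
- **Kernel normalization** by the mean diagonal rather than trace/n of the
  raw Hadamard product keeps all variance components interpretable on the
  same scale.
- **Eigenbasis Gibbs updates** avoid per-iteration Cholesky solves; the
  inner loop is compiled with numba.
- **Zero-variance handling.** Correlations involving a zero-variance vector
  return NaN rather than raising or returning 0; grid minima are NaN-aware.
- **Exact vs simulated bulks.** Exact two-locus enumeration is the default
  truth for bulk values; the simulation mode exists to validate it and to
  model finite-bulk sampling noise when wanted.
- **Standardization.** Phenotypes are centred and scaled before model
  fitting; accuracies are scale-free correlations, so this is harmless and
  stabilizes the priors.

## 5. Scope and limitations

- **All data are synthetic.** Founder panels, maps and traits are generated
  by the package itself; no real genotypes or phenotypes are included, and
  nothing here estimates parameters of any real crop.
- **Two-locus architecture.** Epistasis is confined to disjoint QTL pairs;
  higher-order interactions and linkage between blocks beyond what the
  shared map induces are not modelled.
- **Desk scale vs full scale.** All executed experiments use the desk
  preset. The qualitative orderings checked by the test suite (bulk
  variance loss, accuracy decay T3→T0, divergence sensitivity of
  bulk-training penalties) hold at that scale with 20 replicates per
  structure; full-scale magnitudes are not asserted anywhere.
- **Model scope.** The genomic model assumes homozygous parents, a single
  trait, i.i.d. residuals and no genotype×environment structure; GCA/SCA
  kernels are derived from additive relationship matrices only.
- **F1:2 bulk phenotype = expected progeny value.** Bulk phenotypes are the
  per-hybrid expected selfed-progeny value plus residual noise; competition
  and plot-level sampling effects within a bulk plot are summarized into
  the residual term.
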