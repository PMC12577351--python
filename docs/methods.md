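# Methods

`rumenblup` quantifies and predicts the contributions of host genetics,
the rumen metagenome, and their interaction to feed-efficiency traits
(average daily dry-matter intake, ADDMI, and average daily gain, ADG)
in beef cattle, using kernel-based univariate mixed models. This note
documents the models, the synthetic-data generator used to exercise
them, and the numerical choices.

## Models

All models are univariate animal models over n animals:

    y = Xβ + Zu + Wm + To + e

with fixed effects β (intercept, management group, breed fractions,
expected heterozygosity) and up to three random effects:

* **u** ~ N(0, G_T σ²_u): host genomic effect with G the VanRaden
  method-1 GRM, G = (Q−P)(Q−P)′ / (2 Σ p_i(1−p_i)), built from
  alternate-allele dosages Q and observed frequencies p_i.
* **m** ~ N(0, M_T σ²_m): metagenome effect with M one of six
  metagenome relationship matrices (MRMs, below).
* **o** ~ N(0, J_T σ²_o): genome-by-metagenome interaction, J = G ∘ M
  (Hadamard product of the untuned kernels; PSD by the Schur product
  theorem). Included only when both u and m are in the model.

The subscript T denotes *tuning*: K_T = K + 0.001 I, which guarantees
invertibility. Model complexities are genomic-only, metagenomic-only,
joint, and interaction; crossing the two MRM construction methods with
three adjustments gives 1 + 6 + 6 + 6 = 19 models per trait.

### MRM construction

All MRMs start from the log relative abundance matrix

    S_ij = log10( (R_ij + 1) / Σ_j (R_ij + 1) )

of the ORF read-count table R (unit pseudocount; per row, 10^S sums to
one, so uneven sequencing depth is absorbed).

* **Method 1** (GRM analogue): M1 = (S−N)(S−N)′ / Σ_j var(s_j), with N
  the column-mean matrix. Rows sum to zero; trace(M1) = n−1 under the
  sample-variance convention.
* **Method 2** (column-standardized): C_ij = (S_ij − mean_j)/sd_j and
  M2 = CC′/m. trace(M2) = n−1 exactly; M1 = M2 when all column
  variances are equal.
* **Weighted adjustment**: D = diag(1 − h²_ORF) inserted in either
  cross-product (M1W = (S−N)D(S−N)′/Σ var; M2W = CDC′/m), down-
  weighting ORFs whose abundance is itself heritable so the metagenome
  effect absorbs less host-genetic signal. The per-ORF heritabilities
  are estimated from the data (below) and treated as known; estimates
  are clamped to [0, 1] before forming 1 − h².
* **Data-driven adjustment**: animals are clustered (k = 2) by k-means
  on the first 4 principal components of S, then each cluster is
  centered/scaled by its own statistics. Method-1 cross-cluster blocks
  are divided by the geometric mean of the two clusters' variance sums;
  method-2 blocks are C_a C_b′/m with per-cluster standardization. A
  single cluster reduces exactly to the single-population MRM. The
  weighted and data-driven adjustments are not combined (the design has
  six MRMs, not eight).

### Variance components, ratios, and model fit

Variance components are estimated by REML. The ratios reported are
h² = σ²_u/Σ, m² = σ²_m/Σ, i_a² = (σ²_u+σ²_m)/Σ and
i_i² = (σ²_u+σ²_m+σ²_o)/Σ, where Σ is the sum of **all** components in
the model including σ²_e. Ratio standard errors use the first-order
delta method on the inverse average-information matrix. AIC is
−2 logL_REML + 2·(number of variance components); components that
converge to the zero boundary stay in the count and are flagged. AIC
values are comparable only within a dataset (the likelihood constant is
omitted).

### REML algorithm

Average-information (AI) REML: at each iteration the clipped AI step
and the expectation-style multiplicative step are both evaluated and
the better one taken, with step-halving toward the current point on a
likelihood decrease — the iteration is therefore monotone. Components
are constrained non-negative; a component at 0 may re-enter if its
score turns positive. Convergence requires either a negligible
likelihood change with stable components, or three consecutive
negligible changes (flat-ridge case). If the AI iteration has not
converged after 30 steps — typical of interaction models whose kernel
is strongly collinear with G and M — the fit is finished by bounded
L-BFGS-B on the exact restricted score. Tolerances: relative logL
change < 1e−8, component change < 1e−6 (relative to var(y)); max 200
iterations overall. Correctness is checked in the tests against (a) an
independent error-contrast density oracle and (b) a dense grid over
variance-fraction directions with the overall scale profiled out in
closed form.

Fits with a single kernel for many phenotypes (the per-ORF h² sweep)
use an eigendecomposition of G_T: rotating y and X onto the eigenbasis
makes the covariance diagonal, and the restricted likelihood is
profiled down to a one-dimensional search over the variance fraction
φ = σ²_u/(σ²_u+σ²_e). One rotation serves all ORFs, so the sweep is
O(n p²) per ORF. The eigen path and the AI path agree to ~1e−3 in h²
on the same data (tested).

### BLUP and prediction

Mixed-model solutions use only phenotyped (training) records but return
effects for every animal in the kernels:
û_k = σ²_k K_k[:, train] V⁻¹ (y − Xβ̂). Total animal merit (TAM) is the
sum of the fitted random-effect solutions per animal. Accuracy is the
Pearson correlation between TAM (or each individual solution — EBV,
EMV, EIV) and the adjusted phenotype y_adj = y − Xβ̂ in the test set;
RMSE is computed between TAM and y_adj; dispersion is the slope of the
OLS regression (with intercept) of y_adj on TAM, 1 being perfectly
calibrated. A constant TAM (all components at the zero boundary)
carries no ranking information and is recorded as accuracy 0; its
dispersion is undefined (NaN).

Two cross-validation schemes: **fourfold** (random allocation
stratified by sex so each fold is balanced for diet type, 5 replicates
→ 20 results per model; replicate r is seeded with seed + r) and
**leave-one-diet-out** (train on three diets, test on the fourth → 4
results). Variance components are re-estimated per fold on training
records; kernels are built once on all animals, as relationship
matrices are conventionally shared across CV folds. β̂ for y_adj comes
by default from a full-data fit of the same model, because under LODO
the test diet's management groups are unestimable from training
(management groups are nested in diets); a `beta_source="train"` option
exists for the fourfold scheme and raises an explicit error when a test
level is absent from training. Non-converged folds are excluded from
medians and counted.

## Data filters

* Genotypes: missing dosages imputed by the column mean (2p̂_i), then
  SNPs kept when minor allele frequency > 0.05 (strict).
* ORFs: removed only when prevalence < 10% **and** maximum within-
  sample relative abundance < 0.01% — surviving on either criterion
  (the removal clause is the conjunction of the two deficiencies; an
  `orf_filter_logic="or"` option gives the stricter reading).
* Phenotypes: an animal is removed when any trait lies more than 3
  within-diet SDs from the diet mean; statistics are computed once on
  the original table (single pass, no iteration). Zero-variance groups
  keep all animals.

All filters are idempotent, and the three tables stay aligned on one
ordered animal list.

## Synthetic-data generator

The generator emulates the study's structure so every stage is testable
with known ground truth. Defaults: 704 animals in 16 management groups
nested in 4 diets of 2 diet types (steers on concentrate, heifers on
forage — sex is a diet-type proxy); SNP dosages Binomial(2, p) under
HWE with p ~ U(0.05, 0.5); 18 breed fractions from a symmetric
Dirichlet(0.5); heterozygosity U(0.25, 0.40); management-group effects
from a wide normal (SD 1) so β̂ estimation is non-trivial.

ORF log10 abundances are built as baseline + diet-type shift + genetic
component + noise: per-ORF heritabilities follow Beta(0.605, 8.04)
(mean 0.07, median 0.04, ~75% below 0.10 — most ORFs weakly heritable);
half the ORFs get a ±0.5 log10 diet-type shift; the genetic scores are
correlated across animals through the realized GRM. Counts are
multinomial per animal with log-normal library sizes (CV ≈ 0.4) around
100k reads, so row sums equal library sizes exactly. SNP and ORF counts
default to the low thousands — large enough for stable kernels, small
enough for desk-scale replication; the acceptance checks use n = 600
animals × 1000 ORFs × 2000 SNPs with 20 replicate seeds.

Phenotypes are y = Xβ + u + m + o + e with u ~ N(0, G σ²_u); m a
random weighted sum of centered S columns, which has exactly the
method-1 MRM covariance; o ~ N(0, (G∘M) σ²_o); e iid. Scales are set
from the mean kernel diagonals so the expected variance fractions equal
the targets (total variance 1). The metagenomic and interaction
components are projected onto the orthogonal complement of the
fixed-effect design before scaling: the diet-type shift in S is
collinear with the management groups (nested in diets), so without the
projection part of the targeted microbiability would be absorbed by
the fixed effects and would be invisible to any estimator. In the
error-contrast space REML works in, the projected component retains
exactly the M1 covariance, so the generator's m² target is the
identifiable microbiability.

What the generator does **not** emulate: ORF-ORF covariance beyond
diet and host effects (ORFs are conditionally independent given both),
read-level sequencing error, pedigree structure, temporal microbiome
drift, and genotype-microbiome confounding through breed. Passing
tests therefore demonstrate correctness of the estimation machinery
under the assumed model, not robustness to those real-data features.

## Numerical conventions and edge cases

* Sample (n−1) variance convention throughout kernel construction
  (`ddof` switch for the population convention); this makes
  trace(M1) = trace(M2) = n−1 exact.
* PSD tolerance for untuned kernels: smallest eigenvalue ≥
  −1e−8·trace/n.
* Tuning refuses to run twice (stacked diagonals would silently change
  the model); the Hadamard interaction refuses tuned inputs.
* Method-2 MRMs raise on zero-variance ORF columns (cannot
  standardize); method 1 tolerates them.
* A single random effect with an identity kernel is flagged
  unidentifiable (only σ²_u + σ²_e is determined).
* The REML residual variance is floored at 1e−10·var(y) to keep V
  invertible; boundary components are reported by name.
* Seeds: a single study seed fans out to design, genotypes, microbiome
  and per-trait phenotype stages via `numpy` SeedSequence spawning;
  fourfold replicate r uses seed + r; all outputs are bit-reproducible
  under a fixed seed.

## Known limitations

* AIC absolute values depend on the omitted likelihood constant; only
  within-dataset comparisons are meaningful.
* Interaction models can push the residual to the boundary and absorb
  variance into σ²_o (their kernel is collinear with G and M); the
  i_i² estimates are correspondingly unstable, with large SEs.
* The per-ORF h² sweep assumes the same fixed-effect design as the
  trait models.
* No multivariate models, no Bayesian samplers, no pedigree A-matrix,
  no sparse kernel approximations.
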