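# rumenblup

Joint host-genomic and rumen-metagenomic prediction of feed-efficiency
traits in beef cattle, as a tested analysis pipeline.

Feed efficiency and its component traits — average daily dry-matter
intake (ADDMI) and average daily gain (ADG) — are shaped both by the
host's genetics and by the rumen microbial community that ferments its
feed. This package asks how much trait variation each source explains
and how well phenotypes can be predicted from either or both, using
kernel-based univariate mixed models:

    y = Xβ + Zu + Wm + To + e
    u ~ N(0, G_T σ²_u),  m ~ N(0, M_T σ²_m),  o ~ N(0, J_T σ²_o)

where **G** is a VanRaden method-1 genomic relationship matrix from SNP
dosages, **M** is one of six metagenome relationship matrices (MRMs)
built from ORF log10 relative abundances (two construction methods ×
naive / weighted / data-driven adjustments), **J = G ∘ M** is the
Hadamard interaction kernel, and the subscript T denotes tuning with
+0.001·I for invertibility. Variance components are estimated by
AI-REML; reported ratios are the heritability h² = σ²_u/Σ, the
microbiability m² = σ²_m/Σ, and the combined fractions i_a² and i_i²
(Σ = all components including the residual). Prediction is scored by
two cross-validation schemes — fourfold stratified by sex (5
replicates, 20 results per model) and leave-one-diet-out — via the
correlation between each test animal's summed random-effect solutions
(total animal merit, TAM) and its adjusted phenotype y_adj = y − Xβ̂,
plus RMSE and a dispersion (calibration) slope.

Because the original animals' genotypes are not redistributable, the
package ships a synthetic-data generator that emulates the study
design (~700 animals, 16 management groups nested in 4 diets of 2 diet
types, weakly heritable ORF abundances with a strong diet-type
compositional shift, configurable variance fractions with known ground
truth), so the whole pipeline is testable end to end. See
`docs/methods.md` for the full model and generator description.

## Worked example

The numbered drivers under `analysis/` run the study end to end on
synthetic data and write their tables under `results/`:

```bash
python analysis/01_simulate_study.py
python analysis/02_filter_inputs.py
python analysis/03_build_kernels.py
python analysis/04_fit_model_grid.py
python analysis/05_cross_validate.py
```

The first three stages print:

```
wrote 704 animals x 1500 SNPs x 800 ORFs to results/data
realized variance fractions (ADDMI): h2=0.309 m2=0.207 i2=0.000
removed 2 animals (3-SD within diet), 10 SNPs (MAF), 25 ORFs (prevalence/abundance)
702 animals remain for analysis
wrote 13 kernels (6 MRM, 6 interaction) to results/kernels
trace(M1)=701.000000 trace(M2)=701.000000 (n-1=701)
max |row sum| G=1.18e-14 M1=7.42e-14
```

i.e. the generator hit its variance-fraction targets (0.30/0.20), the
filters removed 2 outlier animals, 10 low-MAF SNPs and 25 rare ORFs,
and the kernels satisfy their exact identities (trace n−1, zero row
sums). Stage 04 then fits the 19-model grid per trait; excerpt of the
parameter table for ADDMI (truth: h² = 0.30, m² = 0.20 plus the
diet-collinear share absorbed by management group):

```
trait  complexity  method  adjustment    h2  h2_se    m2  m2_se  i_a2     AIC
ADDMI     genomic     NaN        None 0.296  0.082   NaN    NaN   NaN 686.598
ADDMI metagenomic     1.0       naive   NaN    NaN 0.266  0.067   NaN 682.884
ADDMI       joint     1.0       naive 0.279  0.075 0.283  0.066 0.562 670.280
```

The genomic-only model recovers h² ≈ 0.30; joint models capture both
sources (i_a² ≈ 0.55); metagenomic-only models absorb some genetic
signal into m², exactly the behavior the weighted adjustment is meant
to curb. Stage 05 cross-validates the naive-adjustment models under
both schemes and summarizes median ± SD accuracy, RMSE and dispersion
per model; excerpt:

```
                     model   scheme  accuracy_TAM_median  dispersion_median  n_folds
             ADDMI:genomic fourfold                0.172              1.147       20
ADDMI:metagenomic:M1:naive fourfold                0.223              0.938       20
      ADDMI:joint:M1:naive fourfold                0.293              1.011       20
ADDMI:interaction:M1:naive fourfold                0.287              1.016       20
      ADDMI:joint:M1:naive     lodo                0.236              0.770        4
```

Models combining genome and metagenome out-predict either source alone,
leave-one-diet-out is harder than the random fourfold split, and
multi-effect models are better calibrated (dispersion near 1).

The same pipeline is scriptable from one YAML config through the CLI
(`rumenblup simulate | filter | kernels | fit | validate | run-all`).

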