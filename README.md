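# bimr — one-sample bidirectional Mendelian randomization

`bimr` estimates the two directed causal effects between a pair of continuous
phenotypes from individual-level genotype/phenotype data. It is aimed at
statistical geneticists and epidemiologists analysing traits that plausibly
affect *each other* — obesity and glycaemic traits, inflammation and sleep,
depression and pain — where applying ordinary unidirectional Mendelian
randomization (MR) separately in each direction is biased by the feedback
loop that mutual causation creates.

## The model

Let Y₁, Y₂ be two phenotypes, X₁ (n×k₁) and X₂ (n×k₂) their SNP dosage
instrument sets, and C an unmeasured confounder. The structural system is

    Y₁ = β₀₁ + X₁β₁₁ + β_CY₁ C + γ₂₁ Y₂ + ε₁
    Y₂ = β₀₂ + X₂β₂₂ + β_CY₂ C + γ₁₂ Y₁ + ε₂

γ₁₂ and γ₂₁ are the two directed causal effects. When |γ₁₂γ₂₁| < 1 the
feedback loop converges to a reduced form in which each trait loads on *both*
instrument sets, every coefficient carrying the common factor 1/(1−γ₁₂γ₂₁).

Four estimators are provided, each in both directions:

| method    | idea |
|-----------|------|
| `ratio`   | naive per-instrument IVW ratio (marginal regressions), feedback ignored |
| `biratio` | IVW ratio with every regression adjusted for the *opposite* instrument set, so the feedback factor cancels |
| `liml`    | naive limited-information maximum likelihood (k-class, k̂ = smallest eigenvalue of the projected cross-product pencil) |
| `biliml`  | LIML with the opposite instrument set carried as included exogenous columns — the recommended estimator, robust to many weak instruments |

A seeded simulation engine generates cohorts under the unidirectional or
bidirectional model (Hardy–Weinberg genotypes, Normal confounder and errors),
and a benchmark harness summarizes estimator accuracy across replicates as
the median estimate, median absolute bias (MAB = median|γ̂ − γ|) and relative
MAB (RMAB = MAB/|γ|, undefined at γ = 0).

## Worked example

Simulate a bidirectional cohort (n = 1000, 5 strong instruments per trait,
γ₁₂ = −1.9, γ₂₁ = 0.5) and estimate both effects with all four methods:

```sh
bimr simulate --kind bmr --n 1000 --k1 5 --k2 5 --beta1 2 --beta2 2 \
    --gamma12 -1.9 --gamma21 0.5 --seed 7 --out demo --prefix demo
bimr estimate --phenotypes demo/demo.phenotypes.tsv \
    --dosages1 demo/demo.dosages1.tsv --dosages2 demo/demo.dosages2.tsv \
    --method all
```

```text
method   direction   var_explained   mean_F               estimate (95% CI)          p
ratio    1->2              68.81%   154.17      -1.9242 (-2.0595--1.7889)  5.92e-171
ratio    2->1              21.44%    46.29       0.4700 (0.4025-0.5375)   2.04e-42
biratio  1->2              68.81%   154.17      -1.8956 (-2.0126--1.7786)  2.28e-221
biratio  2->1              21.44%    46.29       0.4985 (0.4616-0.5354)  2.07e-154
liml     1->2              68.81%   154.17      -1.9230 (-2.0576--1.7884)  4.66e-128
liml     2->1              21.44%    46.29       0.4731 (0.3547-0.5914)   1.12e-14
biliml   1->2              68.81%   154.17      -1.8955 (-1.9404--1.8505)  4.94e-324
biliml   2->1              21.44%    46.29       0.4980 (0.4552-0.5408)   4.26e-93
```

The feedback-aware estimators land on the truth (−1.9, 0.5) while the naive
reverse-direction estimates are attenuated (0.470/0.473 vs 0.50): the
trait-1 instruments leak into trait 2 through the loop and contaminate the
naive regressions. `var_explained` is the incremental R² of the exposure on
its own instrument set; `mean_F` the mean first-stage F (values below 10
flag weak instruments).

The same pattern across 200 replicates, via the benchmark harness:

```sh
bimr benchmark --scenario grid.yaml --seed 1   # one strong-20-IV cell
```

```text
scenario                   truth    F-stat   ratio med    MAB   RMAB biratio med    MAB   RMAB    liml med    MAB   RMAB  biliml med    MAB   RMAB
Strong IVs (20) ... g12   -1.90     41.32       -1.88   0.04     2%       -1.90   0.01     0%       -1.90   0.04     2%       -1.90   0.01     0%
Strong IVs (20) ... g21    0.50     11.76        0.43   0.07    14%        0.50   0.01     2%        0.50   0.04     9%        0.50   0.01     2%
```

The full study grids ship as packaged configs:
`bimr benchmark --scenario scenario2 --out results/` (likewise `scenario1`,
`scenario3`).

For real data, `bimr.read_cohort` ingests tab-delimited phenotype/dosage
tables (realigned by sample id) and `bimr.read_vcf_dosages` pulls dosages
from a VCF (GT allele counts, or the DS field when present); supply observed
covariates (age, sex, principal components) via `--covariate-columns`.

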