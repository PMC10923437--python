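# Methods

## Structural model and reduced form

Two continuous phenotypes are linked by a simultaneous linear system with
genetic instruments X₁ (affecting only trait 1 directly), X₂ (only trait 2),
an unmeasured confounder C loading on both, and independent Normal structural
errors:

    Y₁ = β₀₁ + X₁β₁₁ + β_CY₁ C + γ₂₁ Y₂ + ε₁
    Y₂ = β₀₂ + X₂β₂₂ + β_CY₂ C + γ₁₂ Y₁ + ε₂

Mutual causation makes this a feedback loop. Substituting each equation into
the other generates a geometric series with ratio γ₁₂γ₂₁; when |γ₁₂γ₂₁| < 1
it converges, and solving the 2×2 system gives the reduced form with
d = 1 − γ₁₂γ₂₁:

    Y₁ = (β₀₁+γ₂₁β₀₂)/d + (β_CY₁+γ₂₁β_CY₂)/d · C + X₁β₁₁/d + X₂γ₂₁β₂₂/d + δ₁
    Y₂ = (β₀₂+γ₁₂β₀₁)/d + (β_CY₂+γ₁₂β_CY₁)/d · C + X₁γ₁₂β₁₁/d + X₂β₂₂/d + δ₂

with composite errors δ₁ = (ε₁+γ₂₁ε₂)/d, δ₂ = (ε₂+γ₁₂ε₁)/d, whose SDs and
correlation `reduced_form` returns in closed form. Two consequences drive
everything else: each trait loads on *both* instrument sets (so the opposite
set is an omitted variable for any naive per-instrument regression), and
every coefficient carries the common factor 1/d. At |γ₁₂γ₂₁| = 1 the series
diverges; we reject that boundary rather than define behaviour there.

The assumptions are the standard instrumental-variable triple per instrument
(associated with its own trait, independent of C, no direct path to the other
trait), plus linearity, continuous outcomes, one sample, and no horizontal
pleiotropy, LD between instruments, or population structure.

## Estimators

**Ratio family.** The per-instrument ratio estimate of γ₁₂ is
(coefficient of Y₂ on X₁ᵢ) / (coefficient of Y₁ on X₁ᵢ); multiple instruments
are combined by fixed-effect inverse-variance weighting with weights
den²ᵢ/var(numᵢ), i.e. first-order delta-method weights from the numerator
variance only. The naive estimator uses marginal simple regressions; BiRatio
adjusts every regression for the complete opposite instrument set (and any
covariates), which cancels the 1/d factor from numerator and denominator and
restores consistency under feedback. Within-direction instruments are always
fitted marginally, one at a time, matching the per-instrument IVW form;
computationally all k marginal fits share one residualization against the
adjustment block (Frisch–Waugh–Lovell), so BiRatio costs one thin QR per
direction. Wald 95% CIs and two-sided normal p-values, the summary-MR
convention for IVW. A denominator coefficient below 1e-8 in magnitude raises
an error (an irrelevant instrument would otherwise produce silent sign
flips); an exactly-fitting (noiseless) regression has its zero sampling
variance floored at 1e-30 so the noiseless limit of the weights stays
defined.

**LIML family.** Per direction, the exposure phenotype is an endogenous
regressor. With W the full instrument design, C* the design without the
excluded (own) instruments, and M_A the annihilator of A, the LIML k̂ is the
smallest eigenvalue of the pencil (YᵀM_{C*}Y, YᵀM_W Y), Y = [exposure,
outcome] — the minimizer of the classical variance-ratio objective, always
≥ 1 because span(C*) ⊂ span(W), and exactly 1 in the just-identified case
(where LIML, 2SLS and the ratio estimator coincide; tested). The k-class
solve is β̂ = (Xᵀ(I−k̂M_W)X)⁻¹Xᵀ(I−k̂M_W)y with structural design
X = [1, covariates, included instruments, exposure]. Naive LIML omits the
opposite set from W and X entirely; BiLIML carries it as included exogenous
columns — the only difference, and the whole feedback correction.
Annihilators are applied through thin-QR bases (`v − Q(Qᵀv)`), never as
explicit n×n matrices; both directions of BiLIML share one basis since their
full designs span the same space. SEs use the k-class asymptotic covariance
σ̂²(Xᵀ(I−k̂M_W)X)⁻¹ with σ̂² from structural residuals over n − p, and
t-quantile CIs/p-values with df = n − p. The likelihood itself is never
evaluated; the eigenvalue solution subsumes it. A direction with zero
excluded instruments is rejected as unidentified.

Degenerate inputs: with exactly zero noise both phenotypes lie in the
instrument span, YᵀM_W Y is singular, and LIML raises `SingularityError`
rather than returning an arbitrary answer; the exactness of the closed-form
solve is instead verified at k = 1 (2SLS) and at vanishing noise (sd 1e-6).

## Simulation engine

Cohort defaults are the study conditions: n = 1000; MAF 0.3 with dosages
Binomial(2, maf) (Hardy–Weinberg); confounder Normal(1, 1) with effect 0.3
on both traits; intercepts 1; unit-SD structural errors; per-instrument
effects 1 (one strong IV), 2 (5–20 strong IVs), 0.02 (up to 20 weak IVs) or
0.05 (100 weak IVs). Bidirectional cohorts are drawn directly from the
reduced form; `fixed_point_oracle` iterates the raw structural equations
(Gauss–Seidel from zero, error contracting by |γ₁₂γ₂₁| per pass) and agrees
with the closed form to 1e-8 on shared noise draws — the engine's central
correctness property. Draw order is fixed so a bidirectional run with
γ₂₁ = 0 reproduces the unidirectional run bit-for-bit at the same seed.
Replicate r of a benchmark uses seed base+r, making every cell reproducible
and every replicate independently addressable.

The generator emulates the structure of a real two-trait cohort (e.g. BMI
and fasting glucose with per-trait SNP sets and covariates) but not LD
between instruments, population structure, pleiotropy, assortative mating or
winner's-curse instrument selection — passing benchmarks therefore speak to
estimator correctness under the model's assumptions, not to robustness
against those violations.

By default the simulated confounder is *not* given to the estimators
(unmeasured confounding is the MR premise); `confounder_visible=True`
switches to the alternative reading in which C is an observed covariate in
every design. Both modes are exercised in the tests.

## Benchmark metrics and known limitations

MAB = median|γ̂ − γ| over replicates; RMAB = MAB/|γ|, undefined when γ = 0
(rendered "-"). Instrument strength is reported as the mean marginal
F-statistic of each trait on its own instruments (equivalent in the simple
regression to the instrument-on-trait orientation); F < 10 is the
conventional weak-instrument threshold. Estimator failures on a replicate
are counted and reported per cell.

Two limitations worth knowing:

* **Weak-instrument regime.** At the stated weak-IV effect sizes
  (0.02–0.05 per allele, n = 1000) the achieved mean F is ≈ 1–2, i.e. the
  instruments are nearly irrelevant. The harness always prints the achieved
  F next to the accuracy metrics so that the effective regime is visible
  rather than assumed. In this regime BiLIML clearly dominates BiRatio when
  many (≈ 100) weak instruments are combined; with only a handful of
  near-irrelevant instruments LIML's heavy-tailed sampling distribution can
  cost it the MAB ordering even while its median remains less biased.
* **Inference, not just point estimates.** The ratio-family SEs are
  first-order fixed-effect IVW; no second-order delta correction, no
  random-effects inflation, no robust/sandwich variants. The k-class SEs use
  the classical homoskedastic covariance. Coverage under heteroskedasticity
  is untested.

Problem sizes used by the shipped accuracy checks: 300–1000 replicates of
n = 1000 cohorts per configuration, instrument counts 1–100 per trait.
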