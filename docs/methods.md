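# Methods

## Data-generating model

Each simulated cohort has `n` unrelated individuals and `M` biallelic
variants. For individual *i*:

- Genotypes `G_ij ~ Binomial(2, p_j)` with MAF `p_j ~ Uniform(maf_range)`
  (default 0.01–0.5). Optional LD blocks are generated haplotype-wise by a
  latent-Gaussian copula: within a block of exchangeable correlation ρ, each
  haplotype's latent value is `√ρ·u_i + √(1−ρ)·e_ij` and the allele is
  carried when the latent value falls below `Φ⁻¹(p_j)`. The realized dosage
  correlation is attenuated relative to ρ (dichotomization), which is
  sufficient for exercising the r² clumping rule.
- A latent confounder `C_i ~ N(0,1)`, independent of genotypes; an age-like
  covariate `~N(0,1)` and a sex-like covariate `~Bernoulli(0.5)`.
- Exposure (continuous, BMI-like):
  `X_i = Σ_j β_j (G_ij − 2p_j) + a·C_i + covariate effects + ε_i`,
  `ε_i ~ N(0, σ_ε²)`. Centring the genetic component moves only the
  intercept; association betas are unchanged.
- Outcome (binary, CAD-like):
  `Y_i ~ Bernoulli(expit(α₀ + θ·X_i + b·C_i + covariate effects))`.

### Effect-size spectrum

True effects are parameterized on the non-centrality (NCP) scale: each
causal variant gets a target NCP `t_j` for its single-variant association
chi-square at one-third of the cohort (the size of one group after a
three-way split), and `β_j` is solved from
`t_j ≈ (n/3)·2p_j(1−p_j)β_j² / σ²_resid`. The residual variance includes
the polygenic background, which is itself determined by the targets; with
`S = Σ t_j` and non-genetic variance σ₀², the background solves
`g = σ₀²·S/(n/3 − S)` in closed form. `S ≥ n/3` is rejected as an
infeasible-heritability configuration (it would require h² ≥ 100%).

Targets are drawn **log-uniformly** on (5, 80) by default. Two facts drive
this choice. First, the range must straddle the selection boundary — a
chi-square of ≈29.7 corresponds to P = 5×10⁻⁸ — or selection is
deterministic and there is no curse to study. Second, the *shape* matters:
empirical GWAS effect spectra are bottom-heavy, and in the empirical
split-sample profile this reproduces, the median iteration selects only a
fraction of the loci ever selected. With a flat spectrum most instruments
are comfortably strong, nearly every ever-selected locus is selected in
every split, and the inverse-variance weights concentrate on curse-free
variants — the aggregate bias then drowns in Monte-Carlo noise. A
log-uniform spectrum restores the realistic mixture: some variants selected
in almost every split, many selected only when sampling noise pushes them
over the line.

### Default parameters

| Parameter | Default | Units / rationale |
|---|---|---|
| n_individuals | 30 000 | 10 000 per group; large enough for stable logistic fits, small enough for minute-scale studies |
| n_variants / n_null_variants | 400 / 240 | 160 causal; keeps Σ NCP ≈ 4 300 ≪ 10 000 (h² ≈ 40%) |
| effect_spec | log-uniform NCP (5, 80) | see above |
| exposure_noise_sd | 3.6 | exposure units; with confounding and polygenic variance, total SD ≈ 5.5 (BMI-like) |
| confounder_effect_exposure (a) | 2.0 | exposure units per confounder SD (~13% of exposure variance) |
| confounder_effect_outcome (b) | 0.8 | log-odds per confounder SD; with a = 2.0 the confounded observational slope exceeds θ by ≈ a·b/Var(X) ≈ 0.05 — strong positive confounding, so one-sample weak-instrument bias (scenario 4 vs 1, expected magnitude ~ρ/(1.5·mean χ²) ≈ 0.003) is detectable above the median's Monte-Carlo error (~0.001) at 30 iterations |
| causal_log_or (θ) | 0.08 | log OR per exposure unit (OR ≈ 1.083) |
| baseline_log_odds (α₀) | logit(0.08) | ≈8% baseline prevalence; realized ≈ 14% with positive θ and confounding |
| position_stride_bp | 200 kb | single synthetic chromosome; makes the 1 Mb clumping window meaningful (block members sit 10 kb apart) |

## Study pipeline

Each iteration: (1) uniformly random three-way split into groups whose
sizes differ by ≤1; (2) discovery GWAS for the exposure in group A
(vectorized covariate-adjusted OLS, exactly equal to per-variant OLS via a
QR residualization and full-model degrees of freedom); (3) MAF > 0.01%
filter applied in the discovery group, plus a guard dropping variants
monomorphic in any group (they would make per-group lead associations
inestimable); (4) selection at P < 5×10⁻⁸ and greedy clumping (1 Mb,
r² < 0.01 estimated from group-A dosages; candidates visited by ascending
p-value, ties broken by chromosome/position/id; a blocked candidate joins
the nearest offending lead's locus); (5) per-group exposure (linear) and
outcome (logistic) associations for the lead variants — the group-A
exposure rows are the discovery rows, by construction; (6) MR estimation
for the five scenarios (IVW everywhere; DIVW and FIQT in the overlap
scenarios 2, 3, 5).

Selection strategies. *primary* uses the clumped set as is. *strict*
filters the primary leads to discovery P < 5×10⁻¹¹; filtering (rather than
re-clumping the stricter candidate list) guarantees the strict instrument
set nests inside the primary one, which matches how a stricter sensitivity
analysis is actually run on a fixed discovery set. *no_full_replication*
removes loci whose cross-iteration locus was selected in every iteration.
Both secondary strategies reuse the same splits and association estimates —
no re-randomization.

Cross-iteration locus identity uses single-linkage merging of selected
variants within 1 Mb on a chromosome. The per-locus representative for
curse summaries is the member with the smallest discovery p-value across
all iterations (ties by position). Its group-A exposure beta in *every*
iteration comes from the stored discovery scans; its group-A outcome beta
is computed in a dedicated second pass over all iterations, because curse
statistics average over all iterations, not just those where the variant
was selected. Iterations are weighted equally in these means.

## Estimators and corrections

- IVW: estimate and fixed-effect SE as in the README; heterogeneity
  `Q = Σ w_j (ratio_j − θ̂)²` with `w_j = β̂_Xj²σ_Yj⁻²`; reported SE is the
  fixed-effect SE × max(1, √(Q/(J−1))) for J ≥ 2 (multiplicative
  random-effects, the standard summary-MR convention).
- DIVW: same numerator, denominator `Σ (β̂_Xj² − σ_Xj²)σ_Yj⁻²`; a
  non-positive denominator raises an error advising stronger instruments.
  The SE applies the same multiplicative convention to the debiased
  weights; since debiased weights can be negative for very weak variants, Q
  is floored at zero before the inflation factor. The SE convention for
  DIVW is a package decision — reasonable alternatives exist.
- FIQT: two-sided p-values of the discovery Z-scores are
  Benjamini–Hochberg adjusted (`adj_(k) = min_{l≥k} m·p_(l)/l`, capped at
  1) and mapped back through the upper-tail normal quantile with the
  original sign. The *whole* post-filter discovery scan is transformed, so
  ranks reflect the scan's multiplicity structure, and `m` defaults to the
  scan size; the corrected Z of each lead is then read off. The per-variant
  factor `Z_corr/Z_orig` rescales the betas that were estimated in the
  discovery group — exposure in scenario 2, outcome in scenario 3, both in
  scenario 5 — because those are the associations carrying winner's curse
  (shrinking β̂_X by f < 1 raises the IVW estimate by 1/f; shrinking β̂_Y
  lowers it by f, which is exactly the corrective direction in each
  scenario). Standard errors are left unscaled and selection still uses the
  original p-values, isolating the correction's effect from selection
  changes.

## Numerical choices

- P-values use the two-sided normal approximation for both regressions
  (GWAS convention); they are clipped into (0, 1] against underflow, and
  FIQT clips raw p-values at 10⁻³⁰⁰.
- Logistic fits: Newton with step-halving; convergence at relative
  log-likelihood change < 10⁻¹⁰ or 25 steps; any coefficient beyond |50| is
  declared quasi-complete separation and reported with the variant id.
- Spearman correlations are Pearson correlations of mid-ranks; the p-value
  is a two-sided permutation test (9 999 seeded shuffles by default).
  Undefined percentage differences (zero all-iteration mean) are emitted as
  missing and excluded from correlations.
- Seeding: one master seed per study; per-iteration split seeds derive from
  it through a numpy `SeedSequence`, so iterations are independent yet the
  whole study is bit-reproducible. The cohort has its own config seed.
- Iterations whose discovery selects nothing are flagged and excluded from
  summaries rather than aborting the study; a study where every iteration
  is empty raises an error.

## What the generator does and does not emulate

It emulates: a polygenic continuous exposure with effects straddling the
selection threshold; a confounded binary outcome with a positive causal
effect; covariate adjustment; optional LD for clumping. It does **not**
emulate: realistic LD from a genetic map or reference panel, imputation
dosages/INFO scores, population structure or relatedness, ascertainment, or
the full covariate set of a real biobank GWAS (two stand-in covariates
replace age, sex and genomic principal components). Passing tests therefore
demonstrate the *mechanics and direction* of winner's curse and
weak-instrument bias under clean assumptions, not their magnitude in any
particular real data set.

## Default verification problem sizes

The package's stochastic verification suite runs one 30-iteration study at
the default cohort (30 000 × 400) plus one matched null study (θ = 0, no
outcome confounding), chosen so the full suite completes in about a minute
while leaving the directional effects several Monte-Carlo standard errors
wide. At this scale the parameter-recovery benchmark is the coefficient
from a direct logistic regression of the outcome on the true genetic
exposure score with covariate adjustment: because the outcome model is
logistic, marginal and conditional odds ratios differ (non-collapsibility),
and summary-statistic MR on marginal associations targets the marginal,
slightly attenuated version of θ — the oracle regression targets the same
quantity, making the comparison like-for-like.

## Known limitations

- LD blocks are exchangeable-correlation only; clumping behaviour under
  realistic decay patterns is not tested.
- The DIVW variance convention (above) and the cross-iteration locus
  matching rule (single-linkage within 1 Mb) are package decisions where
  the literature leaves room.
- With 30 iterations the binomial uncertainty on a 5% type-I error is wide
  (±3 SE ≈ ±0.12); the null check is a sanity bound, not a precise
  calibration.
- Percentage inflation for outcome associations can be enormous when the
  all-iteration mean is near zero; absolute differences are the stable
  scale for cross-trait comparison.
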