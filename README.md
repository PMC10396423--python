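# splitmr

Split-sample Mendelian randomization (MR) studies of **winner's curse** and
**weak-instrument bias**.

When genetic instruments are selected in the same data set that supplies the
association estimates, the selected variants' associations are overestimated
(winner's curse), and chance variant–confounder correlations add
weak-instrument bias whose direction depends on whether the exposure and
outcome associations come from the same sample. `splitmr` quantifies both
effects empirically: it simulates a biobank-style cohort, repeatedly splits
it into three equal groups at random (a discovery group A and estimation
groups B and C), runs a discovery GWAS, clumps genome-wide-significant
variants into independent loci, and compares summary-statistic MR estimates
across five overlap scenarios:

| Scenario | Exposure from | Outcome from | Winner's curse in | One-sample |
|---|---|---|---|---|
| 1 | B | C | — | no |
| 2 | A | B | exposure associations | no |
| 3 | B | A | outcome associations | no |
| 4 | B | B | — | yes |
| 5 | A | A | both | yes |

It is aimed at statistical geneticists and epidemiologists who want to see —
and teach — how large these biases get for instruments near the selection
threshold, and how well correction methods recover the truth.

## Estimators

With per-variant exposure associations β̂_Xj (SE σ_Xj) and outcome
associations β̂_Yj (SE σ_Yj), the package implements:

- **Random-effects IVW** — the weighted least-squares fit of β̂_Y on β̂_X
  through the origin:

  θ̂_IVW = Σⱼ β̂_Yj β̂_Xj σ_Yj⁻² / Σⱼ β̂_Xj² σ_Yj⁻²,

  with Cochran's Q over the per-variant ratios and the multiplicative
  random-effects SE, i.e. the fixed-effect SE times max(1, √(Q/(J−1))).
- **DIVW** (debiased IVW) — subtracts the exposure sampling variance from
  the denominator, Σⱼ (β̂_Xj² − σ_Xj²) σ_Yj⁻², removing first-order
  weak-instrument/selection bias.
- **FIQT** — false-discovery-rate inverse-quantile-transformation shrinkage
  of the discovery Z-scores (Benjamini–Hochberg adjust the two-sided
  p-values, map back through the normal quantile); the per-variant factor
  Z_corrected/Z_original rescales whichever betas were estimated in the
  discovery group.

Per-variant winner's curse is summarized per locus as the percentage and
absolute difference between the mean discovery-group beta in iterations
where the variant was genome-wide significant for the exposure and its mean
across all iterations, stratified by minimum p-value and minor allele
frequency.

## Worked example

```python
from splitmr import (SimulationConfig, EffectSpec, StudyConfig, simulate_cohort,
                     run_study, scenario_table, summarize_variant_curse, to_odds_ratio)

config = SimulationConfig(n_individuals=9000, n_variants=100, n_null_variants=70,
                          effect_spec=EffectSpec(5, 60), seed=7)
cohort = simulate_cohort(config)
study = run_study(cohort, 10, StudyConfig(n_iterations=10, seed=11))
table = scenario_table(study)
print(table[table["method"] == "IVW"].round(4).to_string(index=False))
```

```
 scenario method strategy  n_usable  median_estimate  mean_estimate  mean_se  sd_estimates
        1    IVW  primary        10           0.0703         0.0729   0.0461        0.0294
        2    IVW  primary        10           0.0726         0.0791   0.0406        0.0434
        3    IVW  primary        10           0.1214         0.1078   0.0491        0.0433
        4    IVW  primary        10           0.0744         0.0844   0.0446        0.0456
        5    IVW  primary        10           0.1157         0.0983   0.0434        0.0416
```

Estimates are log odds ratios of the binary outcome per one-unit increase in
genetically predicted exposure; the simulated causal effect is 0.08.
Scenario 3 (outcome associations share the discovery sample) is visibly
inflated relative to the no-overlap reference, and at this small scale
(10 iterations, 9 000 individuals) the Monte-Carlo spread is still large —
the full study conditions use 30 000 individuals and more splits.
Converting the reference median: `to_odds_ratio(0.0703)` → `1.073` per
exposure unit.

The per-locus curse table shows the threshold gradient directly
(`summarize_variant_curse(study)`, three loci spanning the range):

```
representative_variant  min_p_exposure  n_iter_selected  pct_diff_x  abs_diff_x   maf
                 v0073        1.29e-08                1        33.7      -0.177  0.33
                 v0097        1.52e-12                7        8.38      0.0738 0.191
                 v0037        3.14e-17               10        2.54         0.1  0.01
```

A locus whose best evidence barely clears P < 5×10⁻⁸ is ~34% inflated in
the iterations where it is selected; a locus at P ≈ 10⁻¹² is ~8% inflated;
a locus at 10⁻¹⁷ is essentially curse-free.

The same pipeline is scriptable from the shell:

```bash
splitmr run --config config.yaml --iterations 100 --seed 3 \
        --strategies primary,strict,no_full_replication --out study_out/
splitmr summarize --study study_out/ --out summaries/
splitmr mr --exposure exp.tsv --outcome out.tsv --method divw
```

`splitmr mr` consumes tab-delimited summary statistics (columns
`variant_id, chromosome, position, effect_allele, other_allele, eaf, beta,
se, z, pvalue, n, trait, group`), so it also works on externally supplied
GWAS results.

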