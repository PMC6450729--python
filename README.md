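# mrscreen

Phenome-wide causal screening on GWAS summary statistics: two-sample
Mendelian randomization (MR) with a full sensitivity battery, LD-score
regression (LDSC) genetic correlation, Bayesian colocalization, and
individual-level genetic risk scoring — plus a synthetic-data module that
generates every input the pipeline needs with a recorded truth ledger, so
the whole analysis is testable offline at desk scale.

## What's inside

| module | purpose |
|---|---|
| `mrscreen.sumstats` | read/validate/write/intersect GWAS summary-statistics tables (headered TSV) |
| `mrscreen.harmonize` | instrument selection (p < 5e-8), greedy LD clumping (r² < 0.001 / ±10 Mb), proxy lookup (r² ≥ 0.8), allele harmonization with palindrome handling |
| `mrscreen.mr` | Wald ratios, IVW (multiplicative random effects), MR-Egger, weighted median (bootstrap SE), Cochran's Q / I², Steiger directionality, leave-one-out, reverse MR, instrument F-statistic |
| `mrscreen.mvmr` | multivariable MR (weighted LS) with lasso-based exposure selection and conditional F |
| `mrscreen.ldsc` | observed-scale h² and bivariate genetic correlation with delete-one-block jackknife SEs |
| `mrscreen.coloc` | Wakefield approximate-Bayes-factor colocalization, PPH0–PPH4 and per-variant H4 posteriors (log-space throughout) |
| `mrscreen.grs` | weighted dosage risk scores, quintile logistic regression with covariate adjustment, strata reruns and a Firth fallback |
| `mrscreen.screen` | the two screening designs: LDSC scan with BH-FDR, and the two-phase MR screen (IVW gate → Egger+weighted-median sensitivity gate → cross-cohort replication) |
| `mrscreen.simulate` | seeded generators for paired exposure/outcome sumstats (LD blocks, pleiotropy, sample overlap), LDSC-model z-scores, colocalization regions, and genotype-level cohorts |

## CLI

Each subcommand takes a YAML config plus `--seed`, `--out-dir`,
`--log-level`; exit code 0 on success, 2 on validation failure.

```sh
mrscreen simulate sim.yaml --seed 3 --out-dir out/      # synthetic sumstats + truth ledger
mrscreen mr mr.yaml --seed 3 --out-dir out/             # estimator battery, one exposure vs outcome
mrscreen ldsc ldsc.yaml --out-dir out/                  # bivariate genetic correlation
mrscreen coloc coloc.yaml --out-dir out/                # ±1 Mb regions around index variants
mrscreen grs grs.yaml --out-dir out/                    # risk-score quintile regression
mrscreen screen screen.yaml --design mr --out-dir out/  # full two-phase screen
```

Minimal screen config over a synthetic library:

```yaml
synthetic: {n_null: 20, n_causal: 2, theta: 0.3}
thresholds: {n_boot: 500}
```

For real data, supply trait entries instead:

```yaml
traits:
  - {path: ldl.tsv, trait_id: ldl, cohort_tag: published, n: 173082}
outcome: {path: als.tsv, trait_id: als, trait_type: binary, n: 80610}
```

## Conventions and defaults

- Coordinates are 1-based GRCh37 (build carried as metadata only).
- IVW defaults to multiplicative random effects with the residual scale
  floored at 1 (`random_effects=False` for fixed effects); Egger
  p-values are on t(k−2), IVW/weighted-median on the normal.
- Palindromic variants are frequency-resolved when both EAFs fall
  outside [0.42, 0.58], otherwise dropped.
- LDSC heritability and genetic covariance share one regression routine,
  so a trait's genetic correlation with itself is exactly 1; h² is
  observed-scale, with a 200-block delete-one jackknife.
- Colocalization priors default to p1 = p2 = 1e-4, p12 = 1e-5 and
  per-trait effect prior SD 0.15 (quantitative) / 0.20 (binary).
- All simulation randomness flows from a single seed with deterministic
  per-component sub-streams; outputs are byte-identical per seed.
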