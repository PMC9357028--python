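# triarchy

Analysis toolkit for discovering the latent structure of executive
functions (EF) from behavior, brain connectivity, and genetics — and for
testing whether the structure holds up across all three levels at once.

Executive functions are usually measured with nine tasks spanning three
putative domains: **inhibiting** (anti-saccade, stop-signal, Stroop),
**updating** (keep-track, letter 3-back, spatial 2-back) and **shifting**
(number-letter, color-shape, category-switch).  Whether these tasks reflect
three separable abilities, one general ability, or a *bifactor* structure —
a common factor C on all nine tasks plus orthogonal domain-specific factors
— is an open ontological question.  `triarchy` implements the full chain
used to adjudicate between 12 candidate latent-variable models:

- **behavior** — trial cleaning (100 ms rule, per-subject Tukey fences),
  binomial-threshold participant exclusion, dependent measures (SSRT by the
  integration method, d′, RT costs), arcsine/logit transforms, median ±
  1.5·IQR truncation, and age/sex residualization;
- **cfa** — maximum-likelihood / FIML confirmatory factor analysis of the
  12 models (Σ = ΛΦΛ′ + Θ, factor variances fixed at 1), CFI/RMSEA/SRMR/
  AIC/BIC, nested χ²-difference tests, regression factor scores;
- **cpm** — connectome-based predictive modelling: partial-correlation edge
  screening, unit-weighted positive/negative summaries, k-fold
  cross-validation over many random splits, permutation inference,
  contributing-edge extraction (≥ 95% of iterations), Benjamini-Hochberg FDR;
- **overlap** — Dice overlap of contributing-edge sets with a
  random-subset permutation null (hypergeometric closed-form oracle), node
  ranking by contributing-edge degree, network-pair enrichment folds;
- **genetics** — genotype QC, GCTA-style GRM, ancestry PCA, relatedness
  pruning, AI-REML SNP heritability (h²_SNP), bivariate genetic correlation
  (r_g), partitioned-heritability enrichment; PLINK .bed/.bim/.fam and GCTA
  GRM binary I/O;
- **geneset** — internal GWAS scan, ±kb SNP-to-gene mapping, best-SNP gene
  scores with confound correction, permutation gene-set enrichment at
  percentile cutoffs, expression-based candidate-set selection (top genes
  by regional fold change);
- **mediation** — high-dimensional mediation Y = Mγ + Zβ + ε with
  M = ZB + η: exact closed-form oracle for VTE/VIE/PVM, a cross-fitted
  REML-based estimator of the proportion of variance mediated, and a
  Freedman-Lane permutation test;
- **simulate** — synthetic cohorts (trials, scores, connectomes,
  genotypes, annotation, expression) with planted ground truth for every
  quantity above;
- **pipeline** — one-config orchestration of the whole study with a
  consolidated JSON report.

The mathematical and numerical details live in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a cohort whose true structure is the "C+S" bifactor model (common
factor on all nine tasks, shifting-specific factor on the three shifting
tasks), residualize the scores, and compare three candidate models:

```python
from triarchy import simulate, behavior, cfa

cohort = simulate.simulate_cohort(simulate.CohortConfig(
    n_subjects=870, seed=7, n_nodes=60, n_snps=1000, n_genes=100))
scores = behavior.residualize_scores(cohort.scores, cohort.covariates[["age", "sex"]])
lib = cfa.model_library()
for name in ["G", "I+U+S", "C+S"]:
    fit = cfa.fit_cfa(scores, lib[name], missing="fiml")
    fi = cfa.fit_indices(fit, scores)
    print(f"{name:6s} chi2={fit.chisq:7.2f} df={fit.df:2d} "
          f"CFI={fi.cfi:.3f} RMSEA={fi.rmsea:.3f} SRMR={fi.srmr:.3f}")
```

prints

```
G      chi2= 142.15 df=27 CFI=0.932 RMSEA=0.070 SRMR=0.051
I+U+S  chi2=  22.71 df=24 CFI=1.000 RMSEA=0.000 SRMR=0.020
C+S    chi2=  22.22 df=24 CFI=1.000 RMSEA=0.000 SRMR=0.019
```

The one-factor model G misfits (CFI < 0.95, RMSEA > 0.05) while the
generating C+S model — and the three-factor I+U+S model it is statistically
close to — pass all three fit criteria.  A nested comparison against the
richer C+U+S bifactor model shows the extra updating-specific factor is not
needed for these data:

```python
d_chi, d_df, p, _ = cfa.chisq_diff_test(
    cfa.fit_cfa(scores, lib["C+S"]), cfa.fit_cfa(scores, lib["C+U+S"]))
print(f"C+S vs C+U+S: dchi2={d_chi:.2f} ddf={d_df} p={p:.3f}")
# C+S vs C+U+S: dchi2=3.35 ddf=3 p=0.340
```

The same cohort carries planted connectome, genotype and mediation truth,
so the downstream stages (`cpm.run_cpm`, `genetics.reml_variance_components`,
`geneset.magenta_test`, `mediation.estimate_mediation`) can each be checked
against known answers; `pipeline.run_full_study(StudyConfig(...))` runs
everything in sequence.  A thin CLI mirrors the stages:

```bash
triarchy simulate --config cohort.yaml --seed 3 --out cohort/
triarchy behavior --scores cohort/scores.tsv --covariates cohort/covariates.tsv --out resid.tsv
triarchy cfa --scores resid.tsv --models all --out fits.json
triarchy run --seed 0 --out study/
```

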