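# Methods

This note documents the models, estimators, numerical choices, and the
synthetic-cohort design behind `triarchy`.  The package re-implements a
gene-brain-behavior analysis chain for discovering the latent structure of
executive functions (EF): behavioral scoring, confirmatory factor analysis,
connectome-based prediction, overlap statistics, GREML genetics, gene-set
enrichment, and high-dimensional mediation.  Because the original cohort is
not publicly distributable, every stage is exercised on synthetic cohorts
with planted ground truth; all empirical claims below are the ones the test
suite and `scripts/acceptance.py` actually compute.

## Behavioral scoring

Nine tasks measure three putative EF domains — inhibiting (anti-saccade,
stop-signal, color-word Stroop), updating (keep-track, letter 3-back,
spatial 2-back), and shifting (number-letter, color-shape, category-switch).
Trial cleaning removes responses faster than 100 ms everywhere and, for
RT-based tasks, responses outside the per-subject Tukey fences
Q1 − 1.5·IQR … Q3 + 1.5·IQR (type-7 linear-interpolation quartiles).
Participants are excluded when more than 20% of trials lack a response or
when their correct count falls below the 95% quantile of
Binomial(N trials, chance rate).

Dependent measures: anti-saccade error rate; SSRT by the integration method
(the p-th percentile of correct-Go RTs minus the mean stop-signal delay,
where p is the observed stop-failure rate; nearest-rank percentile, since no
interpolation rule is standard); RT difference scores for Stroop and the
three switch tasks (correct trials only); keep-track correct count; d′ =
z(hit) − z(false alarm) with rates clamped to [1/(2N), 1 − 1/(2N)].
Orientation and transformation: RT-based scores are negated, anti-saccade
errors become arcsine-root accuracy, the keep-track count becomes a logit
of the proportion with a 0.5-count continuity adjustment.  Final scores are
truncated at median ± 1.5·IQR — fences about the *median*, implemented as
specified rather than the conventional quartile fences.  Scores are then
residualized on age and sex by per-column OLS on available cases and
z-scored.

Choices worth flagging: trial-level fences are computed per subject (the
participant is the cleaning unit); whether pooled fences were intended is
ambiguous, and per-subject is the conservative reading.

## Confirmatory factor analysis

Twelve candidate models over the 9 tasks: five correlated-factors models
(I+U+S; the two-factor mergers S/I+U, U/I+S, S/U+I; one-factor G) and seven
bifactor models (C+I+U+S, C+I+S, C+U+S, C+I+U, C+I, C+S, C+U) in which a
common factor loads on all nine indicators and domain-specific factors are
orthogonal to everything.  Identification fixes factor variances at 1;
free parameters are the pattern loadings, nine residual variances, and (for
correlated models) the factor correlations, so df = 45 − q.

Estimation maximizes the multivariate-normal likelihood of
Σ(θ) = ΛΦΛ′ + Θ.  With incomplete rows the likelihood is full-information
(FIML): rows are grouped by missingness pattern and each pattern contributes
the likelihood of its observed sub-vector; the mean vector is estimated
jointly.  The saturated model under missingness is fitted by an EM
algorithm for the unrestricted MVN; on complete data both reduce to closed
forms.  The optimizer is L-BFGS-B on an unconstrained reparameterization
(log residual variances, atanh correlations) from fixed default starts
(λ = 0.5, Θ = half the column variance, φ = 0.2); residual variances are
bounded below at 10⁻⁶ times the column variance (Heywood guard).  Standard
errors come from the inverse numerical Hessian; loading p-values are Wald.

χ² = 2(ℓ_sat − ℓ_model) (multiplier n, not n−1).  CFI uses the
independence baseline (diagonal Σ, free variances); RMSEA uses n in the
denominator; SRMR is the RMS difference of sample vs implied correlations
over the off-diagonal lower triangle, with the FIML-estimated saturated
covariance standing in for the sample covariance under missingness.
Nested models are compared by the one-sided χ²-difference test.  Factor
scores use the regression (Thurstone) formula ΦΛ′Σ⁻¹(x − μ) evaluated per
missingness pattern.

Calibration (acceptance suite): over 200 replicates from a true C+S model
at n = 2,000, the mean χ² sits within 10% of its 24 df, the generating
model passes CFI > 0.95 and RMSEA < 0.05 in ≥ 95% of replicates, and mean
loading estimates recover the truth to < 0.05.

## Connectome-based prediction (CPM)

Edges are Fisher-z connectivity values over the canonical i<j pairs of a
264-node parcellation (34,716 edges); the pipeline normalizes connectivity
within each participant before modelling.  Within each training fold, each
edge's partial correlation with the score (edge and score both residualized
on scanner and head-motion covariates — the symmetric definition of partial
r) is tested at p ≤ p_thresh (default 0.05; 0.01 and 0.1 supported);
selected edges are summed with unit weights separately by sign; a linear
regression on the two sums predicts the held-out fold, with edges
standardized within the training and test sets separately.  Accuracy per
split is the Pearson r between observed scores and the *concatenated*
held-out predictions (fold-wise averaging was the alternative; concatenation
uses every subject once).  Results average over random fold splits.
Significance comes from shuffling the score across subjects (covariates
stay attached) and re-running the entire cross-validation per permutation;
p uses the +1 small-sample correction.  Edges selected in ≥ 95% of all
fold × split iterations (boundary inclusive) are "contributing edges".
FDR control across components uses Benjamini-Hochberg via statsmodels.

Calibration: permutation type-I error is measured at reduced dimensions
(n = 60, 100 candidate edges, 5 folds, 1 split, 199 permutations, 200
meta-replicates) and must land in [0.03, 0.07].  Power and contributing-edge
recovery are measured on planted data (b = 0.5, 100 informative among 2,000
candidate edges, n = 870); the reference simulation fixed the floors at
precision ≥ 0.7 and recall ≥ 0.9 (it measured ≈ 0.83 / 1.0).

## Overlap statistics

Dice(X, Y) = 2|X∩Y|/(|X|+|Y|) over contributing-edge sets (0 when both are
empty).  The permutation null draws independent uniform subsets of the two
observed sizes — implemented by sampling the intersection size from the
equivalent hypergeometric distribution — and its mean must match the closed
form 2|X||Y|/(N(|X|+|Y|)) to Monte-Carlo accuracy; this closed form is the
module's primary oracle.  Nodes are ranked by contributing-edge degree
(ties broken by node id).  Network enrichment at an anchor node compares
the observed count of selected edges into each partner network against the
uniform expectation E_l = (#partner nodes in l) · k/(n_nodes − 1); all
folds are emitted, including those below 1.

## GREML genetics

QC drops SNPs with MAF < 5%, missingness > 5%, or a 1-df chi-square
Hardy-Weinberg test p < 10⁻⁶ (the asymptotic test; the exact test is out of
scope), then subjects with > 5% missing dosages.  The GRM is
A_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1−p_i)) with missing
dosages mean-imputed (GCTA convention).  Relatedness pruning removes one
random member of each pair above 0.05; ancestry PCs are the GRM's top
eigenvectors with signs fixed by the largest-magnitude loading.

Variance components are estimated by AI-REML: EM warm-up iterations, then
average-information updates, convergence at |ΔlogL| < 10⁻⁶, components
clamped at 10⁻⁶·Var(y), SEs from the inverse AI matrix (delta method for
ratios), and a boundary LRT (0.5·χ²₀ + 0.5·χ²₁) against the no-genetic
model.  Single-GRM fits run in the GRM eigenbasis, where each iteration is
O(n); multi-GRM fits use dense solves with step-halving whenever a proposal
makes V singular or decreases the likelihood.  The bivariate model
V = G⊗A + R⊗I block-diagonalizes in the same eigenbasis into n 2×2 blocks
and is maximized by quasi-Newton over log variances and atanh correlations;
r_g = σ_g12/√(σ²_g1 σ²_g2) with a delta-method SE.  Partitioned
heritability fits set and complement GRMs jointly; the enrichment fold is
h²_set over h²_total · (|set|/m), tested one-sided by z-score.

Recovery (acceptance suite, fixed 2,000 × 5,000 linkage-equilibrium panel,
effects and noise redrawn per replicate): ĥ² within 2 SE of the planted 0.5
in ≥ 90% of 100 replicates; r̂_g likewise over 30 replicates; a causal set
occupying 10% of SNPs yields a fold within 30% of 10 (median of 3); and the
AI-REML optimum agrees with a two-stage grid search of the restricted
likelihood to 10⁻⁴ on a toy dataset.

## Gene scores and set enrichment

An internal GWAS scan (per-SNP OLS with covariates, vectorized by
Frisch-Waugh-Lovell residualization) supplies association p-values.  SNPs
map to every gene whose boundary ± flank (25/35/50 kb) window contains them
(BED 0-based half-open; variant positions 1-based).  A gene's raw score is
its best (minimum) SNP p; −log10 scores are regressed on gene length and
SNP count (full OLS — the original confounder list is open-ended) and the
residuals are the corrected scores.  Enrichment of a candidate set counts
its genes above the 75th (or 95th) percentile of all corrected scores and
compares against random same-size sets drawn from all scored genes
(size-matched sampling by SNP-count decile is available as an option);
one-sided p with the +1 correction.

Because the count statistic is discrete, very small candidate sets make the
permutation test conservative through ties; the null-calibration suite uses
100-gene sets, where the type-I error at α = 0.05 sits in [0.03, 0.07], and
the power suite shows p < 0.05 with probability ≥ 0.8 for a causal set at
generator defaults.

## High-dimensional mediation

The model is Y = Mγ + Zβ + ε with M_j = ZB_j + η_j, where Z holds
standardized dosages of the candidate-set SNPs, M the contributing-edge
values, and Y a factor score; exposure effects are treated as dense random
effects.  The estimand is PVM = VIE/VTE with
VTE = (Bγ+β)′Var(Z)(Bγ+β) and VIE = (Bγ)′Var(Z)(Bγ); `pvm_from_truth`
evaluates these identities exactly on generating parameters, and the cohort
generator rescales (B, γ, β) — with β drawn orthogonal to Bγ — so the true
PVM hits its target to 10⁻⁶.

The estimator uses two REML fits on the exposure relationship matrix
K = ZZ′/q.  VTE is the K-attributable variance of Y.  For VIE, γ is
estimated on a training half by generalized ridge of Y on M whitened
against the exposure random effect (the direct path Zβ acts as
K-structured noise, making the GLS estimate of γ consistent; the penalty is
chosen by 3-fold CV in the whitened metric); on the held-out half the
composite Mγ̂ is rescaled by its GLS slope on Y — which removes the
multiplicative shrinkage that ridge imposes on γ̂ — and its K-attributable
variance is the fold's VIE.  Halves are swapped and fold-size-weighted.
Decomposing the composite's variance with REML, rather than taking the
variance of a BLUP-predicted indirect signal, avoids the attenuation that
plug-in predictors suffer at these dimensions (n = 870, q = 200, p = 100).
Negative PVM estimates are reported as-is.

Inference: the no-mediation null states Y ⊥ M | Z.  Y is split into its
BLUP exposure component plus a residual, and the residuals — exchangeable
under the null — are permuted and re-attached (Freedman-Lane).  This
preserves both the total Z→Y effect and the Z→M coupling while severing
the mediated channel.  Permuting rows of M instead would also destroy the
Z→M structure, which the null retains; with this estimator that scheme is
strongly anti-conservative (measured type-I ≈ 0.6), so it was rejected.

Calibration: median PVM estimates at planted {0, 0.25, 0.5, 0.75, 1} fall
within 0.10/0.15/[0.35,0.65]/0.15/0.15 respectively and increase strictly;
permutation type-I error over 200 replicates at n = 120, q = 10, p = 5 with
199 permutations lands in [0.02, 0.08].

## Synthetic cohorts

`CohortConfig` defaults define the study conditions: 870 subjects, a true
"C+S" bifactor model (common loadings 0.40–0.65, shifting-specific
0.45–0.55), 5% MCAR missingness per task, small age/sex effects, a 264-node
connectome with 100 informative edges per predictable component at slope
b = 0.5 on unit-variance edge noise, site and motion nuisance on all edges,
5,000 linkage-equilibrium SNPs with MAF uniform on [0.05, 0.5], 100 causal
SNPs, heritability 0.62 (common) and 0.19 (shifting-specific), genetic
correlation −0.06 between them, 500 genes tiling a toy chromosome whose
±50 kb windows never overlap neighboring genes, a gene × region expression
matrix with log-fold 3 enhancement of the causal genes' region, and a true
mediated proportion of 0.19 for the common pathway.  The common component
is generated *through* the mediation wiring (M = ZB + η, f₁ = Mγ + Zβ + ε),
so its heritability, its informative edges, and its mediated proportion are
one coherent ground truth; remaining factors get direct additive genetics
(causal effects aligned to the target genetic correlation) and additive
edge effects.  Identical config and seed reproduce byte-identical outputs.

Standalone trait generators used by the recovery suites rescale the genetic
and environmental parts to exact sample variances, so the planted h² (and
realized genetic correlation) hold by construction rather than only in
expectation — the standard practice for variance-component recovery
studies.

What the generator does not emulate: linkage disequilibrium (kept out so
the REML and enrichment oracles stay analytic), non-Gaussian task-score
distributions (no distributional forms are stated for the real scores;
Gaussian is assumed), realistic fMRI autocorrelation or edge dependence,
selection or assortative mating, and the X chromosome.  Passing tests
demonstrate estimator correctness under these idealized conditions, not
robustness to the full complexity of real cohort data.

## Problem sizes and determinism

Simulation scales — 2,000 × 5,000 for GREML recovery, 870 subjects for CPM
power and mediation recovery, reduced dimensions for permutation
calibrations, and a shared genotype panel per replicate batch with effects
and noise redrawn — are the package's desk-scale reference conditions; they
keep the full suite and the acceptance script reproducible in minutes on a
single core.  Every stochastic routine takes an explicit seed, pipeline
stages derive their seeds deterministically from the study seed, and reruns
produce byte-identical reports.
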