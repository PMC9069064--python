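# Methods

`gutresponse` re-implements, as a tested library plus CLI, the
computational analyses linking the longitudinal gut metagenome of
advanced NSCLC patients to anti-PD-1 (immune-checkpoint) treatment
response: diversity dynamics, BMI-adjusted differential testing of
metagenomic species (MGS), signed reporter-score pathway enrichment
over KEGG Orthology (KO) profiles, Dirichlet-multinomial-mixture (DMM)
enterotyping, progression-free-survival (PFS) stratification, and a
two-tiered random-forest response classifier. Because the original
cohort data are access-controlled, every stage is exercised against a
synthetic cohort generator that emulates the study's data structure;
this note records the models, the defaults, and the design decisions.

## Synthetic cohort model

Patients are apportioned to RECIST response groups by deterministic
largest-remainder rounding of the configured proportions (default
13 PR / 24 SD / 43 PD / 5 FD out of 85, with an antibiotics-exposure
rate of 12/85). Samples follow the collection grid M0=week 0, W1=1,
W2=2, M1=4, M2=8, M3=12, M4=16. Baseline is always collected;
afterwards patients drop out monotonically with per-visit probability
`dropout_rate` (default 0.2, which yields ≈285 samples for 73
ATB-free patients, matching the emulated cohort's sample count).
Fast-death (FD) patients contribute only a baseline sample.

Abundances follow a latent log-normal model: feature j has baseline
log-mean `b_j ~ N(-1, 1.5^2)`; each sample draws
`l_ij = b_j + effects + N(0, latent_sd^2)` (default `latent_sd = 1`),
is exponentiated, zero-masked, closed to sum one, and finally floored
at a detection limit (default 1e-6 relative abundance; values below it
become zeros), emulating the read-depth detection floor of shotgun
profiles. Zero inflation is Bernoulli with probability
`pi0 * exp(-max(shift, 0))`, where `shift` is the feature's total
latent boost in that patient and `pi0 = 0.3`: species that are more
abundant are also detected more often, which is what gives
differential species their "barely detectable in the depleted groups"
character. Planted effects:

- `n_differential_mgs` species (default 45) receive a latent shift of
  `mgs_effect_size` (natural-log scale) in a designated group, cycling
  PR → SD → PD. They are planted among features with above-median
  baseline abundance — an undetectable species cannot be a marker.
- a patient-level BMI covariate acts on a random 10% of features with
  coefficient `bmi_confounder_strength` per BMI standard deviation.
- enterotype structure: each patient carries one of
  `enterotype_count` (default 3) community types that boost a fixed
  set of driver genera (Bacteroides; Faecalibacterium/Eubacterium/
  Clostridium; Prevotella) by `enterotype_boost` (default 0.8 natural-
  log units). Enterotypes rotate within each response group, encoding
  the study-level observation that enterotype and response are
  unassociated. The boost default is deliberately moderate: because
  relative abundances are compositional, a strong community-type tilt
  inflates the closure denominator differently per type and pushes
  near-threshold features below the detection limit, which reads as a
  spurious group signal whenever sampling imbalance correlates types
  with groups.

KO profiles are derived by projecting MGS abundances through a random
binary MGS×KO incidence matrix (each MGS carries 1+Poisson(7) KOs) and
renormalizing. Pathways are random KO subsets (default 40 pathways,
5–30 KOs); `n_differential_pathways` of them (default 6) have all
member KOs multiplied by `exp(pathway_effect_size)` in PR samples
before renormalization.

PFS is exponential with group hazards (PR 0.35, SD 0.8, PD 2.5,
FD 8.0 month⁻¹) scaled by configurable hazard ratios for antibiotics
exposure (2.5), high tumor mutational burden (TMB > 5.6 mut/Mb, 0.5)
and high HLA-E (1.8); censoring is uniform-before-event with
probability `censor_rate` (0.2).

All randomness flows from one seed through named sub-streams, one per
patient, so dropout or per-patient changes never perturb another
patient's draws; identical configs give bit-identical bundles.
`CohortConfig.null()` switches off every planted effect (group, BMI,
pathway, and the enterotype boost) — this is the null cohort used for
calibration checks, since any of those effects is a real, if
group-orthogonal, signal source.

What the generator does **not** emulate: patient-level random effects
beyond BMI/enterotype (so longitudinal samples of one patient are
conditionally independent), phylogenetic correlation between species,
read-count noise, batch effects, and time-varying abundances within a
patient. Passing tests therefore demonstrate the statistical machinery
is correct and calibrated under its stated assumptions, not that real
cohorts satisfy those assumptions.

## Diversity dynamics

Alpha diversity is the Shannon index in nats (zero terms skipped);
beta diversity is Bray–Curtis dissimilarity,
`1 − 2·Σ min(p,q) / (Σp + Σq)`, and within-group dispersion at a visit
is the set of all pairwise dissimilarities. The longitudinal
comparison of two groups fits one local-linear smoother per group
(tricube weights, span 0.75 — the classic lowess defaults) over the
shared week range, takes the mean absolute gap between the smoothers
on a 50-point grid as the statistic, and permutes *patients* (all of a
patient's samples move together) between groups; the p-value uses the
add-one convention `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, so it is
exact-level and never zero. Patients are the exchangeable unit because
repeated measures within a patient are not.

## Differential MGS testing

Abundances are transformed as `log10(x + eps)` with `eps` set to half
the smallest nonzero value of the matrix — small enough to preserve
ordering, finite at zero. The primary test pools all visits into one
transformed-abundance mean per patient and fits, per MGS, the linear
model `value ~ group + BMI` against `value ~ BMI`; the p-value is the
extra-sum-of-squares F test. Patient aggregation (rather than testing
samples) is deliberate: group and BMI are patient-level covariates,
and treating repeated visits as independent replicates pseudo-
replicates them. Because patients contribute unequal visit counts, the
patient means are heteroscedastic (variance ∝ 1/n); the fit is
weighted least squares with weights equal to the visit count, which is
the efficient and correctly calibrated model when within-patient noise
dominates. A sample-level mode (`per_patient=False`) and a single-
visit mode (`timepoint=...`) are retained.

Benjamini–Hochberg q-values are reported for all tested MGSs. The
"significant" flag defaults to raw p < 0.05 (mirroring per-feature
ANOVA reporting) and can be switched to q < 0.05; recovery benchmarks
use the q-based flag. Significant MGSs get Tukey HSD pairwise
contrasts (studentized range, Tukey–Kramer for unequal sizes) and
enrichment labels: highest/lowest group median abundance, with median
ties broken by higher occurrence and then the fixed order PR > SD >
PD; if no group reaches `min_occurrence` (default 0.2) the label is
NA, mirroring "too low occurrence to define an enrichment group".

## Reporter scores

For a contrast (better, worse) at one visit, each KO gets a two-sided
Wilcoxon rank-sum p-value (normal approximation with tie correction —
verified against `scipy.stats.mannwhitneyu`) and the signed score
`z = Φ⁻¹(1 − p/2) · sign(median_better − median_worse)` (ties sign
+1; |z| capped at 8 against p underflow). A pathway with member scores
z₁…z_k scores `Z = Σz/√k`, corrected against a Monte-Carlo background:
μ_k and σ_k of `Z` over 1000 seeded draws of k KOs sampled without
replacement from all scored KOs, giving
`corrected_z = (Z − μ_k)/σ_k`. σ_k is floored at 1e-8 so an all-zero
degenerate background returns 0 rather than NaN. Contrasts are
oriented (PR,SD), (PR,PD), (SD,PD) with the first member "better", so
positive scores always mean enrichment with better response.
Significance thresholds are computed normal quantiles (1.960 at 5%,
2.576 at 1%), not hard-coded constants. Cross-visit consistency is the
Spearman correlation of corrected-z vectors against baseline;
contrasts at later visits are cross-sectional, not within-patient
deltas.

## Enterotyping (DMM)

Genus-level profiles are pseudo-counted (renormalize, scale by `depth`
— default 10,000 — round half-to-even, overshoot taken from the
largest genus) because the Dirichlet-multinomial needs counts while
the profiles are relative; `depth` makes that modelling step explicit.
The mixture is fitted by EM: E-step responsibilities from the Polya
log-pmf, M-step mixture weights plus three Minka fixed-point updates
of each component's α (clipped at 1e-8). Restarts (default 5)
initialize responsibilities from k-means on the proportion profiles.
The observed-data log-likelihood trace is monitored; a genuine
decrease terminates the run at the previous best (the inexact M-step
makes EM "generalized", so monotonicity is enforced rather than
assumed). Convergence is a 1e-6 relative change, capped at 500
iterations with a flag.

Model order is chosen by a Laplace-approximated log evidence:
log-likelihood at the fit, plus a weak N(0, 10) prior per log-α
parameter, plus ½d·log 2π, minus ½ log det of the negative Hessian.
The Hessian is analytic per component in log-α coordinates (diagonal
plus rank-one, determinant by the matrix-determinant lemma) and a
BIC-style ½ log n per free mixture weight. The prior matters: with a
flat prior the penalty is too weak and the evidence keeps rising past
the true K. BIC is available via `evidence="bic"`. Evidence ties
resolve to the smaller K.

## Tiered predictor

Stage A is PR-vs-PD, stage B is SD-vs-rest; training draws are
class-stratified and seeded (default 8 PR + 8 PD; those 16 form the
non-SD class against 16 SD). Feature selection runs `n_reps` (default
200, configurable to 1000) repetitions of stratified 8-fold CV; each
repetition draws a random candidate subset of ~4√p features and
trains one CART tree per fold (`max_features="sqrt"`), crediting used
features with impurity importance × held-out fold accuracy (a
selection-frequency variant is exposed). A single tree per repetition
keeps the 3,200-fit selection loop fast; the aggregate over all
(repetition, fold) trees is the ensemble that does the ranking. With
16 training samples, 8-fold stratified CV yields held-out folds of two
(one per class) — degenerate but legal. The per-stage feature count k
is picked from {5, 10, 20, 30} by out-of-fold AUC (coarse 4-fold CV,
25-tree forests; ties to smaller k), and the final per-stage models
are 500-tree random forests refit on the full training draw.

Three-class probabilities combine multiplicatively:
`p_SD = p_B(SD)`, `p_PR = (1 − p_B(SD))·p_A(PR)`,
`p_PD = (1 − p_B(SD))·(1 − p_A(PR))` — a factorization that sums to
one exactly. AUC uses the rank (Mann–Whitney) formulation with ties at
one half and a stratified bootstrap 95% CI (2000 resamples, seeded).
Multi-omics fusion is a weighted arithmetic mean of class-probability
vectors, renormalized, equal weights by default; tumor-genetics
features, when supplied, are encoded as one numeric column (TMB) plus
binary mutation flags.

## Survival

Responders are patients with PFS strictly beyond 3 months; patients
censored at or before the cutoff are labelled missing rather than
guessed. Curves are Kaplan–Meier product-limit estimates (lifelines;
events precede censorings at tied times) and two-group comparisons use
the standard 1-df log-rank test. Strata builders cover antibiotics
yes/no, TMB above/below 5.6 mutations/Mb, HLA-E high/low, and the
four-way TMB × HLA-E combination.

## Problem sizes in the benchmark battery

The benchmark module regenerates cohorts at sizes chosen so the full
battery runs in minutes: null calibration uses 5 cohorts × 300 MGSs
(ANOVA) and 10 cohorts × 50 pathways (reporter); differential recovery
uses 5 cohorts with 1,500 MGSs and 30 planted at effect 1.5; pathway
detection uses 100 cohorts with 3 planted 10-KO pathways at effect
1.0; the predictor benchmark uses 80-patient cohorts (120 MGS + 160 KO
features, 20 informative at effect 2.0) with 200 CV repetitions; DMM
recovery uses 200 samples at depth 5,000 over 12 genera. Reported
rates are means over seeds; the false-discovery rate in particular is
an expectation, so it is estimated by averaging per-seed false-
discovery proportions.

## Known limitations

- The pooled differential test is not a mixed-effects model; true
  patient-level random effects beyond the modelled covariates would
  inflate its type-I error (the spec-level alternative — repeated-
  measures modelling — is out of scope).
- Compositional closure means planted enrichments induce small real
  depletions elsewhere; at the default effect sizes this is
  negligible, but it is a property of relative-abundance data, not a
  bug.
- Reporter-score calibration assumes pathway membership is not
  strongly correlated with the MGS-to-KO projection structure; heavily
  overlapping pathways sharing source MGSs would be anti-conservative.
- The DMM evidence uses an analytic-Hessian Laplace approximation with
  a weak prior, not full marginal likelihood; it is a model-selection
  score, and its absolute value is not comparable across depths.
- Bootstrap AUC CIs are approximate at very small test sets; with
  fewer than ~5 positives per class their coverage drops below
  nominal.
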