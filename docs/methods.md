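# Methods

This note records the models, numerical conventions and design choices
behind `metabotype`, and what the synthetic-data tests do and do not show
about real cohorts.

## Clustering variables and secondary indices

Each patient contributes three clustering variables: the trapezoidal AUCs of
the four-point (0, 30, 60, 120 min) OGTT glucose and insulin curves, and
serum uric acid. On this grid the trapezoid rule reduces to fixed quadrature
weights (15, 30, 45, 30) applied to the four concentrations; the AUC is
linear in the curve and translation-covariant (AUC(y + c) = AUC(y) + 120·c).

The secondary indices use the standard literature forms: HOMA-IR =
g₀·i₀/22.5; HOMA-β = 20·i₀/(g₀ − 3.5); insulinogenic index IGI =
(i₃₀ − i₀)/(g₃₀ − g₀); Matsuda whole-body insulin sensitivity index
WBISI = 10⁴/√(g₀·i₀·ḡ·ī) with glucose converted to mg/dL (×18) and the
means taken over the four available grid points rather than Matsuda's
original five — the study grid has four. Pole cases (g₀ ≤ 3.5 for HOMA-β, a
zero glucose increment for IGI) yield NaN flagged per record instead of an
exception, so one degenerate record cannot abort a cohort run. The
disposition identities DI = HOMA-β/HOMA-IR and DI = IGI×WBISI hold exactly
by construction. Because the exact formulas used in the original analysis
are not published beyond the index names, these standard forms are an
explicit assumption of this package.

## AUC imputation from partial OGTT sampling

For each availability pattern (which time points were measured, per
analyte), a linear model predicts the full four-point AUC from the raw
concentrations at the present times. Selection is classic forward/backward
stepwise OLS: a candidate enters when its partial-F p-value is below
p_in = 0.05 and an included predictor leaves when its p-value exceeds
p_out = 0.10; p_in < p_out plus a step cap guarantees termination, and a
numerically exact fit (relative residual variance < 1e-12) stops selection
since the partial tests are then undefined. Training uses the
complete-OGTT records with a 70/30 train/test split stratified by sex
(downstream clustering is sex-stratified). Held-out quality is reported as
adjusted R² = 1 − (1−R²)(n−1)/(n−p−1) computed on the test split with the
test n and the selected p, alongside its square root, since either
convention appears in applied reports. Candidate predictors are raw
concentrations only — no interactions or cross-analyte terms.

Two built-in consistency anchors: the full-pattern model must recover the
trapezoid weights (15, 30, 45, 30) with zero intercept and R² = 1, and on
generator data the glucose-AUC models must outperform the insulin-AUC models
because insulin curves carry more noise (see below).

## Subtype discovery

Features are z-normalized per sex stratum (sample SD, ddof = 1 — the
convention of the clinical software the workflow mirrors); pooled
normalization is available as an option but off by default, consistent with
fully separate sex sub-models. k-means is Lloyd's algorithm from k-means++
starts, best of n_init = 20 restarts by within-cluster sum of squares,
stopping when the largest center movement falls below 1e-5 or after 30
sweeps; an emptied cluster is re-seeded at the point farthest from its
nearest center. The cluster count is chosen by maximizing the mean
silhouette width over k = 2…8 (ties toward smaller k); members of singleton
clusters contribute silhouette 0. Restarts are used because single-start
behavior depends on seeding internals that are not reproducible across
implementations.

The two-step clusterer agglomerates from singletons with the log-likelihood
merge distance d(j,s) = ξ_j + ξ_s − ξ_⟨j,s⟩, where
ξ_v = −N_v Σ_d ½·log(σ̂²_d + σ̂²_vd), σ̂²_d is the stratum-wide variance of
variable d (a regularizer that keeps singleton clusters finite) and σ̂²_vd
the biased within-cluster variance. The cluster count minimizes Schwarz
BIC(k) = −2·Σ_clusters ξ + 2·d·k·log n (two parameters, mean and variance,
per variable per cluster). The CF-tree pre-clustering stage of the original
industrial implementation is omitted: at desk-scale n the exact
agglomeration is cheap and the distance and BIC criterion are the parts that
define the method. A known property of the minimum-BIC rule under hard
assignment is a tendency to split a loose Gaussian cluster along a plane
(the split itself produces a spurious variance reduction), so the rule is
most reliable when clusters are well separated — as the calibrated geometry
is.

Each sex is clustered separately and the sub-model partitions are pooled. If
the two strata select different k, the larger stratum's k is imposed on both
with a warning, reflecting the expectation of one common cluster structure.
With k = 4, de-normalized centers are named deterministically: highest
glucose AUC = LMO; of the rest, highest insulin AUC = HMO-I; of the
remaining two, highest uric acid = HMO-U; the last is MHO. Centers are
stored in raw units together with the normalization parameters, making the
model portable; for other k the clusters get generic names sorted by
glucose then insulin AUC.

The published selection criterion is described as "minimum silhouette
widths"; this package maximizes mean silhouette, since minimizing it would
select the worst clustering — the phrase is read as a typo for the universal
convention. Both silhouette (k-means) and BIC (two-step) criteria are
exposed.

## Cross-cohort validation

New patients are assigned to the model stratum matching their sex, using the
model's stored normalization (not the new cohort's own means/SDs — required
for a portable model; own-cohort normalization would make assignments depend
on the cohort a patient arrives in). Distance is Euclidean in normalized
space for k-means models; for two-step models it is the log-likelihood
distance increment from adding the single point to each stored cluster,
computed from the per-cluster counts and within-variances. Ties break toward
the lower-index center.

Agreement between an independent clustering (reference) and model assignment
uses an optimal one-to-one label matching (Hungarian assignment on the
contingency table) rather than center-to-center matching, which is fragile
when centers drift between cohorts. Metrics are per-cluster one-vs-rest:
accuracy (TP+TN)/n, sensitivity TP/(TP+FN), specificity TN/(TN+FP), and the
Jaccard coefficient |A∩B|/|A∪B| on member sets, each averaged over clusters.
"Accuracy" is per-cluster one-vs-rest because that is the only reading that
produces one accuracy value per cluster. Zero-denominator cases are NaN with
explicit flags, never silent zeros.

## Comorbidity statistics

Adjusted odds ratios come from binary logistic regression (IRLS via
statsmodels GLM, convergence 1e-8 within 50 iterations) of each comorbidity
on subtype dummies (MHO reference) plus a female indicator and age in years
entering linearly. AOR = exp(β) with Wald 95% CI exp(β ± 1.96·SE) — Wald
rather than profile likelihood, matching mainstream clinical software
defaults. Complete or quasi-separation (|β| > 15 or non-finite covariance)
is flagged on the result, with the CI widened to (0, ∞) when the Wald bound
is meaningless, instead of raising. Records with an unknown comorbidity
state are dropped per comorbidity (complete-case analysis). Chi-square is
Pearson's statistic without continuity correction. Group comparisons are
one-way ANOVA, or ANCOVA with covariates as linear terms, on optionally log-
or sqrt-transformed values; the transform is configuration, not automated
normality testing. Pairwise contrasts are refit per pair with raw p
multiplied by the number of pairs, capped at 1 (Bonferroni).

## Synthetic-data generator

The generator draws each patient's sex (55% female), subtype (multinomial
with weights 0.44/0.33/0.08/0.15), and feature vector from a per-sex normal
centered on the published cluster centers with diagonal within-cluster SDs
(70 mmol/L·min glucose AUC, 3500 mU/L·min insulin AUC, 35 μmol/L uric acid),
truncated to positive values. These SDs are a generator assumption chosen so
nearest cluster centers sit ≥ 2.5 within-SDs apart, consistent with the
clean silhouette structure the subtyping assumes; real within-cluster
dispersions are not published. Within-cluster correlations are zero by
default because only centers are published.

OGTT curves are built as fasting + s·template with fixed non-negative shape
templates over the grid — glucose (0, 1, 1, 0.5), insulin (0, 0.7, 1, 0.45),
insulin peaking later — where s is solved in closed form from the trapezoid
weights so the curve integrates exactly to the drawn AUC; multiplicative
per-point noise (SD 3% for glucose, 20% for insulin, reflecting the much
larger assay and pulsatility noise of insulin measurements) is applied and
the curve rescaled to preserve the AUC exactly. The noise asymmetry is what
makes imputation quality land in the published order (glucose fits better
than insulin). Fasting glucose is subtype-dependent (≈5.2–5.4 mmol/L, 7.8
for LMO) so the secondary indices order the subtypes realistically —
notably a far lower disposition index in LMO than MHO. Age is log-normal
with median ≈ 29 y; BMI is cosmetic. Comorbidity flags follow a logistic
model with per-subtype log-odds shifts echoing the published directions
(diabetes concentrated in LMO, hyperuricemia in HMO-U), plus small sex and
age effects.

What passing on generator data shows: the machinery — normalization,
clustering, k selection, labeling, assignment, matching, metrics, stepwise
selection, logistic recovery — is correct under the published geometry. What
it does not show: performance on real cohorts, whose within-cluster
dispersions, correlations, non-Gaussian tails and measurement artifacts are
unknown; the published real-data medians and odds ratios are therefore not
reproduction targets, only directions.

## Problem sizes and numerical conventions

Default desk-scale runs use a main cohort of n = 882 and verification
cohorts of n = 300, with k searched over 2–8. The end-to-end pipeline at
these sizes runs in seconds. Exhaustive-oracle checks (optimal k-means
WCSS, greedy agglomeration) run at n ≤ 10 where enumeration is exact.
All stochastic operations take an explicit seed; fits are invariant to
input record order (strata are sorted by patient id before clustering).
Cohort I/O validates totally: every malformed cell is reported with row and
column context, zeros are values (never missing), and units are fixed by
the schema with no conversion on input.

## Known limitations

- The three clustering variables are taken as given; the variable-selection
  experiment that produced them is out of scope.
- Point-estimate imputation only; no multiple imputation or uncertainty
  propagation into clustering.
- Two-step supports continuous variables only, and its minimum-BIC k
  selection can over-split loosely dispersed data (see above).
- No bootstrap stability curves; stability is single-split Jaccard.
- The subtype naming rule presumes exactly four clusters; other k fall back
  to generic names.
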