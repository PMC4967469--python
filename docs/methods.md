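# Methods

This note documents the models, numerical choices and limitations of
pharmacoscape, in the spirit of a statistical software methods appendix.
Everything stated here is computed by the test suite or
`scripts/acceptance.py`; no empirical claim below goes beyond what those
runs measure.

## Data model

The universal feature object is the binary alteration matrix: samples ×
CFEs with entries 0/1/NA. CFEs (cancer functional events) are opaque
identifiers tagged with a class — CG (driver-gene mutation), RACS_amp /
RACS_del (recurrent copy-number gain/loss), iCpG (hypermethylated
informative CpG island), fusion, or pathway_activity. Catalogs carry
per-(CFE, cancer type) tumor frequencies and act as the filter applied
to cell-line alterations: filtering restricts and reorders columns to
the catalog, inserting all-zero columns (reported) for catalog CFEs the
panel never shows. Missing entries propagate as NA and are excluded
sample-wise per test downstream, matching the per-test complete-case
regression.

Drug response is summarized per (drug, cell line) as ln IC50 (natural
log µM) and AUC in [0, 1] (1 = no effect), with one maximal tested
concentration per drug. A line is *sensitive* to a drug when its IC50 is
at or below the maximal tested concentration (inclusive).

## iCpG detection and methylation binarization

An island is *informative* when a 2-component Gaussian mixture on
logit-transformed beta values beats the 1-component model by BIC, the
component means are ≥ `min_separation` (default 1.0 logit units) apart,
and both weights are ≥ `min_component_weight` (default 0.05). The
discretization threshold is the equal-posterior point between the two
means, found by root-finding on the fitted mixture and mapped back to
the beta scale; binarization is strictly `beta > threshold` so boundary
behavior is deterministic. Mixture fits use 5 restarts with a fixed
random state, making detection deterministic. Constant vectors and
samples with n < 30 are rejected up front. The criterion itself (BIC +
separation + weight floor) is this package's design choice for an
otherwise unspecified multimodality test; it is parameter-light and
reproducible, but it is tuned to logit-scale Gaussianity and will
over-call distributions that are heavily skewed on that scale.

## Dose–response summarization

Each curve is fit by least squares to a 2-parameter logistic
`v = 1/(1 + exp(slope (ln c − ln IC50)))` with asymptotes fixed at 1 and
0 — the minimal identifiable summary for 5–9-point curves. The optimizer
is a deterministic multi-start (slope ∈ {0.5, 1, 2, 4} × ln-IC50 starts
at the tested-range quartiles, Levenberg–Marquardt refinement). ln IC50
is unconstrained; fits above the maximal tested concentration carry an
`extrapolated` flag and are used as fitted by default (capping is left
to the caller as a sensitivity analysis). AUC is the closed-form mean of
the fitted logistic over the tested log-concentration interval, clipped
to [0, 1]. Replicate concordance reports Pearson r over shared lines and
a one-sided Fisher exact test (log10 p) on the 2×2 table of
sensitive/resistant calls.

## ANOVA association scan

Per (drug, CFE): OLS of ln IC50 on an intercept, one-hot covariates
(cancer type and MSI pan-cancer; MSI only cancer-specific, which
requires > 15 lines of the type), and the CFE indicator added last;
p from the nested-model F-test (equal to the pooled-variance t-test,
F = t², when no covariates remain). Minimum group size is 3 positive and
3 negative complete cases — the smallest size with a defined variance.
CFEs collinear with the covariates (e.g., perfectly confounded with
tissue) are skipped and logged. BH FDR is computed within each scan (one
pan-cancer scan; one per cancer type), not pooled. Gates: significant =
p < 10⁻³ ∧ FDR < 25%; large-effect additionally requires both Glass
deltas > 1. Direction is the sign of the carrier-minus-noncarrier mean
difference; negative = sensitizing.

Implementation note: columns without missing values share the drug's
covariate design, so the scan residualizes response and all complete CFE
columns against the covariates once per drug and forms the added-last
F-statistics from the partial correlations (rank-aware via SVD
least-squares); columns with missing calls fall back to the per-test
path. The two paths are tested for exact agreement, and the fast path is
verified against statsmodels' nested-model F-test. Results are computed
on a sorted sample/CFE order, so the scan is invariant to input row and
column ordering.

A known calibration fact documented by the acceptance suite: over m
independent null tests, BH at FDR q rejects at least one hypothesis with
probability exactly q (Simes' lemma), so ~25% of fully null scans at
q = 0.25 contain a false "significant" hit; the type-I rate per test
stays at the nominal 5%.

## Logic models

Binarization at θ (default ln of the maximal tested concentration,
configurable) labels lines sensitive (IC50 ≤ θ); weights are
|ln IC50 − θ| normalized to sum to 0.5 within each class, so the
objective is balanced and a line exactly at θ carries zero weight.
The optimizer enumerates every K-clause, M-literal two-level formula
(DNF = OR of ANDs by default; CNF available), with negated literals,
distinct features within a clause, and clause reuse allowed so the
complexity classes are nested. Feasibility requires training specificity
≥ 0.8; if no candidate is feasible a flagged null model (all-resistant)
is returned. Ties break toward fewer distinct features, then
lexicographic feature ids, then the canonical clause list — the search
is fully deterministic. Enumeration is exact (tested against a direct
truth-table oracle on every complexity), vectorized over candidate
formulas, and optionally restricted to the top-F features by
single-literal weighted accuracy (default F = 25) to bound cost at scan
scale.

Complexity is selected from the eight candidates
{(1,1), (1,2), (2,1), (1,3), (3,1), (1,4), (4,1), (2,2)} — the symmetric
family of ≤ 4-input two-level models — by repeated stratified 5-fold CV;
the CV error of a fold is the held-out weighted misclassification with
weights re-derived within the held-out fold (a fold degenerating to one
class weights that class to 0.5). The drug-level precondition is ≥ 5
sensitive lines; inside CV folds models are fit on whatever sensitive
lines the fold provides. Permutation significance permutes the IC50
vector and reruns the entire CV selection; p = (1 + #{perm ≤ obs}) /
(n_perm + 1). The recovery experiments use repeats = 1 and n_perm = 39
(minimum attainable p 0.025); production runs default to 100
permutations with BH FDR over drugs at 5% for the "predictive" call.
Feature importance is the inclusion frequency of each feature in the
fold models at the selected complexity (plus the final refit),
normalized to sum to 1 and aggregable by CFE class.

## Multi-omic prediction scan

Feature views (binary alteration blocks, standardized expression,
one-hot tissue) are concatenated per combination; every non-empty
combination is fit independently (tissue is a candidate view pan-cancer
only). Models are elastic net (alpha path tuned on inner 5-fold CV,
l1_ratio ∈ {0.2, 0.5, 0.9}) or random forest (200 trees, leaf ≥ 3), with
5 outer folds collecting held-out predictions; ≥ 40 complete cases
required. Performance is the pooled observed-vs-predicted Pearson r
computed after centering both vectors within each outer fold: raw
pooling is negatively biased under a null response because held-out
predictions track training-fold means, which anti-correlate with
held-out fold means; within-fold centering removes that artifact and
leaves genuine signal essentially unchanged.

The predictiveness threshold is either the fixed defaults (0.21
pan-cancer, 0.25 cancer-specific) or re-derived from the empirical r
distribution: a 2-component Gaussian mixture is fit, the higher-mean
component is taken as informative, and the threshold is the smallest r
from which the posterior odds informative:non-informative stay ≥ 9
(first sustained crossing on a dense grid, refined by root-finding).
Indistinguishable components (BIC prefers one Gaussian) yield +inf with
a warning. The lead model per drug is the predictive model with maximal
r; ties prefer fewer data types, then lexicographic order.

## Concordance and stratification

Frequency profiles are per-(cancer type, cohort) column means over
non-missing entries. Nearest-neighbor tissue matching ranks the other
cohort's profiles by correlation distance (1 − Pearson over shared CFEs)
and pools both directions (cell→tumor and tumor→cell) into one top-k
accuracy. Pathway concordance correlates, per pathway, the per-type
fraction of samples with ≥ 1 altered member CFE across cohorts. The
global class of a sample is the argmax of its per-class alteration count
normalized by the cohort-wide mean count for that class (CG→M, iCpG→H,
RACS_del→CD, RACS_amp→CA; ties and modal ties resolve by the fixed
priority M > H > CD > CA); this burden-argmax rule is a documented
stand-in for a full enrichment clustering. The stratification landscape
reports, per cancer type, the percentage of tumors carrying ≥ 1
sensitizing single-CFE marker and, separately, satisfying ≥ 1
sensitivity logic rule.

## Synthetic-data generator

All generators are pure functions of (config, seed) via numpy's
`default_rng`; identical seeds give bitwise-identical outputs.

* **Cohorts.** Per cancer type, every CFE is an independent Bernoulli
  draw at its configured frequency, identically for tumors and cell
  lines — shared frequencies are exactly the recoverable signal the
  concordance analyses assume. MSI status is Bernoulli (default 5%).
* **Defaults.** The bundled default configuration is desk-scale: 8
  cancer types × (120 tumors, 30 cell lines), 40 CFEs (20 CG, 8+8 RACS,
  4 iCpG) with per-type frequencies drawn once from a long-tailed
  Beta(0.8, 4) rescaled to [0.02, 0.9] (skewed like real driver
  frequency spectra, distinct across types so tissue is recoverable), 12
  drugs with baseline ln IC50 ~ N(2, 1), noise 0.8 ln-units, max
  concentration 10 µM, one planted additive effect (β = −2) and one
  planted OR rule (β = −2).
* **Responses.** ln IC50 = baseline + Σ additive β·indicator + Σ logic
  β·satisfaction + N(0, σ). The AUC column is filled analytically from
  the planted ln IC50 with a nominal slope-1 curve over the drug's
  9-point 2-fold dilution range.
* **Raw curves.** Per (drug, line), a 2-parameter logistic at the
  table's ln IC50 with a log-normal slope (sd 0.25 on the log scale),
  Gaussian viability noise clipped to [−0.1, 1.2] mimicking plate-reader
  artifacts.
* **Methylation.** Logit-normal beta values: informative islands mix
  components at logit(0.1) and logit(0.8) (sd 0.5 logit units, weight
  0.35–0.65), non-informative islands are unimodal at a low-to-moderate
  level. Ground truth records flags and component parameters.
* **Concordance fixtures.** The class-concordance experiments
  additionally plant a predominant CFE class per cancer type (frequency
  0.4–0.9 for the dominant class vs 0.02–0.25 otherwise), emulating the
  real-world pattern that tumor types are dominated by one alteration
  class; without a dominant class the modal class is undetermined and
  its cohort agreement is not a meaningful recovery target.

What the generator does **not** emulate: linkage/co-occurrence between
CFEs beyond independence, panel composition bias, screening batch
effects, heavy-tailed or heteroscedastic IC50 noise, probe-level
methylation structure, or realistic expression networks (expression is
tissue-shifted white noise). Passing recovery tests therefore
demonstrates correctness and calibration of the estimators under the
stated generative assumptions, not robustness to real-data artifacts.

## Problem sizes and numerical choices

Experiments run at sizes chosen to make the statistical properties
measurable on a single CPU in minutes: 10,000 single tests for type-I
calibration; 20 null scans of 50 drugs × 40 CFEs; 100 runs of the
planted-additive recovery (30 carriers of 300 lines); 50 runs of the
planted-OR recovery (n = 300, 8 features, noise 0.5, CV repeats 1,
39 permutations); 50 random instances (≤ 30 samples, ≤ 6 features) for
exhaustive-oracle equivalence across all eight complexities; 100 noisy
curves for inversion error; 2,000 r values for threshold recovery; 20
seeds of 6-type matched cohorts for concordance.

Floating-point ties in the logic search are resolved with a 1e-12
tolerance before the deterministic tie-break; curve fits report
rmse = +inf on total failure rather than raising; logit transforms clip
betas to [1e-4, 1 − 1e-4]; Fisher p-values are floored at 1e-300 before
log10.

## Known limitations

* The ANOVA is OLS-based; no robust or mixed-effects variants.
* The logic-model search is exact but exponential in (K, M); the
  prefilter bounds cost at the expense of exactness outside the top-F
  features (exactness is guaranteed, and tested, for ≤ F features).
* The per-curve logistic deliberately ignores information sharing
  across cell lines; IC50s far above the tested range are extrapolations
  with large variance, retained but flagged.
* Cancer-specific scans need > 15 lines; rarer types are simply not
  testable at desk scale.
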