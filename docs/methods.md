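# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical conventions that make results
reproducible.

## Data model

The unit of analysis is a longitudinal cohort: each patient contributes a
baseline visit (time 0 by definition) and two or more follow-up visits at
real-valued times measured in years from that patient's own baseline, not
calendar dates.  Abundances are positive relative quantities on an
arbitrary per-metabolite scale; missing measurements are explicit (NaN).
Covariates are age at baseline (years), sex (0/1, female = 1) and prior
disease-modifying-therapy history (0/1).  The coding of the binary
covariates only flips coefficient signs; it never changes test decisions.

## Preprocessing

* **Missingness filter.** A metabolite is removed when its missing
  fraction is *strictly greater* than `missing_frac_max` (default 0.30);
  a metabolite missing in exactly 30% of samples is retained.
* **KNN imputation** (default k = 10).  Neighbors are metabolites, the
  usual convention for omics feature matrices.  The distance between two
  metabolites is the root-mean-square difference over the samples where
  both are observed — dividing by the shared-sample count makes metabolites
  with different missingness patterns comparable — and pairs sharing no
  samples are non-neighbors.  A missing entry becomes the unweighted mean
  of the k nearest metabolites observed in that sample; with fewer than k
  available, those available are used; with none, the metabolite's own
  observed median.  Distance ties break by metabolite id, so imputation is
  deterministic.  Observed values are never modified, and imputing an
  already-complete table is the identity.
* **Normalization.** Each metabolite is divided by its own median across
  samples (post-scaling median exactly 1, checked to 1e-12) and natural-log
  transformed.  Imputation runs on raw abundances *before* scaling; the
  alternative order is a configuration switch but not the default.

## Correlation-network modules

The network is built on the complete normalized matrix: pairwise Pearson
correlation `r`, soft-thresholded to an adjacency `a = |r|^β` (unsigned,
default) or `a = ((1+r)/2)^β` (signed), with β = 12.  β is treated as a
fixed protocol parameter; scale-free-fit selection is out of scope.

Adjacency is converted to the topological overlap measure

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu a_uj,   k_i = Σ_{u≠i} a_iu,

which rewards shared neighborhoods and is less noisy than raw adjacency.
Modules are branches of an average-linkage dendrogram on `1 − TOM`, cut at
a fixed height, with clusters below `min_module_size` (default 10) labeled
grey (unassigned).  Detected modules are named by the conventional
size-ordered color palette (turquoise, blue, brown, ...).

**Static cut height.**  A fixed cut at 0.9995 replaces the dynamic hybrid
tree cut of the canonical implementation.  The value follows from the
geometry of soft-thresholded networks at β = 12: metabolites correlated at
ρ ≈ 0.6 have adjacency ≈ 0.6¹² ≈ 2·10⁻³ and within-module TOM of the same
order, so their merge heights cluster just below 1 − 2·10⁻³·(module size
factor) ≈ 0.999, while unrelated metabolites (TOM ~ 10⁻⁷) merge at heights
indistinguishable from 1.  A cut at 0.9995 separates those two regimes; a
cut at 0.995 would sit *below* the within-module merge heights and leave
genuine modules unassigned.  The static cut is simpler and fully
deterministic; its known cost is less adaptivity for modules with very
heterogeneous internal correlation (see Limitations).

**Eigen-metabolites.**  Each module is summarized by the first principal
component of its standardized (mean 0, SD 1, ddof = 1) member profiles,
rescaled to unit variance.  Because a principal component's sign is
arbitrary, scores are oriented to correlate non-negatively with the mean
standardized member profile; a single-member module's eigen-metabolite is
that standardized metabolite.  The score is provably the variance-
maximizing unit-norm linear combination (tested against brute-force
eigendecomposition).  Module membership (kME) is the Pearson correlation
of each metabolite with each eigen-metabolite.

## Longitudinal trend model

Every feature (metabolite or eigen-metabolite) is tested with the same
random-intercept model

    y_ij = β0 + β1·t_ij + β2·age_i + β3·sex_i + β4·DMT_i + b_i + ε_ij,
    b_i ~ N(0, σ²_b),  ε_ij ~ N(0, σ²_e),

i.e. one shared per-patient intercept and a common per-year slope β1,
the quantity of interest.  No random slope is fit: with ~30 patients and
3–5 visits a random slope is weakly identified and the fixed-slope model
is the minimal one consistent with repeated measures.

Fitting is by REML.  The variance ratio θ = σ²_b/σ²_e is profiled over a
bounded 1-D optimization (Brent on [0, 1e5], with θ = 0 checked
explicitly); at each θ, β is the GLS solution using the closed-form
within-group inverse `I − θ/(1 + n_i θ)·J`, which keeps each evaluation
O(n).  The profiled REML criterion `(N−p)·log RSS + Σ log(1+n_i θ) +
log|X'WX|` is unimodal in practice; a regression test verifies the
returned optimum against a 100-point grid.  The residual sum of squares is
floored at 1e-12 so noise-free inputs degrade gracefully.

Inference on β1 uses the Wald normal approximation (CI = estimate ±
1.96·SE; p from the normal tail).  Satterthwaite or Kenward–Roger degrees
of freedom are not used; at the design sizes targeted here the difference
is small, and the simulation suite verifies 95% CI coverage within
[0.92, 0.98] and type-I error within [0.03, 0.07] at the study scale
(31 patients × 4 visits, σ_b = 0.3, σ_e = 0.2).

P-values from the per-metabolite scan are adjusted by the
Benjamini–Hochberg step-up procedure across the scanned features.  The
clinical/quality-of-life models are exploratory and reported unadjusted.

## Pathway enrichment

Metabolites are ranked by `s_m = sign(β1)·(−log10 p)` (p floored at the
smallest positive double; ties broken by id).  Ranking by p-value alone
would discard direction, yet enrichment is reported as up- or
down-regulation, so the sign of the estimate must enter; this signed
statistic is the minimal choice consistent with both requirements.  For a pathway (sub-pathway granularity, minimum 5
scanned members) the enrichment score is the signed maximum deviation of
the weighted Kolmogorov–Smirnov running sum: hits add `|s|^w / Σ_hits
|s|^w` (w = 1 default; w = 0 gives the classic unweighted statistic),
misses subtract `1/(N − n_set)`.

The null is metabolite-label permutation: random same-size sets from the
ranked list (the ranking comes from per-feature models, so a phenotype/
sample permutation is unavailable at this layer).  With `n_perm` draws
(default 1000): nominal `p = (1 + #{same-sign |ES*| ≥ |ES|}) / (1 +
#same-sign)` — add-one corrected so p is never 0 — and `NES = ES /
mean(|ES*| among same-sign permutations)`, which calibrates scores across
set sizes.  Because the null depends only on the set size, it is computed
once per distinct size and shared across pathways; this is identical in
distribution to per-pathway resampling and deterministic given the seed.
BH adjustment is applied across pathways; the table is sorted by |NES|.

## Disability and quality-of-life outcomes

Endpoints compare each patient's baseline against the *last available*
visit.

* **EDSS-Plus improvement**: EDSS decrease ≥ 1.0 from baseline ≤ 5.5, or
  ≥ 0.5 from baseline > 5.5, or a time reduction ≥ 20% in any of T25FW,
  9HPT-dominant, 9HPT-non-dominant.
* **ODRS**: per-component +1 / 0 / −1.  The EDSS component uses the
  EDSS-Plus improvement thresholds and, for worsening, the same magnitudes
  mirrored as increases (the literal reading of "the same improvement or
  worsening threshold"; a conventional 1.5/1.0/0.5 progression
  stratification is *not* applied).  Timed components score ±1 at a 15%
  reduction/increase.  The total ranges over [−4, +4]; improvement is a
  strictly positive total.
* All threshold comparisons are inclusive ("at least", "or more") with an
  absolute tolerance of 1e-9 against floating-point representation of
  percentages.
* **Wilcoxon signed-rank** (EDSS change): zero differences dropped,
  midranks for tied magnitudes, W = positive-rank sum.  The two-sided
  p-value is exact — the sign-assignment distribution built by convolution,
  equivalent to enumerating all 2^n assignments — whenever the effective n
  ≤ 15 (midranks make the enumeration exact under ties too); beyond that, a
  normal approximation with tie-aware variance (Σr²/4) and continuity
  correction.
* **Neuro-QOL improvement**: a favorable-direction T-score change strictly
  greater than the item's minimal detectable change.  The shipped MDC
  table is a placeholder (5.0 T-score points per item, marked
  non-canonical in the source); real analyses must supply the published
  conditional MDC values via configuration.  Item directions follow the
  instrument (e.g. higher anxiety/stigma = worse; higher cognitive
  function = better).

## Metabolome–clinical association

Per-patient deltas (last − baseline, on processed values or eigen-metabolite
scores) are standardized across patients to unit sample SD, so logistic
coefficients are per-SD effects.  The improvement model is

    logit P(improved_i) = γ0 + γ1·Δfeature_i + γ2·age_i + γ3·sex_i
                          + γ4·followup_i + γ5·DMT_i,

fit by iteratively reweighted least squares (deviance tolerance 1e-8, max
100 iterations); the reported effect is OR = exp(γ1) with a Wald 95% CI.
"Years of follow-up" is the patient's last visit time.  Complete
separation — diverging coefficients or perfect classification — is flagged
and the feature is reported without an OR rather than rescued (no Firth
penalty).  Zero-variance deltas are excluded as non-informative.

Partial Spearman correlation between eigen-metabolite deltas and neuro-QOL
item deltas: all variables are rank-transformed (midranks), the ranked x
and y are residualized on the ranked covariates plus intercept by least
squares, rho is the Pearson correlation of the residuals, and p comes from
`t = rho·√((n−2−k)/(1−rho²))` on `n−2−k` degrees of freedom.  With no
covariates this reduces exactly to ordinary Spearman correlation.

## Synthetic cohort generator

The generator emits the full input bundle plus ground truth.  Defaults are
the study conditions the pipeline targets: 31 patients, 4 visits at ≈0, 1,
2, 3 years (uniform ±0.15-year jitter on non-baseline visits, matching
roughly-annual sampling), 300 metabolites with planted modules of sizes
40/30/25/20 at within-module correlation 0.6, per-year log-scale slopes
−0.10 and −0.12 on the two largest modules, 10% missingness of which half
is left-censored, age ~ N(41, 10²), P(female) = 0.68, P(prior DMT) = 0.71,
improvement prevalence 0.29, and an odds ratio of 0.3 per SD linking the
second module's change to improvement.

On the log scale, metabolite m of module M for patient i at visit j is

    x_mij = μ_m + λ_m·f_Mij + b_mi + δ_M·t_ij + ε_mij

with a shared per-(module, patient, visit) factor f ~ N(0,1) whose loading
λ = √(ρ/(1−ρ))·σ_w induces within-module correlation ≈ ρ over the
patient-intercept (σ = 0.2) and residual (σ = 0.2) noise; abundances are
exp(x), hence positive and log-normal — consistent with the pipeline's log
transform.  Missingness mixes left-censoring (masking within each chosen
metabolite's lowest ~30% of values) with completely-random masking; the
real mechanism in untargeted metabolomics is unknown, so the censored
share is a configurable assumption.  Improvement labels are drawn from a
logistic model in the standardized target-module factor-trajectory change,
and clinical trajectories are then constructed so that labeled-improved
patients meet the ODRS-positive condition at the final visit and others do
not — the outcome stage is consistent by construction, which is what makes
label-recovery tests meaningful.

What the generator does **not** emulate: batch effects and instrument
drift, heteroscedastic or intensity-dependent noise, correlated module
overlap (planted modules are disjoint), informative dropout, relapses or
non-monotone disability trajectories, and real neuro-QOL correlation
structure (items drift independently).  Passing recovery tests therefore
demonstrates correctness of the algorithms under the assumed generative
model, not robustness to every artifact of real metabolomics data.

## Numerical conventions and determinism

Every stochastic stage takes an explicit seed and refuses to run without
one; two runs with the same inputs, configuration and seed produce
byte-identical output files (verified end-to-end in the test suite).
Deterministic tie-breaks: metabolite id order in the imputer, stable size-
then-first-member ordering for module colors, id-lexicographic ordering in
the ranked list.  Degenerate inputs are handled explicitly: zero-variance
metabolites are rejected before network construction, all-grey partitions
produce empty (not missing) downstream tables, separated logistic fits are
flagged, and a non-positive TOM denominator yields 1.

## Problem sizes used in validation

The calibration suites run at the design scale of the target study:
module recovery over 20 seeds of the default 31×4×300 cohort; mixed-model
bias/coverage over 500 replicates; permutation-test calibration over 200
seeds of 20 disjoint size-5 pathways; odds-ratio recovery at 500 patients
(a deliberately scaled-up power check — at n = 31 the OR is recovered in
direction but with wide intervals, as expected).

## Known limitations

* The static tree cut trades the adaptivity of the dynamic hybrid cut for
  determinism; modules whose internal correlation varies strongly may be
  split or partially assigned to grey near the cut height.
* Wald-normal inference in the mixed model and logistic model is
  approximate at very small n; the simulation suite bounds the error at
  the supported design sizes but extreme designs (2–3 patients) are
  rejected rather than supported.
* The eigen-metabolite summarizes only the first principal component;
  modules with substantial secondary structure lose information.
* The enrichment null permutes metabolite labels, not samples, so it tests
  ranking concentration given the observed statistics rather than a full
  resampling of the longitudinal design.
* The shipped neuro-QOL MDC values are placeholders, not the published
  conditional MDCs.
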