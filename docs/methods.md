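# Methods

This note documents the models, numerical choices, and limitations behind
`metaboclock`, in the order the pipeline runs them.

## Synthetic data generator

The generator (`metaboclock.synthetic`) emulates a two-regime
experimental-evolution metabolomics design on a latent log-abundance scale.
For sample *i* (regime *r*, history *h*, replicate *p*, age *t*, batch *b*)
and metabolite *j*:

```
latent_ij = baseline_j
          + [age-responsive_j]     · s_j·m_j · slope_r · (t − t̄)
          + [regime-responsive_j]  · s_j·m_j · regime_effect · 1{r=A}
          + [interaction_j]        · s_j·m_j · interaction_slope · (t − t̄) · 1{r=A}
          + [history-responsive_j] · s_j · history_effect · (±1{h=recent})
          + replicate_pj + batch_bj + ε_ij
```

with `s_j ∈ {−1, +1}`, `m_j ~ U(0.5, 1.5)`, `baseline_j ~ N(4, 1)`,
`replicate_pj ~ N(0, replicate_sd²)`, `batch_bj ~ N(0, batch_sd²)`,
`ε ~ N(0, residual_sd²)`, and `t̄` the mean of all sampled ages (centering
keeps the exponentiated values well-scaled). Emitted abundances are
`exp(latent)`, so the pipeline's log transform operates on a positive,
peak-area-like scale.

Defaults are the study conditions: 202 metabolites; 2 regimes × 2 selection
histories × 5 replicate populations; accelerated (A) populations sampled at
9/21/28/35 days from egg and controls (C) at 21/28/35/70, giving 80 pooled
samples; 3 LC-MS batches. Effect parameters have no published values, so
they were fixed once at values a metabolomics practitioner would call
realistic for pooled fly samples and are not tuned per analysis:
`slope_A = 0.04`, `slope_C = 0.02` log-units/day (the regimes' 2:1 aging
ratio), `regime_effect = 0.5`, `interaction_slope = 0.02`,
`batch_sd = 0.3`, `replicate_sd = 0.15`, `residual_sd = 0.15` (pooling ~50
flies per sample suppresses biological noise; pooling is modeled only as
this reduced residual SD, not as explicit individuals), 40% of metabolites
age-responsive, 30% regime-responsive, 10% interacting. Day-9 A samples
receive an extra "post-eclosion" offset (`eclosion_effect = 1`, random 30%
of metabolites) so the downstream exclusion logic has a physiologically
distinct group to exclude. The history effect defaults to 0 — the
convergence null — and, when nonzero, enters with opposite signs in the two
regimes so it is specifically a regime × history interaction, the term the
divergence test targets.

Mortality is simulated per cage cohort (two per replicate population,
pooled downstream) from a discrete Gompertz hazard
`P(death on day d) = min(1, b·e^{g·d})` with binomial daily death counts;
every fly dies by the end of the series. The network generator plants
pathway nodes with dedicated member metabolites, bridges consecutive
pathways through one member each, and attaches background metabolites to
random existing metabolites, yielding a single connected component with
known memberships for recovery tests.

What the generator does **not** emulate: missing-at-random peak dropout
(completeness filtering is exercised by tests, not by the default
generator), heavy-tailed peak-area noise, correlated metabolite modules,
batch × metabolite interactions, or real KEGG topology. Passing tests
therefore demonstrate correctness of the estimators under the declared
generative model, not robustness to every pathology of real LC-MS data.

## Normalization

Order fixed as filter → natural log → within-sample (row) mean-centering →
per-metabolite batch residualization (categorical main effect by least
squares, equivalent to subtracting per-batch means). Natural log is used;
downstream inference is base-invariant up to scaling. Row means after
centering and per-batch means after residualization are zero to 1e-9.
Singleton batches are refused rather than silently zeroed. The technical CV
uses the sample (n−1) standard deviation. Missing metabolites are dropped,
never imputed.

## Convergence tests

PCA is computed on the covariance matrix (metabolites centered, not
rescaled) of the normalized table restricted to ages sampled in both
regimes (21/28/35). Each of the first 12 components is modeled as
`score ~ age × regime × history + (1 | replicate)` with age an unordered
categorical factor; the replicate intercept is a true random effect
estimated by maximum likelihood, and term p-values are hierarchical
likelihood-ratio chi-square tests (each term against the model containing
all terms of equal or lower order minus that term). Rank-deficient dummy
expansions (an age present in only one regime) are pruned by pivoted QR and
LRT degrees of freedom use the actual ranks. When the iterative optimizer
ends near the replicate-variance boundary, the exact zero-variance (OLS)
candidate is also evaluated and the higher likelihood kept — maximum
likelihood over the closed parameter space.

Divergence is declared if any tested component shows a regime × history or
regime × history × age effect at **unadjusted** p < 0.05 — a deliberately
liberal any-of-24-tests rule whose null firing probability is high by
construction (~90% measured; ≥ 1 − 0.95²⁴ ≈ 71% for any correctly sized
per-test procedure), so a *negative* result is strong evidence of
convergence while a positive one is weak evidence of divergence. The
per-term chi-square type-I rate is close to nominal (~9% at 20 replicate
groups; chi-square LRTs are mildly anti-conservative at this group count).
Main effects are additionally reported with Bonferroni correction over the
components tested.

The regime discriminant is a two-component PLS regression on class codes
{0 = C, 1 = A}, with the continuous prediction clipped to [0, 1] as the
class-A probability and thresholded at 0.5 — the simplest faithful
two-class PLS-DA. Training accuracy and the ROC/AUC are computed from
seeded, regime-stratified 5-fold cross-validated predictions on the
training partition; the deployed projection is refit on all training
samples. Feature weights are reported per standardized metabolite unit.

## Clocks and age acceleration

A clock is an elastic-net regression of age (numeric days from egg) on
metabolite abundances standardized to unit variance within the training set
(training parameters reused on held-out samples, preserving leakage
freedom). The penalty pair (L1 fraction, strength) is selected by seeded
5-fold CV RMSE from a dense grid: mixing 0.1–1.0 in steps of 0.1 × 100
penalty strengths log-spaced four decades down from λ_max (the smallest
penalty zeroing all coefficients). Within-regime predictions use
leave-one-replicate-out: for each replicate population a clock is fit on
the rest (CV seeded as `seed + replicate index`) and predicts the held-out
replicate, so every sample's prediction comes from a model that never saw
its replicate; the leakage-freedom property is recorded and asserted
structurally. Between-regime clocks are fit on all samples of one regime
and predict only the other. Day-9 A samples are excluded from all clock
fitting and prediction via an explicit exclusion list (default {(A, 9)}).
With the default design this leaves 30 A and 40 C samples; each C LORO
iteration trains on 36 samples, each A iteration on 27.

The acceleration model `predicted_age ~ α + β₁·age + β₂·mode + β₃·age·mode`
(mode = 1 for between-regime predictions) is ordinary least squares with
conventional t-tests; all available non-excluded ages enter even where the
age ranges differ between regimes (C day 70 has no A analog). Feature-set
comparison between two clocks uses the 2×2 membership table over the shared
panel (Fisher's exact test; the reported odds ratio is the sample
cross-product estimate), Pearson correlation of shared-feature coefficients
(defined only for ≥ 3 shared features), and two-sided rank-sum tests of
|β| for shared vs clock-unique features.

## Trajectories and clustering

Each metabolite's normalized abundance is modeled as
`value ~ regime + age + regime×age + (1 | replicate)` with age categorical
(the design samples discrete timepoints), fit by ML with the same boundary
handling as above. Term tests are likelihood-ratio: interaction = full vs
main-effects; age = main-effects vs regime-only; regime = main-effects vs
age-only. BH adjustment is applied per term across metabolites and flags
set at q < 0.01. Non-converging metabolites are flagged and excluded from
adjustment rather than failing the run. Day-9 A samples are excluded from
the models but retained in the group-mean matrix used for clustering and
display.

Cluster count selection and assignment deliberately follow a two-step rule
that mixes objectives: K is chosen by Lloyd K-means (25 seeded restarts per
K, minimum WSS kept) as the K maximizing the discrete second difference of
the WSS curve, ties toward smaller K; assignments then come from cutting a
complete-linkage Euclidean dendrogram into K groups. The WSS curve is
monotone non-increasing up to restart noise (~1% tolerance). Group-mean
profiles enter unscaled — they are already normalized residuals — with no
per-row z-scoring.

A row cluster carries the "aged phenotype" when, restricted to its rows,
(a) the C day-70 column is strictly closer (Euclidean) to the centroid of
the A 21/28/35 columns than to the centroid of the C 21/28/35 columns, and
(b) the A columns are on average strictly closer to C day-70 than to the
young-C centroid. This is a quantitative rule standing in for what is
otherwise a by-inspection judgement; ties fail the strict inequalities, so
degenerate flat clusters are never flagged.

## Enrichment

Diffusion scores are the stationary distribution of a random walk with
restart (restart probability 0.5, exposed in config) from a uniform seed
distribution on a cluster's metabolites, computed on the largest connected
component via the kernel `K = r(I − (1−r)P)⁻¹` with P column-stochastic;
scores over all nodes sum to 1, and permutation scores are column means of
K, so 10⁴–10⁵ permutations are cheap. The empirical p ("p.score") uses the
+1 pseudo-count, `(1 + #{perm ≥ obs})/(1 + n_perm)`, hence never equals 0,
followed by BH across pathway nodes at FDR < 0.05. Only pathway-type nodes
receive p-values; clusters with fewer than 4 in-network metabolites are
skipped with a logged notice. The default permutation count is 10⁴
(configurable to 10⁵). This permutation scheme is a declared generic
stand-in for diffusion-based enrichment tools, not a reimplementation of
any specific package's normalization.

## Mortality

Age-specific mortality is the fraction of flies alive entering a day that
died during it, `M_d = (n_{d−1} − n_d)/n_{d−1}` ∈ [0, 1], undefined (and
omitted) after extinction. The reversed difference orientation
`(n_d − n_{d−1})/n_{d−1}` would be negative whenever flies die; the
standard positive orientation is implemented. Cohorts pool by day-wise summation of
deaths before M is computed (equivalently after — the operations commute).
Raw daily values are emitted, unsmoothed.

## Problem sizes in tests and the acceptance script

Simulation-heavy checks run at sizes chosen for desk-scale iteration, as
package defaults: calibration runs use 60-metabolite panels (the type-I
behavior of per-metabolite tests does not depend on panel width),
sign-recovery experiments use 80 metabolites with a reduced elastic-net
grid (4 mixing values × 20 strengths over 2 decades), 50 seeds in the test
suite and 20 in the acceptance script, and the end-to-end pipeline run in
the acceptance script uses the full default design with the full clock
grid. Enrichment recovery tests use 2 000–10 000 permutations.

## Known limitations

- Chi-square LRTs with ~20 replicate groups are mildly anti-conservative;
  small-sample corrections (Kenward–Roger/Satterthwaite) are not
  implemented.
- The any-PC divergence verdict has a high family-wise null rate by design
  (see above); interpret a positive verdict accordingly.
- The elastic-net feature sets are unstable under collinearity, as
  penalized regression is designed to be; feature lists should be read as
  representatives of correlated modules, not exhaustive age markers.
- The second-difference elbow rule favors the dominant kink of the WSS
  curve; hierarchically separated data can legitimately place that kink at
  a coarser K than the finest planted structure.
- Mixed models treat replicate intercepts as Gaussian; heavy-tailed
  replicate effects are not modeled.
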