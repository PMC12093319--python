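# metaboclock

Analysis pipeline for metabolomic aging in two-regime experimental-evolution
studies of *Drosophila melanogaster*: populations kept on a short generation
cycle (the accelerated or **A** regime) evolve fast development and early
death, while control (**C**) populations on a long cycle age slowly. Given a
samples × metabolites LC-MS abundance table with sample metadata (regime,
selection history, replicate population, age in days from egg, batch),
`metaboclock` answers three questions:

1. **Convergence** — have recently derived populations converged on the
   metabolome of long-standing populations under the same regime?
   Tested two ways: per-component mixed models on a covariance-matrix PCA
   (`score ~ age × regime × history + (1 | replicate)`, divergence declared
   if any of the first 12 PCs shows a regime × history or
   regime × history × age effect at unadjusted p < 0.05), and a
   two-component PLS discriminant trained on long-standing populations and
   asked to classify the recently derived ones.
2. **Biological age** — does a metabolomic clock see accelerated aging?
   Elastic-net clocks predict age from standardized abundances; within a
   regime, predictions are leave-one-replicate-out (LORO) so no sample is
   predicted by a model that saw its replicate population. Pooling
   within-regime and between-regime predictions, the age-acceleration model

   ```
   predicted_age ~ α + β₁·age + β₂·mode + β₃·age·mode + ε
   ```

   (mode = 0 within, 1 between) tests for an age-independent shift (β₂)
   and a difference in apparent aging rate (β₃). A control clock applied to
   an accelerated regime recovering β₃ > 0 is the metabolomic signature of
   accelerated biological aging. Clock accuracy is
   R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)².
3. **Trajectories** — which metabolites drive the difference? Per-metabolite
   mixed models `value ~ Sel + Age + Sel×Age + (1 | Rep)` with
   likelihood-ratio term tests and Benjamini–Hochberg FDR (q < 0.01);
   group-mean profiles clustered by complete-linkage Euclidean dendrograms
   with the cluster count chosen by the K-means WSS second-difference elbow;
   clusters where old-control profiles (C day 70) resemble the younger
   accelerated samples are flagged as carrying the "aged phenotype"; and
   flagged clusters are scored against a metabolite/pathway network by
   random-walk-with-restart diffusion with a permutation empirical p-value.

Normalization follows the field-standard LC-MS recipe (drop incomplete
metabolites, natural log, within-sample mean-centering, per-metabolite batch
residualization), and a mortality module turns cohort death logs into
age-specific mortality series M_d = (n_{d−1} − n_d)/n_{d−1}.

Everything is exercisable without any data download through a synthetic-data
generator (`metaboclock.synthetic`) that emulates the study design: 202
metabolites × 80 pooled samples (2 regimes × 2 histories × 5 replicate
populations × 4 ages; A sampled at days 9/21/28/35, C at 21/28/35/70), three
LC-MS batches, replicate random effects, and planted age/regime/interaction
effects with known ground truth.

## Worked example

```python
from metaboclock import (SimulationConfig, simulate_metabolome, normalize,
                         loro_predictions, between_regime_predictions,
                         fit_age_acceleration, r_squared)

cfg = SimulationConfig(seed=7)          # A ages 2x faster than C by default
table, truth = simulate_metabolome(cfg)
norm = normalize(table).exclude([("A", 9)])   # drop post-eclosion samples
a = norm.subset(norm.metadata["regime"] == "A")
c = norm.subset(norm.metadata["regime"] == "C")

within_c = loro_predictions(c, seed=1)
clock_c, on_a = between_regime_predictions(c, a, seed=1)
fit = fit_age_acceleration(within_c, on_a)
print(round(r_squared(within_c.predictions["age_days"],
                      within_c.predictions["predicted_age"]), 2))
print(round(fit.params["beta3"], 2), f'{fit.pvalues["beta3"]:.1e}')
```

prints

```
0.99
1.05 8.0e-23
```

— the control clock predicts control ages almost perfectly under this
low-noise configuration (R² = 0.99), and applied to the accelerated regime
it sees a significantly steeper predicted-age slope (β₃ = 1.05,
P = 8.0 × 10⁻²³): the accelerated metabolome appears to age faster, as
planted (generative slope ratio 2).

The same run is available end-to-end from the shell:

```bash
metaboclock all --config run.yaml   # or with built-in defaults: metaboclock all
```

which writes per-stage TSVs plus a `report.json` whose rerun under the same
config is byte-identical.

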