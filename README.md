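# mbinterp

Interpolation of missing samples in longitudinal microbiome data sets —
a toolkit for predicting community composition at unsampled time points,
benchmarking interpolation methods, and predicting how accurate an
interpolated sample will be.

## The problem

Longitudinal 16S studies sample individuals irregularly: participants miss
collections, studies are misaligned in time, and many analyses need
compositions on a common grid. The standard fix is to interpolate the
relative-abundance profile x<sup>t</sup> ∈ Δ<sup>n</sup> (the simplex of
n taxa) at a missing time t from the same individual's other samples. This
package implements the full spectrum of methods used for that task and the
machinery to evaluate them:

* **naive** — per-taxon mean or median over all samples, or
  carry-the-last-sample-forward; plus the `equal` null that predicts
  abundance 1/n for every taxon;
* **general-purpose** — weighted average of the bracketing samples
  ((t₂−t)x₁ + (t−t₁)x₂)/(t₂−t₁); K-nearest-neighbors in time with
  Epanechnikov kernel weights ¾(1−u²), u = |tᵢ−t| / maxⱼ|tⱼ−t| (K=5 by
  default); per-taxon cubic splines with clipping at zero;
* **ecological dynamics** — the discretized generalized Lotka-Volterra
  model Δln xᵢ/Δt = βᵢ + Σⱼ αᵢⱼ xⱼ, written as the regression F = (A B)Y
  and estimated by least squares (`glv_mse`), ridge regression (`mlrr`),
  or the sparse bootstrap-stepwise LIMITS estimator;
* **temporal machine learning** — a linear-Gaussian dynamic Bayesian
  network linking each taxon to the taxa (plus the inter-sample gap Δt) at
  the previous sample, in dense (ridge) and sparse (greedy BIC)
  configurations.

Accuracy is measured by leave-one-out cross-validation with the
Bray-Curtis similarity 1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) (= Σ min(xᵢ,yᵢ) on the
simplex). On top of the comparison sit the analyses that explain *why*
accuracy varies: local community stability (mean Bray-Curtis similarity
among the samples surrounding a time point), per-taxon stability via the
bimodality coefficient β = (γ²+1) / (κ + 3(n−1)²/((n−2)(n−3))), Shannon
diversity, sample-size and sampling-gap Monte-Carlo experiments, and a
linear mixed model with per-individual random intercepts that predicts
logit-transformed accuracy from the sampling gaps and the accuracy at
neighboring time points.

A seeded synthetic-cohort generator (stable adult-like dynamics vs
successional infant-like dynamics, conditionally-present taxa, 30 taxa +
an "others" category) makes every stage testable without any external
data.

## Worked example

```python
import mbinterp as mi

cfg = mi.SyntheticConfig(n_individuals=4, n_adult=2,
                         n_samples_range=(30, 40), seed=7)
profiles, truth = mi.simulate_cohort(cfg)

records = []
for prof in profiles:
    for method in ("knn", "weighted_average", "last", "equal"):
        records.extend(mi.loo_evaluate(prof, method))

print(mi.summarize_accuracy(records, group_by="method").round(3))
```

```
                    n  mean_bc  median_bc  mean_relative_error  n_failed  rank
method
weighted_average  131    0.838      0.888               21.190         0     1
knn               131    0.816      0.868               27.028         0     2
last              131    0.782      0.840               27.170         0     3
equal             131    0.490      0.550              886.630         0     4
```

Each row is one method's leave-one-out performance pooled over the four
individuals' 131 interior samples: `mean_bc` is the mean Bray-Curtis
similarity between predicted and held-out compositions (1 = perfect), and
the neighbor-based methods clearly beat both the naive carry-forward and
the uniform null (whose huge relative error comes from assigning rare taxa
the same abundance as dominant ones). Fitting the accuracy predictor to
the KNN records:

```python
fit = mi.InterpolationAccuracyModel.from_records(
    [r for r in records if r.method_name == "knn"]).fit()
print(fit.summary())
```

```
Interpolation-accuracy mixed model (logit Bray-Curtis response)
  converged: True
  random intercept variance: 0.00111262
  residual variance:         0.180264

                 coef       se      z          p
intercept      0.5243   0.2129  2.462     0.0138
gap_prev      -0.1261  0.04799 -2.628   0.008579
gap_next      -0.1014  0.05294 -1.916    0.05534
logit_bc_prev  0.4838  0.06996  6.916  4.652e-12
logit_bc_next  0.4152  0.08174   5.08  3.783e-07
```

Longer gaps to the neighboring samples reduce expected accuracy (negative
coefficients), while high accuracy at the adjacent time points strongly
predicts high accuracy at the target — the temporal autocorrelation that
makes accuracy predictable at all.

The same workflow is scriptable from the shell:

```bash
mbinterp simulate --out sim/ --seed 3
mbinterp evaluate --input sim/A00_table.tsv --meta sim/A00_meta.tsv \
    --individual A00 --methods knn,spline,mlrr --out records.tsv
mbinterp run --out full_run/ --seed 3        # full pipeline + manifest
```

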